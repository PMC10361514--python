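lncrnas	mirna	mrnas
UBXN1,ZFYVE21	hsa-miR-4725-3p	MOCS1,CALCOCO1
MSTRG.881527.1	hsa-miR-449a	PAMR1
ANTXR1	hsa-miR-3187-3p	SCAPER
SORBS3	hsa-miR-6125	HOXA5
FLOT1	hsa-miR-4763	AP001931.2
ANTXR1	hsa-miR-4741	PYGM
WBP2	hsa-miR-4446	EVI5,PAK6,ATAD1,CYB5D2
NONO	hsa-miR-1306-5p	B3GNT3
ANTXR1	hsa-miR-2278	PYGM,ALG12,PAK6
MSTRG.1236517.2	hsa-miR-185-5p	ALOX15B
LGMN,SORBS3,OAZ1	hsa-miR-6764-5p	PAK6,PAMR1
TALDO1	hsa-miR-1343	CYB5D2
MOCS1,WBP2	hsa-miR-3151	ARVCF,SNUPN,MOCS1
ZFYVE21	hsa-miR-3198	NYNRIN
SPCS1,PRRC1,ZFYVE21	hsa-miR-4478	PAK6
MSTRG.881527.1	hsa-miR-449b-5p	PAMR1
POLR2H	hsa-miR-6780a-5p	SLC34A2
BRAT1	hsa-miR-4707	AP001931.2,PAK6
SPCS1	hsa-miR-4689	ALG12
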