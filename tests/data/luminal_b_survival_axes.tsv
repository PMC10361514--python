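lncrnas	mirna	mrnas
MSTRG.1293794.213,NONHSAT193357.1	hsa-miR-1908-5p	OGFR,AC068580.4
LLGL1	hsa-miR-1268	DES
OAZ1	hsa-miR-7851-3p	ALG12,HOXA5
SORBS3	hsa-miR-1273h	RRAS
NONHSAT135873.2	hsa-miR-2277-5p	TPBG,CYP4X1
SORBS3,ZNF207	hsa-miR-6803-5p	PAPPA2
SORBS3,MSTRG.662649.52	hsa-miR-3178	ARVCF
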