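# cerna-texo

Competing endogenous RNA (ceRNA) network inference for tissue-exosome
expression profiles.

## The problem

Long noncoding RNAs (lncRNAs) can act as molecular sponges: by binding a
shared microRNA (miRNA) they relieve the repression that miRNA exerts on
its mRNA targets. In expression data this ceRNA relationship leaves a
characteristic signature — the miRNA is *negatively* correlated with both
the lncRNA and the mRNA, while the lncRNA and mRNA co-vary *positively*.
`cerna-texo` implements the standard small-cohort workflow for mapping
such regulation in tissue-derived exosome RNA-seq of tumor subtypes
(e.g. luminal B vs triple-negative breast cancer, each against benign
controls):

1. **Differential expression** per RNA class (mRNA, lncRNA, miRNA) with
   the two-group Mann–Whitney U test on FPKM values, filtered by
   FPKM > 5, raw P < 0.05 and fold change > 1.5 (symmetric);
2. **lncRNA target assignment** — *cis* by a ±100-kb genomic window,
   *trans* by expression correlation (Pearson r > 0.95);
3. **miRNA-target evidence integration** from multiple prediction
   sources (miRanda/TargetScan/miRWalk-style edge lists) with a
   configurable source-agreement requirement;
4. **ceRNA triple assembly**: a (lncRNA, miRNA, mRNA) axis is kept when
   both miRNA-target correlations are negative with |r| > 0.5;
5. **Network analysis**: the triples form a tripartite graph
   (miRNA–lncRNA and miRNA–mRNA edges); hubs are nodes with degree > 5;
   two subtype networks can be intersected node- and edge-wise;
6. **Survival screening**: each network miRNA is dichotomized at the
   cohort median and tested with the two-sample log-rank statistic
   χ² = (O−E)²/V (hypergeometric variance); significant miRNAs are
   expanded into survival axes listing all their network partners.

Because the patient sequencing data such studies use are access-restricted,
the package ships a synthetic-data generator that plants known DE features,
ceRNA triples with controlled correlation strength, decoy interaction
evidence and prognostic miRNAs — so the whole pipeline is testable and
benchmarkable end to end with exact ground truth.

## Worked example

```python
import cerna_texo as ct

design = ct.SimulationDesign(seed=1)          # 8 cases vs 8 controls
matrices, truth, annotation, evidence, cohort = ct.generate_dataset(design)

result = ct.run_comparison(matrices, evidence)
print(result.summary())

emitted = {(t.lncrna, t.mirna, t.mrna) for t in result.triples}
planted = set(truth.triples)
print("precision", len(emitted & planted) / len(emitted),
      "recall", len(emitted & planted) / len(planted))

km, axes = ct.run_survival_screen(result.network, cohort.table,
                                  cohort.mirna_expression)
print("survival axes:", ct.count_axes(axes))
```

prints

```
{'n_nodes': 31, 'n_lncrna': 10, 'n_mirna': 10, 'n_mrna': 11, 'n_edges': 21,
 'n_triples': 11, 'n_triple_memberships': 22,
 'de_mRNA': 30, 'de_lncRNA': 30, 'de_miRNA': 30, 'hubs': 0}
precision 0.9090909090909091 recall 1.0
survival axes: 3
```

All 30 planted DE features per class are called, all 10 planted triples
are recovered (one extra triple arises from a decoy edge at the default
30 % decoy rate), and the 3 planted prognostic miRNAs come out as the 3
survival axes.

The same pipeline is available from the shell:

```bash
cerna-texo simulate --outdir data --seed 1
cerna-texo run --mrna data/mrna.tsv --lncrna data/lncrna.tsv \
    --mirna data/mirna.tsv --groups data/groups.tsv \
    --evidence data/evidence.tsv --annotation data/annotation.gff3 \
    --survival data/survival.tsv \
    --survival-expression data/survival_mirna_expression.tsv \
    --outdir out
```

`out/` then contains the DE tables, the qualified-edge and triple tables,
the network in GraphML and SIF, the hub table, the KM screen and the
survival-axis table. `cerna-texo intersect` compares two subtype networks
and `cerna-texo survival-screen` re-screens an existing network, either
against a survival cohort or a precomputed per-miRNA p-value table.

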