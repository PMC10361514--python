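# Methods

## Pipeline model and assumptions

The pipeline operationalizes ceRNA inference as a chain of filters over
three FPKM-scale expression matrices (mRNA, lncRNA, miRNA) from one
case-vs-control comparison, plus candidate miRNA-target edge lists.

**Differential expression.** Each feature is tested with the two-group
Mann–Whitney U test. The p-value is exact — computed over the full
rank-assignment distribution — whenever both groups have ≤ 8
observations and the pooled values carry no ties, which always holds at
the 8-vs-8 design on continuous FPKM values; otherwise the tie-corrected
normal approximation with continuity correction is used. A feature is
DE when all three filters pass, with *strict* comparators exactly as
such thresholds are printed: max(group means) > 5 FPKM, raw two-sided
P < 0.05, and fold change (pseudocount 0.01 on both group means) > 1.5
or < 1/1.5. The abundance filter defaults to the max of the two group
means so that features expressed in only one condition — exactly the
features a tumor-vs-control contrast must see — survive; "both" and
"overall" interpretations are configurable. No multiplicity correction
enters the filter; a Benjamini–Hochberg q-value column is emitted for
information. At n = 8 + 8 the smallest exact two-sided p is
2/C(16,8) ≈ 1.6 × 10⁻⁴, so the P < 0.05 filter is attainable at study
size.

**lncRNA targets.** Cis: two features pair when they share a chromosome
and their interval gap (boundary-to-boundary, 0 on overlap) is at most
100,000 bp — gap 100,000 passes, 100,001 fails. Strand is ignored: the
window is symmetric upstream/downstream. Trans: Pearson r of the two
expression profiles must exceed 0.95, *signed* by default (a config flag
switches to |r|); constant profiles have undefined correlation and are
excluded with a logged count.

**Evidence integration.** Per-source edge rows are de-duplicated on
(miRNA, target, source) and an edge qualifies when its distinct source
count reaches the class requirement. The default requirement is 1
(union of sources) with the source list recorded on every edge, because
multi-tool target predictions are usually pooled rather than
intersected and the union preserves recall; intersection behavior is a
single config change (`mrna_sources_required`, `lncrna_sources_required`).

**Triple assembly.** For each miRNA with at least one qualified lncRNA
edge and one qualified mRNA edge among DE-passed features, a triple is
emitted when r(miRNA, mRNA) < 0 and r(miRNA, lncRNA) < 0, each with
|r| > 0.5. The correlation threshold is read as a magnitude requirement
under the negative-sign rule. The lncRNA–mRNA correlation is always
computed and reported; requiring it positive (> +0.5) is off by default
— the assembly rules constrain only the two miRNA arms — and available
as `require_lnc_mrna_positive`. Correlations are computed over all
samples of the comparison (case + control pooled) by default, since
ceRNA co-variation is a cross-condition signal; per-group scopes are
configurable.

**Network.** Nodes are the union of triple members, typed by RNA class;
edges are the de-duplicated union of miRNA–lncRNA and miRNA–mRNA pairs
over triples, so the graph is bipartite between {miRNA} and
{lncRNA ∪ mRNA} by construction and a node's degree counts distinct
incident edges. Because "interactions" can be counted either way, both
the edge count and the triple-membership count (2 per triple) are
reported. Hubs are nodes with degree > 5 (strict), ordered by degree
descending and then id — the tie-break is a package choice, as hub
tables in the literature state none. Network intersection compares node
ids verbatim by default; an optional normalizer strips `-NNN`
transcript suffixes for gene-level comparison, since published tables
mix transcript-level and gene-level symbols.

**Survival screen.** Each network miRNA is dichotomized at the cohort
median expression with ties assigned to the low group; an all-equal
profile leaves an empty high group and is flagged non-evaluable rather
than tested. The two-sample log-rank statistic is computed in its
observed-minus-expected form with hypergeometric variance and referred
to χ²(1); the hazard direction is the sign of O − E in the
high-expression group. The screening threshold reuses the global
P < 0.05 with no multiplicity correction, matching the screening style
of such analyses; alternative cutpoints (tertiles, best-cutoff scans)
are deliberately not implemented because a cutoff scan would require
multiplicity control that the screening design does not define. A
precomputed per-miRNA p-value table (e.g. from an external cohort
service) can be dropped in via `read_precomputed_screen`. Significant
miRNAs become survival axes aggregating *all* their lncRNA and mRNA
partners from the network, one row per miRNA.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study conditions downstream stages are
designed for: two groups of 8 samples, log-normal FPKM baselines
(natural-log mean 2.0, sd 1.0 — values chosen so the FPKM > 5 filter
bites on a realistic fraction of features; real dispersions are
dataset-specific and no published value exists for this design), planted
DE features at a multiplicative effect `fc_effect` (default 4), planted
ceRNA triples, decoy evidence edges, and an independent survival cohort
(default 200 patients) with exponential event times.

Correlated triples use one latent N(0,1) factor per triple per sample:

    log x_i = mu_i + shift_i(group) + noise_sd · (s_i·√c·f + √(1−c)·e_i)

with sign s = +1 for the lncRNA and mRNA and −1 for the miRNA, so the
within-group pairwise correlation is ±`corr_strength` (c) in
expectation, independently of `noise_sd` — the construction controls r
directly. Within a triple the lncRNA and mRNA shift together between
groups and the miRNA shifts oppositely, which is the ceRNA-consistent
configuration and further aligns pooled-sample correlations. Planted
features draw their baseline above log(10): planting differential
signal below the abundance filter would make the truth unrecoverable by
construction, which is not what the benchmark is meant to measure;
non-planted features keep the full baseline distribution. Decoy
evidence pairs are added so the expected decoy fraction of distinct
(miRNA, target) pairs equals `decoy_edge_rate` (default 0.3). Survival
hazards are `λ₀·exp(Σ βk zk)` over the designated prognostic miRNAs
(β = ±1 by default, z the standardized log-expression), with uniform
independent censoring on (0, 150] against a baseline median of 60 time
units.

Randomness comes from one root seed with four child streams spawned in
a fixed order (expression, annotation, evidence, survival), so each
generator is reproducible in isolation and a fixed seed gives
byte-identical outputs.

The generator does **not** emulate read-level sequencing noise, UMI
counting, isoform structure, batch effects, library-size artifacts, or
the heavy zero-inflation of real exosome RNA-seq. Passing the recovery
benchmarks therefore shows the *inference chain* is correct under its
own model — not that the thresholds are well-calibrated for any real
dataset.

## Numerical choices and degenerate inputs

- All thresholds are strict inequalities; boundary values fail. This is
  centralized in `PipelineConfig` predicates used by every stage.
- Fold change uses a 0.01 FPKM pseudocount on both group means; both the
  pseudocount and the Mann–Whitney method (auto/exact/asymptotic) are
  config-exposed because neither is ever stated in published methods.
- Undefined correlations (constant profiles) never pass a correlation
  filter and are counted in the stage log.
- Coordinates are 0-based half-open internally (BED convention); GFF3 is
  converted at the boundary (start−1, end) and converted back on write,
  so both round-trips are identity maps.
- A degenerate log-rank table (no events, empty group, zero variance)
  yields χ² = 0, p = 1, or a non-evaluable flag rather than an error.
- Deterministic ordering everywhere: DE tables by feature id, triples by
  (lncRNA, miRNA, mRNA), hubs by (degree desc, id), axes by miRNA.

## Problem sizes

Default simulated sizes are 300 mRNAs, 150 lncRNAs, 80 miRNAs, 30
planted DE features per class, 10 triples and a 200-patient survival
cohort: large enough that the abundance/FC/p filters, decoys and the
median split all act non-trivially, while a full study run (generation
through survival screen) completes in seconds. The type-I benchmark
uses 2,000 null features; recovery benchmarks average 5 seeds.

## Known limitations

- The Mann–Whitney exact path delegates to scipy; tied data at small n
  fall back to the corrected normal approximation rather than an exact
  conditional test.
- The trans-target step computes a dense correlation matrix; for
  genome-scale inputs (tens of thousands of features) it should be
  chunked.
- Survival screening assumes right censoring independent of expression.
- Evidence integration treats sources as exchangeable labels; scores
  from individual tools are carried through but never thresholded.
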