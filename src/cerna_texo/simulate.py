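"""Synthetic three-layer expression data with planted ceRNA structure.

The generator emulates the study design the pipeline is meant for: two
small patient groups (8 tumor-tissue exosome samples vs 8 controls),
FPKM-scale abundances, a set of planted differentially expressed features
per RNA class at a chosen fold-change effect, and planted
lncRNA/miRNA/mRNA triples whose expression profiles carry the ceRNA
correlation signature (miRNA anti-correlated with both partners, the
lncRNA-mRNA pair positively correlated). Candidate interaction evidence
is emitted with configurable per-source attribution plus decoy edges, and
a separate survival cohort carries hazards tied to designated prognostic
miRNAs. The planted truth is returned alongside, so recovery of every
downstream stage can be measured exactly.

Generative model
----------------
Feature log-FPKM baselines are Normal(baseline_log_mean, baseline_log_sd)
(natural log). For a planted triple, the three members share a per-sample
latent factor f ~ N(0,1):

    log x_i = mu_i + shift_i(group) + noise_sd * (s_i*sqrt(c)*f + sqrt(1-c)*e_i)

with s_i = +1 for the lncRNA and mRNA, -1 for the miRNA, c = corr_strength,
and e_i iid N(0,1); within-group pairwise Pearson correlation is therefore
+/- corr_strength in expectation, independent of noise_sd. Planted DE
features receive a case-group shift of +/- log(fc_effect); within a triple
the lncRNA and mRNA shift together and the miRNA in the opposite
direction, so pooled-sample correlations keep the ceRNA-consistent signs.
Non-planted features are independent noise.

Randomness: one root seed; four child streams (expression, annotation,
evidence, survival) spawned in that order, so each generator is
reproducible on its own.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, validate_survival

_STREAMS = {"expression": 0, "annotation": 1, "evidence": 2, "survival": 3}

# Planted features draw their baseline above this floor (mean FPKM >= 10):
# differential signal planted below the abundance filter would be
# unrecoverable by construction, which is not what the benchmark measures.
_PLANTED_LOG_FLOOR = math.log(10.0)


class SizingError(ValueError):
    """Feature counts too small to host the requested planted structure."""


@dataclasses.dataclass
class SimulationDesign:
    """All knobs of the synthetic study, with the study-design defaults."""

    n_case: int = 8
    n_control: int = 8
    n_mrna: int = 300
    n_lncrna: int = 150
    n_mirna: int = 80
    n_de_per_class: int = 30
    n_triples: int = 10
    fc_effect: float = 4.0
    corr_strength: float = 0.9
    noise_sd: float = 0.2
    decoy_edge_rate: float = 0.3
    baseline_log_mean: float = 2.0
    baseline_log_sd: float = 1.0
    cis_fraction: float = 0.5
    mrna_edge_sources: Sequence[str] = ("sourceA", "sourceB", "sourceC")
    lncrna_edge_sources: Sequence[str] = ("sourceA", "sourceD")
    n_patients: int = 200
    n_prognostic: int = 3
    survival_beta: float = 1.0
    baseline_median_time: float = 60.0
    censor_horizon: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise SizingError("need at least 2 samples per group")
        if not self.fc_effect > 1:
            raise SizingError(f"fc_effect must be > 1, got {self.fc_effect}")
        if not 0 <= self.corr_strength <= 1:
            raise SizingError(f"corr_strength must be in [0, 1], got {self.corr_strength}")
        if not 0 <= self.decoy_edge_rate < 1:
            raise SizingError(f"decoy_edge_rate must be in [0, 1), got {self.decoy_edge_rate}")
        if not 0 <= self.cis_fraction <= 1:
            raise SizingError(f"cis_fraction must be in [0, 1], got {self.cis_fraction}")
        if self.noise_sd < 0:
            raise SizingError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.n_triples > self.n_de_per_class:
            raise SizingError(
                f"{self.n_triples} triples need {self.n_triples} DE features per class, "
                f"but n_de_per_class={self.n_de_per_class}")
        for n_features, label in ((self.n_mrna, "n_mrna"), (self.n_lncrna, "n_lncrna"),
                                  (self.n_mirna, "n_mirna")):
            if n_features < self.n_de_per_class:
                raise SizingError(f"{label}={n_features} cannot host "
                                  f"{self.n_de_per_class} planted DE features")
        if self.n_prognostic > self.n_triples:
            raise SizingError(f"n_prognostic={self.n_prognostic} exceeds n_triples={self.n_triples}")

    def rng(self, stream: str) -> np.random.Generator:
        """Child generator for one of the four documented streams."""
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return np.random.default_rng(children[_STREAMS[stream]])


@dataclasses.dataclass
class PlantedTruth:
    """Ground truth of a simulated dataset.

    ``de_features``: (feature id, rna class, direction) tuples;
    ``triples``: (lncRNA, miRNA, mRNA) id tuples;
    ``prognostic_mirnas``: (miRNA id, hazard direction) with direction
    ``high-risk`` (higher expression, higher hazard) or ``low-risk``.
    """

    de_features: list[tuple[str, str, str]]
    triples: list[tuple[str, str, str]]
    prognostic_mirnas: list[tuple[str, str]]

    def de_ids(self, rna_class: str | None = None) -> set[str]:
        return {f for f, cls, _ in self.de_features
                if rna_class is None or cls == rna_class}

    def planted_pairs(self) -> set[tuple[str, str]]:
        """All (miRNA, target) couplings implied by the planted triples."""
        pairs: set[tuple[str, str]] = set()
        for lnc, mir, mrna in self.triples:
            pairs.add((mir, mrna))
            pairs.add((mir, lnc))
        return pairs

    def to_json(self, path: str | Path) -> None:
        payload = {"de_features": self.de_features, "triples": self.triples,
                   "prognostic_mirnas": self.prognostic_mirnas}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        payload = json.loads(Path(path).read_text())
        return cls(de_features=[tuple(x) for x in payload["de_features"]],
                   triples=[tuple(x) for x in payload["triples"]],
                   prognostic_mirnas=[tuple(x) for x in payload["prognostic_mirnas"]])


def _feature_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(1, n + 1)]


def _plan_truth(design: SimulationDesign) -> PlantedTruth:
    """Deterministic assignment of planted ids and directions."""
    ids = {"mRNA": _feature_ids("gene", design.n_mrna),
           "lncRNA": _feature_ids("lnc", design.n_lncrna),
           "miRNA": _feature_ids("mir", design.n_mirna)}
    de_features: list[tuple[str, str, str]] = []
    triples: list[tuple[str, str, str]] = []
    for t in range(design.n_triples):
        direction = "up" if t % 2 == 0 else "down"
        flipped = "down" if direction == "up" else "up"
        lnc, mir, mrna = ids["lncRNA"][t], ids["miRNA"][t], ids["mRNA"][t]
        triples.append((lnc, mir, mrna))
        de_features += [(lnc, "lncRNA", direction), (mrna, "mRNA", direction),
                        (mir, "miRNA", flipped)]
    for cls in ("mRNA", "lncRNA", "miRNA"):
        for k in range(design.n_triples, design.n_de_per_class):
            direction = "up" if k % 2 == 0 else "down"
            de_features.append((ids[cls][k], cls, direction))
    prognostic = [(mir, "high-risk" if i % 2 == 0 else "low-risk")
                  for i, (_, mir, _) in enumerate(triples[: design.n_prognostic])]
    return PlantedTruth(de_features=de_features, triples=triples,
                        prognostic_mirnas=prognostic)


def generate_expression(design: SimulationDesign
                        ) -> tuple[dict[str, ExpressionMatrix], PlantedTruth]:
    """Generate the three FPKM matrices and the planted truth.

    Returns a dict keyed by rna class (``mRNA``, ``lncRNA``, ``miRNA``)
    and the :class:`PlantedTruth`.
    """
    rng = design.rng("expression")
    truth = _plan_truth(design)
    n_samples = design.n_case + design.n_control
    samples = [f"case{i + 1:02d}" for i in range(design.n_case)] + \
              [f"ctrl{i + 1:02d}" for i in range(design.n_control)]
    groups = pd.Series(["case"] * design.n_case + ["control"] * design.n_control,
                       index=samples)
    case_mask = np.array([g == "case" for g in groups])

    direction_of = {feat: d for feat, _, d in truth.de_features}
    triple_member: dict[str, tuple[int, float]] = {}  # feature -> (triple idx, sign)
    for t, (lnc, mir, mrna) in enumerate(truth.triples):
        triple_member[lnc] = (t, +1.0)
        triple_member[mrna] = (t, +1.0)
        triple_member[mir] = (t, -1.0)

    # one latent factor per triple per sample, shared across the three classes
    factors = rng.standard_normal((max(design.n_triples, 1), n_samples))
    sqrt_c = math.sqrt(design.corr_strength)
    sqrt_1c = math.sqrt(1.0 - design.corr_strength)
    log_fc = math.log(design.fc_effect)

    matrices: dict[str, ExpressionMatrix] = {}
    sizes = {"mRNA": design.n_mrna, "lncRNA": design.n_lncrna, "miRNA": design.n_mirna}
    prefixes = {"mRNA": "gene", "lncRNA": "lnc", "miRNA": "mir"}
    for cls in ("mRNA", "lncRNA", "miRNA"):
        features = _feature_ids(prefixes[cls], sizes[cls])
        mu = design.baseline_log_mean + design.baseline_log_sd * rng.standard_normal(len(features))
        noise = rng.standard_normal((len(features), n_samples))
        log_x = np.empty((len(features), n_samples))
        for i, feat in enumerate(features):
            base = mu[i]
            if feat in direction_of and base < _PLANTED_LOG_FLOOR:
                base = _PLANTED_LOG_FLOOR + abs(base - design.baseline_log_mean) * 0.25
            row = np.full(n_samples, base)
            if feat in triple_member:
                t, sign = triple_member[feat]
                latent = sign * sqrt_c * factors[t] + sqrt_1c * noise[i]
                row = row + design.noise_sd * latent
            else:
                row = row + design.noise_sd * noise[i]
            if feat in direction_of:
                shift = log_fc if direction_of[feat] == "up" else -log_fc
                row = row + shift * case_mask
            log_x[i] = row
        values = pd.DataFrame(np.exp(log_x), index=features, columns=samples)
        matrices[cls] = ExpressionMatrix(values, cls, groups)
    return matrices, truth


def generate_annotation(design: SimulationDesign, truth: PlantedTruth,
                        cis_fraction: float | None = None) -> pd.DataFrame:
    """Genomic intervals for mRNAs and lncRNAs (internal 0-based half-open).

    The first ``round(cis_fraction * n_triples)`` planted lncRNA-mRNA pairs
    are placed within 100 kb on the same chromosome; the remaining planted
    pairs are placed on different chromosomes. Other features are placed
    uniformly at random.
    """
    if cis_fraction is None:
        cis_fraction = design.cis_fraction
    rng = design.rng("annotation")
    chroms = [f"chr{i}" for i in range(1, 6)]
    chrom_len = 200_000_000

    rows: dict[str, dict] = {}

    def place(feature: str, chrom: str, start: int) -> None:
        length = int(rng.integers(5_000, 50_000))
        start = int(np.clip(start, 0, chrom_len - length - 1))
        rows[feature] = {"feature": feature, "chrom": chrom, "start": start,
                         "end": start + length,
                         "strand": "+" if rng.random() < 0.5 else "-"}

    n_cis = int(round(cis_fraction * len(truth.triples)))
    for t, (lnc, _mir, mrna) in enumerate(truth.triples):
        gene_chrom_idx = int(rng.integers(len(chroms)))
        place(mrna, chroms[gene_chrom_idx], int(rng.integers(1_000_000, chrom_len - 1_000_000)))
        if t < n_cis:
            gap = int(rng.integers(0, 50_000))
            place(lnc, chroms[gene_chrom_idx], rows[mrna]["end"] + gap)
        else:
            other = chroms[(gene_chrom_idx + 1) % len(chroms)]
            place(lnc, other, int(rng.integers(1_000_000, chrom_len - 1_000_000)))

    for prefix, n in (("gene", design.n_mrna), ("lnc", design.n_lncrna)):
        for feature in _feature_ids(prefix, n):
            if feature not in rows:
                chrom = chroms[int(rng.integers(len(chroms)))]
                place(feature, chrom, int(rng.integers(0, chrom_len - 100_000)))

    table = pd.DataFrame(list(rows.values()),
                         columns=["feature", "chrom", "start", "end", "strand"])
    return table.sort_values("feature").reset_index(drop=True)


def generate_evidence(truth: PlantedTruth, design: SimulationDesign) -> pd.DataFrame:
    """Candidate interaction evidence: planted couplings plus decoys.

    Every planted triple (L, X, M) contributes X->M rows attributed to each
    of ``design.mrna_edge_sources`` and X->L rows attributed to each of
    ``design.lncrna_edge_sources``. Decoy (miRNA, target) pairs not
    corresponding to planted couplings are added so that the expected decoy
    fraction of distinct pairs equals ``decoy_edge_rate``; each decoy gets
    a random non-empty subset of the class's sources.
    """
    rng = design.rng("evidence")
    rows = []
    for lnc, mir, mrna in truth.triples:
        for source in design.mrna_edge_sources:
            rows.append({"mirna": mir, "target": mrna, "target_class": "mRNA",
                         "source": source})
        for source in design.lncrna_edge_sources:
            rows.append({"mirna": mir, "target": lnc, "target_class": "lncRNA",
                         "source": source})

    planted_pairs = truth.planted_pairs()
    n_planted = len(planted_pairs)
    rate = design.decoy_edge_rate
    if rate > 0 and n_planted > 0:
        total = int(round(n_planted / (1.0 - rate)))
        n_decoys = int(rng.binomial(total, rate))
        mirnas = _feature_ids("mir", design.n_mirna)
        targets = ([(g, "mRNA") for g in _feature_ids("gene", design.n_mrna)] +
                   [(l, "lncRNA") for l in _feature_ids("lnc", design.n_lncrna)])
        seen = set(planted_pairs)
        made = 0
        while made < n_decoys:
            mir = mirnas[int(rng.integers(len(mirnas)))]
            target, cls = targets[int(rng.integers(len(targets)))]
            if (mir, target) in seen:
                continue
            seen.add((mir, target))
            pool = design.mrna_edge_sources if cls == "mRNA" else design.lncrna_edge_sources
            k = int(rng.integers(1, len(pool) + 1))
            for source in rng.choice(list(pool), size=k, replace=False):
                rows.append({"mirna": mir, "target": target, "target_class": cls,
                             "source": str(source)})
            made += 1
    return pd.DataFrame(rows, columns=["mirna", "target", "target_class", "source"])


@dataclasses.dataclass
class SurvivalDataset:
    """A simulated survival cohort: outcome table plus its miRNA expression.

    The cohort is independent of the 8-vs-8 tissue samples, emulating the
    external patient cohort such screens are run against.
    """

    table: pd.DataFrame                 # sample, time, event
    mirna_expression: pd.DataFrame      # miRNAs x patients, FPKM scale


def generate_survival(truth: PlantedTruth, design: SimulationDesign) -> SurvivalDataset:
    """Exponential event times with hazards tied to prognostic miRNAs.

    Per-patient hazard is ``lambda0 * exp(sum_k beta_k * z_k)`` where
    ``z_k`` is the standardized log-expression of prognostic miRNA k and
    ``beta_k = +survival_beta`` for high-risk, ``-survival_beta`` for
    low-risk miRNAs; all other miRNAs have beta = 0. Censoring is uniform
    on (0, censor_horizon], independent of the event process.
    """
    rng = design.rng("survival")
    patients = [f"patient{i + 1:04d}" for i in range(design.n_patients)]
    mirnas = _feature_ids("mir", design.n_mirna)
    z = rng.standard_normal((len(mirnas), design.n_patients))
    expression = pd.DataFrame(np.exp(design.baseline_log_mean + z),
                              index=mirnas, columns=patients)

    beta = {mir: (design.survival_beta if direction == "high-risk" else -design.survival_beta)
            for mir, direction in truth.prognostic_mirnas}
    log_hazard = np.zeros(design.n_patients)
    for mir, b in beta.items():
        log_hazard += b * z[mirnas.index(mir)]
    lambda0 = math.log(2.0) / design.baseline_median_time
    event_times = rng.exponential(1.0 / (lambda0 * np.exp(log_hazard)))
    censor_times = rng.uniform(0.0, design.censor_horizon, size=design.n_patients)
    time = np.minimum(event_times, censor_times)
    event = (event_times <= censor_times).astype(int)
    table = validate_survival(pd.DataFrame({"sample": patients, "time": time,
                                            "event": event}))
    return SurvivalDataset(table=table, mirna_expression=expression)


def generate_dataset(design: SimulationDesign):
    """Run all four generators; returns (matrices, truth, annotation, evidence, survival)."""
    matrices, truth = generate_expression(design)
    annotation = generate_annotation(design, truth)
    evidence = generate_evidence(truth, design)
    survival = generate_survival(truth, design)
    return matrices, truth, annotation, evidence, survival


def write_dataset(design: SimulationDesign, outdir: str | Path) -> None:
    """Generate a full dataset and write every artifact to ``outdir``."""
    from . import io as io_mod  # local import to avoid a cycle at import time

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrices, truth, annotation, evidence, survival = generate_dataset(design)
    names = {"mRNA": "mrna", "lncRNA": "lncrna", "miRNA": "mirna"}
    for cls, matrix in matrices.items():
        io_mod.write_expression(matrix, outdir / f"{names[cls]}.tsv")
    matrices["mRNA"].groups.to_csv(outdir / "groups.tsv", sep="\t", header=False)
    io_mod.write_annotation(annotation, outdir / "annotation.gff3")
    io_mod.write_evidence(evidence, outdir / "evidence.tsv")
    io_mod.write_survival(survival.table, outdir / "survival.tsv")
    survival.mirna_expression.to_csv(outdir / "survival_mirna_expression.tsv",
                                     sep="\t", index_label="feature")
    truth.to_json(outdir / "truth.json")
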