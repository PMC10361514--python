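"""lncRNA target assignment and miRNA-target evidence integration.

Cis targets: same chromosome and a boundary-to-boundary gap of at most
the cis window (default 100 kb; overlap counts as gap 0; strand ignored —
the window is symmetric upstream/downstream). Trans targets: Pearson
correlation of expression profiles above the trans threshold (signed
r > 0.95 by default). Evidence edges qualify when enough distinct
prediction sources agree (default 1, i.e. union of sources).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .containers import ExpressionMatrix, ValidationError
from .io import log_stage


class InputError(ValueError):
    pass


def interval_gap(start_a: int, end_a: int, start_b: int, end_b: int) -> int:
    """Boundary gap between two half-open intervals; 0 when they overlap."""
    return max(0, max(start_a, start_b) - min(end_a, end_b))


def cis_targets(lnc_annotation: pd.DataFrame, gene_annotation: pd.DataFrame,
                config: PipelineConfig) -> pd.DataFrame:
    """All lncRNA-gene pairs within the cis window on the same chromosome.

    Returns columns lncrna, gene, mode ('cis'), distance_bp.
    """
    pairs = lnc_annotation.merge(gene_annotation, on="chrom",
                                 suffixes=("_lnc", "_gene"))
    if len(pairs):
        gap = np.maximum(
            0,
            np.maximum(pairs["start_lnc"], pairs["start_gene"])
            - np.minimum(pairs["end_lnc"], pairs["end_gene"]))
        keep = gap <= config.cis_window_bp
        result = pd.DataFrame({
            "lncrna": pairs.loc[keep, "feature_lnc"].to_numpy(),
            "gene": pairs.loc[keep, "feature_gene"].to_numpy(),
            "mode": "cis",
            "distance_bp": gap[keep].astype(int).to_numpy(),
        })
    else:
        result = pd.DataFrame(columns=["lncrna", "gene", "mode", "distance_bp"])
    result = result[result["lncrna"] != result["gene"]]
    result = result.sort_values(["lncrna", "gene"]).reset_index(drop=True)
    log_stage("cis_targets", lncrnas=lnc_annotation["feature"].nunique(),
              genes=gene_annotation["feature"].nunique(), pairs=len(result))
    return result


def trans_targets(lnc_matrix: ExpressionMatrix, gene_matrix: ExpressionMatrix,
                  config: PipelineConfig,
                  lnc_ids: list[str] | None = None) -> pd.DataFrame:
    """lncRNA-gene pairs whose expression correlation clears the trans filter.

    ``lnc_ids`` restricts the lncRNA side (typically to DE lncRNAs).
    Constant profiles have undefined correlation and are excluded (their
    count is logged). Returns columns lncrna, gene, mode ('trans'),
    pearson_r.
    """
    if set(lnc_matrix.samples) != set(gene_matrix.samples):
        raise InputError("lncRNA and gene matrices must share an identical sample set")
    scope = config.correlation_sample_scope
    samples = lnc_matrix.samples_for_scope(scope)
    lnc_ids = list(lnc_ids) if lnc_ids is not None else lnc_matrix.features

    lnc_values = lnc_matrix.values.loc[lnc_ids, samples].to_numpy(dtype=float)
    gene_values = gene_matrix.values.loc[:, samples].to_numpy(dtype=float)
    lnc_const = lnc_values.std(axis=1) == 0
    gene_const = gene_values.std(axis=1) == 0
    n_const = int(lnc_const.sum() + gene_const.sum())

    rows = []
    with np.errstate(invalid="ignore", divide="ignore"):
        lnc_z = _standardize(lnc_values)
        gene_z = _standardize(gene_values)
        corr = lnc_z @ gene_z.T / lnc_values.shape[1]
    gene_ids = gene_matrix.features
    for i, lnc in enumerate(lnc_ids):
        if lnc_const[i]:
            continue
        for j in np.flatnonzero(~gene_const):
            gene = gene_ids[j]
            if gene == lnc:
                continue
            r = float(corr[i, j])
            if config.passes_trans_r(r):
                rows.append({"lncrna": lnc, "gene": gene, "mode": "trans",
                             "pearson_r": r})
    result = pd.DataFrame(rows, columns=["lncrna", "gene", "mode", "pearson_r"])
    result = result.sort_values(["lncrna", "gene"]).reset_index(drop=True)
    log_stage("trans_targets", lncrnas=len(lnc_ids), genes=len(gene_ids),
              constant_excluded=n_const, pairs=len(result))
    return result


def _standardize(values: np.ndarray) -> np.ndarray:
    centered = values - values.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1, keepdims=True)
    return np.divide(centered, sd, out=np.zeros_like(centered), where=sd > 0)


def qualify_mirna_edges(evidence: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Collapse per-source evidence rows into qualified candidate edges.

    An edge qualifies when its distinct source count reaches the
    class-specific requirement. Duplicate (mirna, target, source) rows
    count once. Returns columns mirna, target, target_class, n_sources,
    sources (comma-joined, sorted).
    """
    if evidence.empty:
        raise InputError("evidence table is empty")
    bad = sorted(set(evidence["target_class"]) - {"mRNA", "lncRNA"})
    if bad:
        raise ValidationError(f"unknown target_class value(s): {bad}")
    deduped = evidence.drop_duplicates(subset=["mirna", "target", "source"])
    grouped = (deduped.groupby(["mirna", "target", "target_class"])["source"]
               .agg(lambda s: sorted(set(s))).reset_index())
    grouped["n_sources"] = grouped["source"].map(len)
    required = grouped["target_class"].map(
        {"mRNA": config.mrna_sources_required, "lncRNA": config.lncrna_sources_required})
    qualified = grouped[grouped["n_sources"] >= required].copy()
    qualified["sources"] = qualified["source"].map(",".join)
    qualified = (qualified.drop(columns=["source"])
                 .loc[:, ["mirna", "target", "target_class", "n_sources", "sources"]]
                 .sort_values(["mirna", "target"]).reset_index(drop=True))
    log_stage("qualify_mirna_edges", candidate_edges=len(grouped),
              qualified=len(qualified))
    return qualified
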