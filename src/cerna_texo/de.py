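"""Two-group differential expression on the FPKM scale.

Per feature: a two-sided Mann-Whitney U test between case and control
samples, a pseudocounted fold change of group means, and the three-way
filter (abundance, significance, effect size) with strict comparators.
The test is exact (full enumeration over rank assignments) when both
groups have at most 8 observations and the data carry no ties — i.e.
always at the 8-vs-8 study size on continuous FPKM values — and falls
back to the tie-corrected normal approximation with continuity correction
otherwise.

Filtering uses the raw P-value; a Benjamini-Hochberg q-value column is
emitted for information only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .containers import ExpressionMatrix
from .io import log_stage

DE_COLUMNS = ("feature", "rna_class", "mean_case", "mean_control", "fc",
              "log2fc", "U", "p", "bh_q", "direction", "passed")


class InputError(ValueError):
    pass


def mann_whitney(case_values, control_values, method: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U for the case group, p).

    ``method='auto'`` uses exact enumeration when both groups have <= 8
    observations and the pooled data contain no ties, otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size < 2 or control.size < 2:
        raise InputError(f"each group needs >= 2 observations, "
                         f"got {case.size} and {control.size}")
    if method == "auto":
        pooled = np.concatenate([case, control])
        has_ties = np.unique(pooled).size < pooled.size
        method = "asymptotic" if (has_ties or max(case.size, control.size) > 8) else "exact"
    result = stats.mannwhitneyu(case, control, alternative="two-sided",
                                method=method, use_continuity=True)
    return float(result.statistic), float(result.pvalue)


def run_de(matrix: ExpressionMatrix, config: PipelineConfig) -> pd.DataFrame:
    """One DE result row per feature, ordered by feature id.

    Columns: feature, rna_class, mean_case, mean_control, fc, log2fc,
    U, p, bh_q, direction, passed. ``direction`` is case-relative
    (``up`` = higher in case) and ``ns`` for features failing any filter.
    """
    case_samples = matrix.samples_in_group("case")
    control_samples = matrix.samples_in_group("control")
    if not case_samples or not control_samples:
        raise InputError("matrix must contain both case and control samples")

    rows = []
    for feature in sorted(matrix.features):
        case = matrix.profile(feature, case_samples)
        control = matrix.profile(feature, control_samples)
        mean_case = float(case.mean())
        mean_control = float(control.mean())
        fc = (mean_case + config.pseudocount) / (mean_control + config.pseudocount)
        u_stat, p = mann_whitney(case, control, method=config.mw_method)
        mean_overall = float(np.concatenate([case, control]).mean())
        passed = (config.passes_abundance(mean_case, mean_control, mean_overall)
                  and config.passes_p(p)
                  and config.passes_fold_change(fc))
        direction = ("up" if fc > 1 else "down") if passed else "ns"
        rows.append({"feature": feature, "rna_class": matrix.rna_class,
                     "mean_case": mean_case, "mean_control": mean_control,
                     "fc": fc, "log2fc": float(np.log2(fc)), "U": u_stat, "p": p,
                     "direction": direction, "passed": passed})
    table = pd.DataFrame(rows)
    table["bh_q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    table = table.loc[:, list(DE_COLUMNS)]
    n_up = int((table["direction"] == "up").sum())
    n_down = int((table["direction"] == "down").sum())
    log_stage("run_de", rna_class=matrix.rna_class, features=len(table),
              passed=n_up + n_down, up=n_up, down=n_down)
    return table


def shared_de(de_a: pd.DataFrame, de_b: pd.DataFrame
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Features DE in both comparisons, split by direction concordance.

    Returns ``(concordant, discordant)`` tables with columns
    feature, rna_class, direction_a, direction_b.
    """
    classes_a = set(de_a["rna_class"])
    classes_b = set(de_b["rna_class"])
    if classes_a != classes_b:
        raise InputError(f"rna_class mismatch between tables: {sorted(classes_a)} "
                         f"vs {sorted(classes_b)}")
    passed_a = de_a.loc[de_a["passed"], ["feature", "rna_class", "direction"]]
    passed_b = de_b.loc[de_b["passed"], ["feature", "direction"]]
    merged = passed_a.merge(passed_b, on="feature", suffixes=("_a", "_b"))
    merged = merged.sort_values("feature").reset_index(drop=True)
    concordant = merged[merged["direction_a"] == merged["direction_b"]].reset_index(drop=True)
    discordant = merged[merged["direction_a"] != merged["direction_b"]].reset_index(drop=True)
    log_stage("shared_de", concordant=len(concordant), discordant=len(discordant))
    return concordant, discordant
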