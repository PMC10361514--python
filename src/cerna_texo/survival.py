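"""Kaplan-Meier screening of network miRNAs for prognostic power.

Each miRNA's cohort is dichotomized at the median expression (ties go to
the low group) and the two survival curves are compared with the
two-sample log-rank test in its observed-minus-expected form: at each
distinct event time, the expected high-group event count under the null
is d * n_high / n and the variance is the hypergeometric
d * (n_high/n) * (1 - n_high/n) * (n - d)/(n - 1); the statistic
(O - E)^2 / V is referred to a chi-square with 1 df. The sign of O - E in
the high group gives the hazard direction (more events than expected in
high expressers = high-risk miRNA).

Significant miRNAs are expanded into survival axes: one row per miRNA
aggregating all of its lncRNA partners and all of its mRNA partners from
the ceRNA network. A precomputed per-miRNA p-value table can stand in for
the KM screen (e.g. results from an external cohort service).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .containers import validate_survival
from .io import log_stage
from .network import CeRNANetwork


class InputError(ValueError):
    pass


@dataclasses.dataclass
class KMScreenResult:
    """Log-rank outcome for one miRNA after median dichotomization."""

    mirna: str
    n_high: int
    n_low: int
    logrank_chi2: float
    p_value: float
    hazard_direction: str           # "high-risk" | "low-risk" | "na"
    significant: bool
    evaluable: bool = True


def logrank_two_group(time, event, in_high) -> tuple[float, float, float]:
    """Two-sample log-rank test; returns (chi2, p, O_minus_E_high).

    ``in_high`` is a boolean mask selecting the high-expression group.
    A degenerate table (no events, or an empty group) yields chi2=0, p=1.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    in_high = np.asarray(in_high, dtype=bool)

    observed_high = 0.0
    expected_high = 0.0
    variance = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = int(at_risk.sum())
        n_high = int((at_risk & in_high).sum())
        d = int(((time == t) & (event == 1)).sum())
        d_high = int(((time == t) & (event == 1) & in_high).sum())
        observed_high += d_high
        expected_high += d * n_high / n
        if n > 1:
            variance += d * (n_high / n) * (1 - n_high / n) * (n - d) / (n - 1)
    o_minus_e = observed_high - expected_high
    if variance <= 0:
        return 0.0, 1.0, o_minus_e
    chi2 = o_minus_e ** 2 / variance
    return float(chi2), float(stats.chi2.sf(chi2, df=1)), float(o_minus_e)


def km_logrank(survival: pd.DataFrame, expression: pd.Series,
               config: PipelineConfig | None = None,
               mirna: str = "") -> KMScreenResult:
    """Median-split KM screen of one miRNA against a survival table.

    ``expression`` is indexed by sample id; only samples present in both
    inputs are used. Ties at the median go to the low group. An
    all-equal expression vector (empty high group) is flagged
    non-evaluable.
    """
    config = config or PipelineConfig()
    survival = validate_survival(survival)
    common = [s for s in survival["sample"] if s in expression.index]
    if len(common) < 4:
        raise InputError(f"need >= 4 overlapping samples, got {len(common)}")
    table = survival.set_index("sample").loc[common]
    values = expression.loc[common].to_numpy(dtype=float)
    median = float(np.median(values))
    in_high = values > median
    n_high, n_low = int(in_high.sum()), int((~in_high).sum())
    if n_high < 2 or n_low < 2:
        return KMScreenResult(mirna=mirna, n_high=n_high, n_low=n_low,
                              logrank_chi2=float("nan"), p_value=float("nan"),
                              hazard_direction="na", significant=False,
                              evaluable=False)
    chi2, p, o_minus_e = logrank_two_group(table["time"], table["event"], in_high)
    direction = "na" if o_minus_e == 0 else ("high-risk" if o_minus_e > 0 else "low-risk")
    return KMScreenResult(mirna=mirna, n_high=n_high, n_low=n_low,
                          logrank_chi2=chi2, p_value=p, hazard_direction=direction,
                          significant=config.passes_p(p), evaluable=True)


SCREEN_COLUMNS = ("mirna", "n_high", "n_low", "logrank_chi2", "p_value",
                  "hazard_direction", "significant", "evaluable")


def screen_mirnas(network: CeRNANetwork, survival: pd.DataFrame,
                  mirna_expression: pd.DataFrame,
                  config: PipelineConfig | None = None) -> pd.DataFrame:
    """KM-screen every miRNA of the network; one row per miRNA.

    miRNAs without expression in the cohort are reported non-evaluable.
    """
    config = config or PipelineConfig()
    rows = []
    for mirna in sorted(network.nodes_of_type("miRNA")):
        if mirna not in mirna_expression.index:
            result = KMScreenResult(mirna=mirna, n_high=0, n_low=0,
                                    logrank_chi2=float("nan"), p_value=float("nan"),
                                    hazard_direction="na", significant=False,
                                    evaluable=False)
        else:
            result = km_logrank(survival, mirna_expression.loc[mirna], config, mirna=mirna)
        rows.append(dataclasses.asdict(result))
    table = pd.DataFrame(rows, columns=list(SCREEN_COLUMNS))
    log_stage("screen_mirnas", mirnas=len(table),
              significant=int(table["significant"].sum()),
              non_evaluable=int((~table["evaluable"]).sum()))
    return table


def read_precomputed_screen(path: str | Path,
                            config: PipelineConfig | None = None) -> pd.DataFrame:
    """Adapter: a TSV of (mirna, p [, direction]) from an external screen."""
    config = config or PipelineConfig()
    table = pd.read_csv(path, sep="\t")
    if "mirna" not in table.columns or "p" not in table.columns:
        raise InputError(f"{path}: adapter table needs 'mirna' and 'p' columns")
    out = pd.DataFrame({
        "mirna": table["mirna"].astype(str),
        "n_high": 0, "n_low": 0,
        "logrank_chi2": float("nan"),
        "p_value": table["p"].astype(float),
        "hazard_direction": table.get("direction", pd.Series(["na"] * len(table))),
        "evaluable": True,
    })
    out["significant"] = [config.passes_p(p) for p in out["p_value"]]
    return out.loc[:, list(SCREEN_COLUMNS)]


def screen_axes(network: CeRNANetwork, km_results: pd.DataFrame,
                config: PipelineConfig | None = None) -> pd.DataFrame:
    """One survival axis per significant network miRNA.

    Each axis aggregates ALL lncRNA partners and ALL mRNA partners the
    miRNA has in the network (the multi-partner row shape of a survival
    ceRNA table). Columns: mirna, lncrnas, mrnas (comma-joined, sorted),
    p_value; rows ordered by mirna.
    """
    del config  # significance is already recorded in km_results
    network_mirnas = network.nodes_of_type("miRNA")
    rows = []
    for row in km_results.itertuples(index=False):
        if not row.significant or row.mirna not in network_mirnas:
            continue
        lncrnas = network.neighbors_of_type(row.mirna, "lncRNA")
        mrnas = network.neighbors_of_type(row.mirna, "mRNA")
        if not lncrnas or not mrnas:
            continue
        rows.append({"mirna": row.mirna, "lncrnas": ",".join(lncrnas),
                     "mrnas": ",".join(mrnas), "p_value": row.p_value})
    table = pd.DataFrame(rows, columns=["mirna", "lncrnas", "mrnas", "p_value"])
    table = table.sort_values("mirna").reset_index(drop=True)
    log_stage("screen_axes", axes=len(table))
    return table


def count_axes(axes: pd.DataFrame) -> int:
    """Number of distinct miRNA-keyed survival axes."""
    return int(axes["mirna"].nunique())
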