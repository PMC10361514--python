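"""Pipeline configuration: every filter threshold of the analysis in one place.

All comparators are *strict*, exactly as thresholds of this kind are printed
in methods sections (FPKM > 5, fold change > 1.5, P < 0.05, r > 0.95,
|r| > 0.5, degree > 5): a value sitting exactly on a threshold fails its
filter.  The predicate methods on :class:`PipelineConfig` are the single
source of truth for these comparisons; every pipeline stage routes its
filtering through them.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Optional

import yaml

FPKM_FILTER_MODES = ("max", "both", "overall")
CORRELATION_SCOPES = ("all", "case", "control")
MW_METHODS = ("auto", "exact", "asymptotic")


class ConfigError(ValueError):
    """Raised when a configuration value violates its invariant."""


@dataclasses.dataclass
class PipelineConfig:
    """Thresholds and policy switches for the ceRNA pipeline.

    Parameters
    ----------
    fpkm_min : float
        Abundance filter on the FPKM scale (strictly greater-than).
    fc_min : float
        Fold-change filter, applied symmetrically: a feature passes when
        FC > fc_min or FC < 1/fc_min.
    p_max : float
        Raw two-sided P-value ceiling (strictly less-than). No multiple
        testing correction is applied in filtering; a BH q-value column is
        emitted for information.
    trans_r_min : float
        Pearson threshold for trans-acting lncRNA target calls. Signed by
        default (r > trans_r_min); set ``trans_use_abs`` to threshold |r|.
    cerna_abs_r_min : float
        Magnitude threshold for the miRNA-target correlations inside a
        ceRNA triple (the sign must be negative; see ``passes_cerna_r``).
    cis_window_bp : int
        Maximum boundary-to-boundary gap for a cis lncRNA-gene pair
        (inclusive: a gap equal to the window passes).
    hub_min_degree : int
        Minimum degree to call a network node a hub. The default 6
        implements the strict "degree > 5" convention.
    mrna_sources_required, lncrna_sources_required : int
        How many distinct prediction sources an evidence edge needs.
    correlation_sample_scope : str
        Which samples correlations are computed over: "all" (case +
        control pooled, the default — ceRNA co-variation is
        cross-condition), "case" or "control".
    pseudocount : float
        FPKM offset added to both group means before the fold-change
        ratio, guarding against division by zero.
    fpkm_filter_mode : str
        Interpretation of the abundance filter: "max" (default; max of the
        two group means — keeps features expressed in only one condition),
        "both", or "overall".
    trans_use_abs : bool
        Threshold |r| instead of signed r for trans target calls.
    require_lnc_mrna_positive : bool
        Additionally require r(lncRNA, mRNA) > cerna_abs_r_min in a triple.
        Off by default: the assembly rules constrain only the two
        miRNA-target correlations.
    mw_method : str
        Mann-Whitney p-value method: "auto" (exact when both groups have
        <= 8 observations and no ties), "exact", or "asymptotic".
    """

    fpkm_min: float = 5.0
    fc_min: float = 1.5
    p_max: float = 0.05
    trans_r_min: float = 0.95
    cerna_abs_r_min: float = 0.5
    cis_window_bp: int = 100_000
    hub_min_degree: int = 6
    mrna_sources_required: int = 1
    lncrna_sources_required: int = 1
    correlation_sample_scope: str = "all"
    pseudocount: float = 0.01
    fpkm_filter_mode: str = "max"
    trans_use_abs: bool = False
    require_lnc_mrna_positive: bool = False
    mw_method: str = "auto"

    def __post_init__(self) -> None:
        for name in ("fpkm_min", "fc_min", "p_max", "trans_r_min",
                     "cerna_abs_r_min", "pseudocount"):
            value = getattr(self, name)
            if not (value > 0) or not math.isfinite(value):
                raise ConfigError(f"{name} must be a positive finite number, got {value!r}")
        if self.cis_window_bp <= 0:
            raise ConfigError(f"cis_window_bp must be > 0, got {self.cis_window_bp!r}")
        if not isinstance(self.hub_min_degree, int) or self.hub_min_degree < 1:
            raise ConfigError(f"hub_min_degree must be an integer >= 1, got {self.hub_min_degree!r}")
        for name in ("mrna_sources_required", "lncrna_sources_required"):
            value = getattr(self, name)
            if not isinstance(value, int) or value < 1:
                raise ConfigError(f"{name} must be an integer >= 1, got {value!r}")
        if self.fpkm_filter_mode not in FPKM_FILTER_MODES:
            raise ConfigError(f"fpkm_filter_mode must be one of {FPKM_FILTER_MODES}")
        if self.correlation_sample_scope not in CORRELATION_SCOPES:
            raise ConfigError(f"correlation_sample_scope must be one of {CORRELATION_SCOPES}")
        if self.mw_method not in MW_METHODS:
            raise ConfigError(f"mw_method must be one of {MW_METHODS}")

    # ------------------------------------------------------------------
    # Filter predicates (strict comparators; single source of truth)
    # ------------------------------------------------------------------

    def passes_abundance(self, mean_case: float, mean_control: float,
                         mean_overall: Optional[float] = None) -> bool:
        """FPKM abundance filter (strict: exactly fpkm_min fails)."""
        if self.fpkm_filter_mode == "max":
            return max(mean_case, mean_control) > self.fpkm_min
        if self.fpkm_filter_mode == "both":
            return min(mean_case, mean_control) > self.fpkm_min
        if mean_overall is None:
            raise ConfigError("fpkm_filter_mode='overall' needs mean_overall")
        return mean_overall > self.fpkm_min

    def passes_fold_change(self, fold_change: float) -> bool:
        """Symmetric fold-change filter: FC > fc_min or FC < 1/fc_min."""
        return fold_change > self.fc_min or fold_change < 1.0 / self.fc_min

    def passes_p(self, p_value: float) -> bool:
        """Raw P-value filter (strict: exactly p_max fails)."""
        return p_value < self.p_max

    def passes_trans_r(self, r: float) -> bool:
        """Trans-acting correlation filter (signed by default)."""
        if math.isnan(r):
            return False
        value = abs(r) if self.trans_use_abs else r
        return value > self.trans_r_min

    def passes_cerna_r(self, r: float) -> bool:
        """miRNA-target correlation rule: negative sign AND |r| above threshold."""
        if math.isnan(r):
            return False
        return r < 0 and abs(r) > self.cerna_abs_r_min

    def passes_lnc_mrna_r(self, r: float) -> bool:
        """Optional lncRNA-mRNA positive co-expression check."""
        if math.isnan(r):
            return False
        return r > self.cerna_abs_r_min

    def within_cis_window(self, gap_bp: int) -> bool:
        """Cis window test on the boundary gap (gap == window passes)."""
        return 0 <= gap_bp <= self.cis_window_bp

    def is_hub(self, degree: int) -> bool:
        """Hub rule: degree >= hub_min_degree (default: degree > 5)."""
        return degree >= self.hub_min_degree

    # ------------------------------------------------------------------
    # Serialization
    # ------------------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level of the config must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=False)
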