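"""In-memory containers for the pipeline's primary data: expression
matrices on the FPKM scale, genomic feature annotation (internally
0-based half-open), and right-censored survival tables.

Validation happens at construction: downstream stages can assume ids are
unique, values dense and non-negative, and every sample group-labelled.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RNA_CLASSES = ("mRNA", "lncRNA", "miRNA")
GROUP_LABELS = ("case", "control")
ANNOTATION_COLUMNS = ("feature", "chrom", "start", "end", "strand")
SURVIVAL_COLUMNS = ("sample", "time", "event")


class ValidationError(ValueError):
    """Raised when input data violates a container invariant."""


def _check_unique(ids: Sequence, what: str) -> None:
    counts = pd.Index(ids).value_counts()
    dupes = counts[counts > 1]
    if len(dupes):
        raise ValidationError(f"duplicate {what} id(s): {sorted(map(str, dupes.index[:5]))}")


class ExpressionMatrix:
    """A dense features x samples FPKM matrix for one RNA class.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by feature id, columns by sample id. Non-negative,
        no missing entries.
    rna_class : str
        One of ``mRNA``, ``lncRNA``, ``miRNA``.
    groups : mapping or pandas.Series
        Sample id -> group label (``case`` / ``control``); every sample
        in ``values`` must be labelled.
    """

    def __init__(self, values: pd.DataFrame, rna_class: str,
                 groups: Mapping[str, str] | pd.Series):
        if rna_class not in RNA_CLASSES:
            raise ValidationError(f"rna_class must be one of {RNA_CLASSES}, got {rna_class!r}")
        _check_unique(values.index, "feature")
        _check_unique(values.columns, "sample")
        array = values.to_numpy(dtype=float, copy=True)
        if np.isnan(array).any():
            bad = values.index[np.isnan(array).any(axis=1)][0]
            raise ValidationError(f"missing value in feature {bad!r}")
        if (array < 0).any():
            bad = values.index[(array < 0).any(axis=1)][0]
            raise ValidationError(f"negative FPKM value in feature {bad!r}")
        groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
        missing = [s for s in values.columns if s not in groups.index]
        if missing:
            raise ValidationError(f"sample(s) without a group label: {missing[:5]}")
        bad_labels = sorted(set(groups.loc[list(values.columns)]) - set(GROUP_LABELS))
        if bad_labels:
            raise ValidationError(f"group labels must be in {GROUP_LABELS}, got {bad_labels}")

        self.values = pd.DataFrame(array, index=values.index.astype(str),
                                   columns=values.columns.astype(str))
        self.rna_class = rna_class
        self.groups = groups.loc[list(values.columns)].astype(str)
        self.groups.index = self.groups.index.astype(str)

    # -- accessors -----------------------------------------------------

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in_group(self, group: str) -> list[str]:
        if group not in GROUP_LABELS:
            raise ValidationError(f"unknown group {group!r}")
        return [s for s in self.samples if self.groups[s] == group]

    def samples_for_scope(self, scope: str) -> list[str]:
        """Samples used for correlation under a config scope."""
        if scope == "all":
            return self.samples
        return self.samples_in_group(scope)

    def profile(self, feature: str, samples: Iterable[str] | None = None) -> np.ndarray:
        row = self.values.loc[feature]
        if samples is not None:
            row = row.loc[list(samples)]
        return row.to_numpy(dtype=float)

    def subset_features(self, features: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(features)], self.rna_class, self.groups)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"ExpressionMatrix({self.rna_class}, {self.n_features} features x "
                f"{self.n_samples} samples)")


def validate_annotation(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a feature annotation table (0-based half-open intervals)."""
    missing = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"annotation missing column(s): {missing}")
    _check_unique(table["feature"], "annotated feature")
    if table["chrom"].astype(str).str.len().eq(0).any():
        raise ValidationError("annotation has an empty chromosome name")
    starts = table["start"].to_numpy()
    ends = table["end"].to_numpy()
    bad = np.flatnonzero(~(starts < ends))
    if bad.size:
        row = table.iloc[bad[0]]
        raise ValidationError(
            f"feature {row['feature']!r}: start must be < end, got [{row['start']}, {row['end']})")
    if (starts < 0).any():
        raise ValidationError("annotation has a negative start coordinate")
    bad_strand = sorted(set(table["strand"]) - {"+", "-", "."})
    if bad_strand:
        raise ValidationError(f"invalid strand value(s): {bad_strand}")
    out = table.loc[:, list(ANNOTATION_COLUMNS)].copy()
    out["feature"] = out["feature"].astype(str)
    out["chrom"] = out["chrom"].astype(str)
    out["start"] = out["start"].astype(int)
    out["end"] = out["end"].astype(int)
    return out.reset_index(drop=True)


def validate_survival(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a survival table: positive times, binary event indicator."""
    missing = [c for c in SURVIVAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"survival table missing column(s): {missing}")
    _check_unique(table["sample"], "survival sample")
    times = table["time"].to_numpy(dtype=float)
    if not np.all(times > 0):
        bad = table.iloc[int(np.flatnonzero(~(times > 0))[0])]
        raise ValidationError(f"sample {bad['sample']!r}: time must be > 0, got {bad['time']}")
    events = table["event"].to_numpy()
    if not np.isin(events, [0, 1]).all():
        bad = table.iloc[int(np.flatnonzero(~np.isin(events, [0, 1]))[0])]
        raise ValidationError(f"sample {bad['sample']!r}: event must be 0 or 1, got {bad['event']}")
    out = table.loc[:, list(SURVIVAL_COLUMNS)].copy()
    out["sample"] = out["sample"].astype(str)
    out["time"] = out["time"].astype(float)
    out["event"] = out["event"].astype(int)
    return out.reset_index(drop=True)
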