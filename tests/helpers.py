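"""Shared test helpers."""

import pandas as pd

from cerna_texo import ExpressionMatrix


def make_matrix(rows: dict, n_case=4, n_control=4, rna_class="mRNA") -> ExpressionMatrix:
    """Tiny expression matrix from feature -> values (case samples first)."""
    samples = [f"c{i}" for i in range(n_case)] + [f"n{i}" for i in range(n_control)]
    groups = {s: ("case" if s.startswith("c") else "control") for s in samples}
    return ExpressionMatrix(pd.DataFrame(rows, index=samples).T, rna_class, groups)
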