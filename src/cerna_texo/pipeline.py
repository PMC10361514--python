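"""End-to-end orchestration: expression matrices + evidence in, DE tables,
triples, network, hubs and survival axes out."""

from __future__ import annotations

import dataclasses
from typing import Mapping

import pandas as pd

from .config import PipelineConfig
from .containers import ExpressionMatrix
from .de import run_de, shared_de
from .network import (CeRNANetwork, CeRNATriple, IntersectionReport,
                      assemble_triples, build_network, find_hubs,
                      intersect_networks)
from .survival import screen_axes, screen_mirnas
from .targets import cis_targets, qualify_mirna_edges, trans_targets


@dataclasses.dataclass
class ComparisonResult:
    """Everything computed for one case-vs-control comparison."""

    de_tables: dict[str, pd.DataFrame]
    qualified_edges: pd.DataFrame
    triples: list[CeRNATriple]
    network: CeRNANetwork
    hubs: pd.DataFrame
    lnc_targets: pd.DataFrame | None = None

    def directions(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for table in self.de_tables.values():
            for row in table.loc[table["passed"]].itertuples(index=False):
                out[row.feature] = row.direction
        return out

    def summary(self) -> dict:
        summary = dict(self.network.summary())
        for cls, table in self.de_tables.items():
            summary[f"de_{cls}"] = int(table["passed"].sum())
        summary["hubs"] = len(self.hubs)
        return summary


def run_comparison(matrices: Mapping[str, ExpressionMatrix],
                   evidence: pd.DataFrame,
                   config: PipelineConfig | None = None,
                   annotation: pd.DataFrame | None = None) -> ComparisonResult:
    """DE -> evidence qualification -> triples -> network -> hubs.

    ``matrices`` is keyed by rna class (mRNA / lncRNA / miRNA). When an
    annotation table is supplied, cis and trans lncRNA targets of the DE
    lncRNAs are computed as well.
    """
    config = config or PipelineConfig()
    de_tables = {cls: run_de(matrix, config) for cls, matrix in matrices.items()}
    qualified = qualify_mirna_edges(evidence, config)
    triples = assemble_triples(de_tables, qualified, matrices, config)
    directions = {}
    for table in de_tables.values():
        for row in table.loc[table["passed"]].itertuples(index=False):
            directions[row.feature] = row.direction
    network = build_network(triples, directions)
    hubs = find_hubs(network, config)

    lnc_targets = None
    if annotation is not None:
        de_lnc = sorted(de_tables["lncRNA"].loc[de_tables["lncRNA"]["passed"], "feature"])
        lnc_ann = annotation[annotation["feature"].isin(de_lnc)]
        gene_ids = set(matrices["mRNA"].features)
        gene_ann = annotation[annotation["feature"].isin(gene_ids)]
        cis = cis_targets(lnc_ann, gene_ann, config)
        trans = trans_targets(matrices["lncRNA"], matrices["mRNA"], config,
                              lnc_ids=[f for f in de_lnc])
        lnc_targets = pd.concat([cis, trans], ignore_index=True)
    return ComparisonResult(de_tables=de_tables, qualified_edges=qualified,
                            triples=triples, network=network, hubs=hubs,
                            lnc_targets=lnc_targets)


@dataclasses.dataclass
class StudyResult:
    """Two subtype comparisons plus their shared-DE and network intersection."""

    comparison_a: ComparisonResult
    comparison_b: ComparisonResult
    shared: dict[str, pd.DataFrame]
    discordant: dict[str, pd.DataFrame]
    intersection: IntersectionReport


def run_study(matrices_a: Mapping[str, ExpressionMatrix],
              matrices_b: Mapping[str, ExpressionMatrix],
              evidence_a: pd.DataFrame, evidence_b: pd.DataFrame,
              config: PipelineConfig | None = None) -> StudyResult:
    """Run both subtype comparisons and intersect them."""
    config = config or PipelineConfig()
    result_a = run_comparison(matrices_a, evidence_a, config)
    result_b = run_comparison(matrices_b, evidence_b, config)
    shared, discordant = {}, {}
    for cls in result_a.de_tables:
        concordant_t, discordant_t = shared_de(result_a.de_tables[cls],
                                               result_b.de_tables[cls])
        shared[cls] = concordant_t
        discordant[cls] = discordant_t
    intersection = intersect_networks(result_a.network, result_b.network)
    return StudyResult(comparison_a=result_a, comparison_b=result_b,
                       shared=shared, discordant=discordant,
                       intersection=intersection)


def run_survival_screen(network: CeRNANetwork, survival: pd.DataFrame,
                        mirna_expression: pd.DataFrame,
                        config: PipelineConfig | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """KM-screen the network miRNAs and emit the survival axes."""
    config = config or PipelineConfig()
    km = screen_mirnas(network, survival, mirna_expression, config)
    axes = screen_axes(network, km, config)
    return km, axes
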