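"""ceRNA triple assembly and the tripartite network built from triples.

A triple (lncRNA L, miRNA X, mRNA M) is emitted when both X->M and X->L
are qualified evidence edges among DE-passed features of one comparison
and both miRNA-target correlations are negative with magnitude above the
threshold; the lncRNA-mRNA correlation is recorded (and optionally
required positive). The network is the undirected union of the two edge
kinds over all triples, de-duplicated: it is bipartite between {miRNA}
and {lncRNA, mRNA} by construction, and a node's degree counts distinct
incident edges.
"""

from __future__ import annotations

import dataclasses
import re
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .config import PipelineConfig
from .containers import ExpressionMatrix
from .io import log_stage

_SUFFIX_RE = re.compile(r"-\d{3}$")


@dataclasses.dataclass(frozen=True)
class CeRNATriple:
    """One lncRNA/miRNA/mRNA axis with its three correlations."""

    lncrna: str
    mirna: str
    mrna: str
    r_mi_lnc: float
    r_mi_m: float
    r_lnc_m: float
    mrna_sources: tuple[str, ...] = ()
    lncrna_sources: tuple[str, ...] = ()


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def assemble_triples(de_tables: Mapping[str, pd.DataFrame],
                     qualified_edges: pd.DataFrame,
                     matrices: Mapping[str, ExpressionMatrix],
                     config: PipelineConfig) -> list[CeRNATriple]:
    """Build the correlation-constrained triple list for one comparison.

    ``de_tables`` and ``matrices`` are keyed by rna class. Qualified edges
    whose members lack expression are skipped with a logged count. Output
    is ordered (lncrna, mirna, mrna) lexicographically.
    """
    passed = {cls: set(t.loc[t["passed"], "feature"]) for cls, t in de_tables.items()}
    scope = config.correlation_sample_scope
    samples = matrices["miRNA"].samples_for_scope(scope)
    profiles = {cls: m.values.loc[:, samples] for cls, m in matrices.items()}

    missing_expression = 0
    edges = {"mRNA": {}, "lncRNA": {}}  # class -> mirna -> [(target, sources)]
    for row in qualified_edges.itertuples(index=False):
        cls = row.target_class
        if row.mirna not in passed.get("miRNA", set()) or row.target not in passed.get(cls, set()):
            continue
        if row.mirna not in profiles["miRNA"].index or row.target not in profiles[cls].index:
            missing_expression += 1
            continue
        sources = tuple(str(row.sources).split(",")) if row.sources else ()
        edges[cls].setdefault(row.mirna, []).append((row.target, sources))

    triples: list[CeRNATriple] = []
    for mirna in sorted(set(edges["mRNA"]) & set(edges["lncRNA"])):
        x = profiles["miRNA"].loc[mirna].to_numpy(dtype=float)
        lnc_ok = []
        for lnc, lnc_sources in sorted(edges["lncRNA"][mirna]):
            r_xl = _pearson(x, profiles["lncRNA"].loc[lnc].to_numpy(dtype=float))
            if config.passes_cerna_r(r_xl):
                lnc_ok.append((lnc, r_xl, lnc_sources))
        if not lnc_ok:
            continue
        for mrna, mrna_sources in sorted(edges["mRNA"][mirna]):
            m_profile = profiles["mRNA"].loc[mrna].to_numpy(dtype=float)
            r_xm = _pearson(x, m_profile)
            if not config.passes_cerna_r(r_xm):
                continue
            for lnc, r_xl, lnc_sources in lnc_ok:
                r_lm = _pearson(profiles["lncRNA"].loc[lnc].to_numpy(dtype=float), m_profile)
                if config.require_lnc_mrna_positive and not config.passes_lnc_mrna_r(r_lm):
                    continue
                triples.append(CeRNATriple(lncrna=lnc, mirna=mirna, mrna=mrna,
                                           r_mi_lnc=r_xl, r_mi_m=r_xm, r_lnc_m=r_lm,
                                           mrna_sources=mrna_sources,
                                           lncrna_sources=lnc_sources))
    triples.sort(key=lambda t: (t.lncrna, t.mirna, t.mrna))
    log_stage("assemble_triples", qualified_edges=len(qualified_edges),
              missing_expression=missing_expression, triples=len(triples))
    return triples


def triples_to_frame(triples: Sequence[CeRNATriple]) -> pd.DataFrame:
    rows = [{"lncrna": t.lncrna, "mirna": t.mirna, "mrna": t.mrna,
             "r_mi_lnc": t.r_mi_lnc, "r_mi_m": t.r_mi_m, "r_lnc_m": t.r_lnc_m,
             "mrna_sources": ",".join(t.mrna_sources),
             "lncrna_sources": ",".join(t.lncrna_sources)} for t in triples]
    return pd.DataFrame(rows, columns=["lncrna", "mirna", "mrna", "r_mi_lnc",
                                       "r_mi_m", "r_lnc_m", "mrna_sources",
                                       "lncrna_sources"])


class CeRNANetwork:
    """Typed tripartite graph over the triple set.

    Nodes carry ``node_type`` (lncRNA/miRNA/mRNA) and ``direction`` (the
    DE direction, or "na"); edges carry ``kind`` (miRNA-lncRNA or
    miRNA-mRNA) and ``n_triples`` (how many triples use the edge).
    """

    def __init__(self, graph: nx.Graph, triples: Sequence[CeRNATriple]):
        self.graph = graph
        self.triples = list(triples)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_triple_memberships(self) -> int:
        """Interactions counted per triple membership (2 per triple)."""
        return 2 * len(self.triples)

    def node_counts_by_type(self) -> dict[str, int]:
        counts = {"lncRNA": 0, "miRNA": 0, "mRNA": 0}
        for _, data in self.graph.nodes(data=True):
            counts[data["node_type"]] += 1
        return counts

    def nodes_of_type(self, node_type: str) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["node_type"] == node_type}

    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def neighbors_of_type(self, node: str, node_type: str) -> list[str]:
        return sorted(n for n in self.graph.neighbors(node)
                      if self.graph.nodes[n]["node_type"] == node_type)

    def summary(self) -> dict:
        counts = self.node_counts_by_type()
        return {"n_nodes": self.n_nodes, "n_lncrna": counts["lncRNA"],
                "n_mirna": counts["miRNA"], "n_mrna": counts["mRNA"],
                "n_edges": self.n_edges,
                "n_triples": len(self.triples),
                "n_triple_memberships": self.n_triple_memberships}


def build_network(triples: Sequence[CeRNATriple],
                  directions: Mapping[str, str] | None = None) -> CeRNANetwork:
    """Union of miRNA-lncRNA and miRNA-mRNA edges over the triples.

    ``directions`` maps feature id -> DE direction for node annotation.
    """
    directions = directions or {}
    graph = nx.Graph()
    for triple in triples:
        for node, node_type in ((triple.lncrna, "lncRNA"), (triple.mirna, "miRNA"),
                                (triple.mrna, "mRNA")):
            graph.add_node(node, node_type=node_type,
                           direction=directions.get(node, "na"))
        for partner, kind in ((triple.lncrna, "miRNA-lncRNA"),
                              (triple.mrna, "miRNA-mRNA")):
            if graph.has_edge(triple.mirna, partner):
                graph[triple.mirna][partner]["n_triples"] += 1
            else:
                graph.add_edge(triple.mirna, partner, kind=kind, n_triples=1)
    network = CeRNANetwork(graph, triples)
    log_stage("build_network", **network.summary())
    return network


def find_hubs(network: CeRNANetwork, config: PipelineConfig) -> pd.DataFrame:
    """Nodes clearing the hub rule, sorted by degree desc then id.

    Columns hub, degree, node_type, direction (the hub-table shape:
    hub / degree / expression direction).
    """
    rows = [{"hub": node, "degree": degree,
             "node_type": network.graph.nodes[node]["node_type"],
             "direction": network.graph.nodes[node]["direction"]}
            for node, degree in network.degrees().items() if config.is_hub(degree)]
    table = pd.DataFrame(rows, columns=["hub", "degree", "node_type", "direction"])
    return table.sort_values(["degree", "hub"], ascending=[False, True]).reset_index(drop=True)


def strip_transcript_suffix(feature_id: str) -> str:
    """Normalize transcript-suffixed ids (``SORBS3-203`` -> ``SORBS3``)."""
    return _SUFFIX_RE.sub("", feature_id)


@dataclasses.dataclass
class IntersectionReport:
    """Shared nodes/edges of two comparison networks.

    ``shared_nodes`` columns: node, node_type, direction_a, direction_b,
    concordant. ``subnetwork`` is the induced graph on shared nodes
    restricted to edges present in both networks.
    """

    shared_nodes: pd.DataFrame
    shared_edges: list[tuple[str, str]]
    subnetwork: nx.Graph


def intersect_networks(net_a: CeRNANetwork, net_b: CeRNANetwork,
                       normalize_ids: bool = False) -> IntersectionReport:
    """Commutative, idempotent intersection of two ceRNA networks.

    With ``normalize_ids`` the comparison strips ``-NNN`` transcript
    suffixes (gene-level intersection); reported node ids are then the
    normalized ones.
    """
    def node_map(net: CeRNANetwork) -> dict[str, str]:
        return {n: (strip_transcript_suffix(n) if normalize_ids else n)
                for n in net.graph.nodes}

    map_a, map_b = node_map(net_a), node_map(net_b)
    rev_a = {v: k for k, v in map_a.items()}
    rev_b = {v: k for k, v in map_b.items()}
    shared_ids = sorted(set(map_a.values()) & set(map_b.values()))

    rows = []
    for node in shared_ids:
        a, b = rev_a[node], rev_b[node]
        dir_a = net_a.graph.nodes[a]["direction"]
        dir_b = net_b.graph.nodes[b]["direction"]
        rows.append({"node": node, "node_type": net_a.graph.nodes[a]["node_type"],
                     "direction_a": dir_a, "direction_b": dir_b,
                     "concordant": dir_a == dir_b and dir_a != "na"})
    shared_nodes = pd.DataFrame(rows, columns=["node", "node_type", "direction_a",
                                               "direction_b", "concordant"])

    edges_a = {frozenset((map_a[u], map_a[v])) for u, v in net_a.graph.edges}
    edges_b = {frozenset((map_b[u], map_b[v])) for u, v in net_b.graph.edges}
    shared_edges = sorted(tuple(sorted(e)) for e in edges_a & edges_b)

    subnetwork = nx.Graph()
    for row in rows:
        subnetwork.add_node(row["node"], node_type=row["node_type"])
    for u, v in shared_edges:
        kind = net_a.graph.edges[rev_a[u], rev_a[v]]["kind"]
        subnetwork.add_edge(u, v, kind=kind)
    log_stage("intersect_networks", shared_nodes=len(shared_nodes),
              shared_edges=len(shared_edges))
    return IntersectionReport(shared_nodes=shared_nodes, shared_edges=shared_edges,
                              subnetwork=subnetwork)
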