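"""Triple assembly, network arithmetic, hubs and subtype intersection."""

import numpy as np
import pandas as pd
import pytest

import cerna_texo as ct

from cerna_texo import (CeRNANetwork, CeRNATriple, PipelineConfig, build_network,
                        find_hubs, intersect_networks, run_comparison)
from cerna_texo.network import strip_transcript_suffix
from tests.helpers import make_matrix


def triple(lnc, mir, mrna):
    return CeRNATriple(lncrna=lnc, mirna=mir, mrna=mrna,
                       r_mi_lnc=-0.8, r_mi_m=-0.8, r_lnc_m=0.8)


def random_triples(rng, n):
    return [triple(f"L{rng.integers(8)}", f"X{rng.integers(8)}", f"M{rng.integers(8)}")
            for _ in range(n)]


def brute_force_counts(triples):
    """Independent recount of nodes, edges and degrees from the triple list."""
    nodes, edges = {}, set()
    for t in triples:
        nodes[t.lncrna] = "lncRNA"
        nodes[t.mirna] = "miRNA"
        nodes[t.mrna] = "mRNA"
        edges.add(frozenset((t.mirna, t.lncrna)))
        edges.add(frozenset((t.mirna, t.mrna)))
    degrees = {n: sum(n in e for e in edges) for n in nodes}
    return nodes, edges, degrees


class TestAssembleTriples:
    @staticmethod
    def build_inputs(mir_profile, lnc_profile, m_profile):
        matrices = {"miRNA": make_matrix({"X1": mir_profile}, rna_class="miRNA"),
                    "lncRNA": make_matrix({"L1": lnc_profile}, rna_class="lncRNA"),
                    "mRNA": make_matrix({"M1": m_profile}, rna_class="mRNA")}
        de = {cls: pd.DataFrame({"feature": [f], "rna_class": [cls],
                                 "direction": ["up"], "passed": [True]})
              for cls, f in (("miRNA", "X1"), ("lncRNA", "L1"), ("mRNA", "M1"))}
        edges = pd.DataFrame({"mirna": ["X1", "X1"], "target": ["M1", "L1"],
                              "target_class": ["mRNA", "lncRNA"],
                              "n_sources": [1, 1], "sources": ["sourceA", "sourceA"]})
        return de, edges, matrices

    def test_anticorrelated_candidate_emitted(self, config):
        x = [8, 7, 6, 5, 4, 3, 2, 1]
        partner = [1, 2, 3, 4, 5, 6, 7, 8]
        de, edges, matrices = self.build_inputs(x, partner, partner)
        triples = ct.assemble_triples(de, edges, matrices, config)
        assert len(triples) == 1
        t = triples[0]
        assert t.r_mi_m == pytest.approx(-1.0) and t.r_mi_lnc == pytest.approx(-1.0)
        assert t.r_lnc_m == pytest.approx(1.0)

    def test_positive_mirna_target_correlation_rejected(self, config):
        x = [1, 2, 3, 4, 5, 6, 7, 8]
        de, edges, matrices = self.build_inputs(x, x, x)  # r = +1 everywhere
        assert ct.assemble_triples(de, edges, matrices, config) == []

    def test_weak_negative_correlation_rejected(self):
        """|r| below the magnitude threshold fails even with the right sign."""
        x = [1, 2, 3, 4, 5, 6, 7, 8]
        weak = [5, 7, 4, 8, 3, 6, 2, 5.5]  # r(x, weak) ~ -0.30
        de, edges, matrices = self.build_inputs(x, weak, weak)
        r = float(np.corrcoef(x, weak)[0, 1])
        assert -0.5 < r < 0  # the fixture really is weakly negative
        assert ct.assemble_triples(de, edges, matrices, PipelineConfig()) == []

    def test_non_de_member_blocks_triple(self, config):
        x = [8, 7, 6, 5, 4, 3, 2, 1]
        partner = [1, 2, 3, 4, 5, 6, 7, 8]
        de, edges, matrices = self.build_inputs(x, partner, partner)
        de["mRNA"].loc[0, "passed"] = False
        assert ct.assemble_triples(de, edges, matrices, config) == []

    def test_anti_monotone_in_r_threshold(self, dataset):
        result = run_comparison(dataset["matrices"], dataset["evidence"],
                                PipelineConfig())
        stricter = run_comparison(dataset["matrices"], dataset["evidence"],
                                  PipelineConfig(cerna_abs_r_min=0.95))
        loose = {(t.lncrna, t.mirna, t.mrna) for t in result.triples}
        strict = {(t.lncrna, t.mirna, t.mrna) for t in stricter.triples}
        assert strict <= loose


class TestBuildNetwork:
    def test_single_triple_counts(self):
        net = build_network([triple("L1", "X1", "M1")])
        assert net.n_nodes == 3 and net.n_edges == 2
        assert net.degrees() == {"L1": 1, "X1": 2, "M1": 1}

    def test_shared_mirna_merges(self):
        net = build_network([triple("L1", "X", "M1"), triple("L2", "X", "M2")])
        assert net.n_nodes == 5 and net.n_edges == 4
        assert net.degrees()["X"] == 4
        assert net.node_counts_by_type() == {"lncRNA": 2, "miRNA": 1, "mRNA": 2}

    def test_degrees_match_brute_force_on_random_sets(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            triples = random_triples(rng, int(rng.integers(1, 51)))
            net = build_network(triples)
            nodes, edges, degrees = brute_force_counts(triples)
            assert net.n_nodes == len(nodes)
            assert net.n_edges == len(edges)
            assert net.degrees() == degrees
            assert {n: d["node_type"] for n, d in net.graph.nodes(data=True)} == nodes
            assert sum(net.degrees().values()) == 2 * net.n_edges

    def test_bipartite_between_mirna_and_partners(self):
        rng = np.random.default_rng(8)
        net = build_network(random_triples(rng, 30))
        for u, v in net.graph.edges:
            kinds = {net.graph.nodes[u]["node_type"], net.graph.nodes[v]["node_type"]}
            assert "miRNA" in kinds and kinds != {"miRNA"}

    def test_membership_count_vs_edge_count(self):
        triples = [triple("L1", "X", "M1"), triple("L2", "X", "M1")]
        net = build_network(triples)
        assert net.n_edges == 3                  # X-L1, X-L2, X-M1 (deduplicated)
        assert net.n_triple_memberships == 4     # 2 per triple


class TestHubs:
    def test_degree_six_is_hub_degree_five_is_not(self, config):
        six = build_network([triple(f"L{i}", "X", f"M{i}") for i in range(3)])
        assert six.degrees()["X"] == 6
        assert list(find_hubs(six, config)["hub"]) == ["X"]
        five = build_network([triple(f"L{i}", "X", f"M{i}") for i in range(2)]
                             + [triple("L0", "X", "M2")])
        assert five.degrees()["X"] == 5
        assert find_hubs(five, config).empty

    def test_empty_network(self, config):
        assert find_hubs(build_network([]), config).empty

    def test_ordering_degree_desc_then_id(self, config):
        triples = [triple(f"L{i}", "X1", f"M{i}") for i in range(3)] + \
                  [triple(f"L{i+10}", "X0", f"M{i+10}") for i in range(3)]
        hubs = find_hubs(build_network(triples), config)
        assert list(hubs["hub"]) == ["X0", "X1"]  # equal degree -> lexicographic


class TestIntersect:
    def test_idempotent_and_commutative(self):
        rng = np.random.default_rng(9)
        net_a = build_network(random_triples(rng, 20))
        net_b = build_network(random_triples(rng, 20))
        self_report = intersect_networks(net_a, net_a)
        assert set(self_report.shared_nodes["node"]) == set(net_a.graph.nodes)
        assert len(self_report.shared_edges) == net_a.n_edges
        ab = intersect_networks(net_a, net_b)
        ba = intersect_networks(net_b, net_a)
        assert list(ab.shared_nodes["node"]) == list(ba.shared_nodes["node"])
        assert ab.shared_edges == ba.shared_edges

    def test_disjoint_networks_empty(self):
        net_a = build_network([triple("L1", "X1", "M1")])
        net_b = build_network([triple("L2", "X2", "M2")])
        report = intersect_networks(net_a, net_b)
        assert report.shared_nodes.empty and report.shared_edges == []

    def test_direction_concordance_reported(self):
        t = [triple("L1", "X1", "M1")]
        net_a = build_network(t, directions={"L1": "down", "X1": "up", "M1": "down"})
        net_b = build_network(t, directions={"L1": "down", "X1": "down", "M1": "down"})
        report = intersect_networks(net_a, net_b)
        rows = report.shared_nodes.set_index("node")
        assert bool(rows.loc["L1", "concordant"])
        assert not bool(rows.loc["X1", "concordant"])

    def test_published_axis_tables_intersect_on_known_ids(self, luminal_b_axes, tnbc_axes):
        """Set intersection over the two printed subtype axis tables."""
        def members(table, column):
            return {m for cell in table[column] for m in str(cell).split(",")}

        shared_lnc = members(luminal_b_axes, "lncrnas") & members(tnbc_axes, "lncrnas")
        shared_mrna = members(luminal_b_axes, "mrnas") & members(tnbc_axes, "mrnas")
        assert shared_lnc == {"OAZ1", "SORBS3"}
        assert shared_mrna >= {"ALG12", "HOXA5"}

    def test_transcript_suffix_normalization(self):
        assert strip_transcript_suffix("SORBS3-203") == "SORBS3"
        assert strip_transcript_suffix("hsa-miR-7851-3p") == "hsa-miR-7851-3p"
        net_a = build_network([triple("SORBS3-203", "X1", "M1")])
        net_b = build_network([triple("SORBS3", "X1", "M1")])
        assert "SORBS3-203" not in intersect_networks(net_a, net_b).shared_nodes["node"].tolist()
        normalized = intersect_networks(net_a, net_b, normalize_ids=True)
        assert "SORBS3" in set(normalized.shared_nodes["node"])


class TestEndToEndRecovery:
    def test_planted_triples_recovered_with_decoys(self):
        """corr 0.9, fc 4, noise 0.2, decoys 0.3: precision & recall >= 0.8."""
        precisions, recalls = [], []
        for seed in range(5):
            design = ct.SimulationDesign(seed=seed)
            matrices, truth, _, evidence, _ = ct.generate_dataset(design)
            result = run_comparison(matrices, evidence, PipelineConfig())
            emitted = {(t.lncrna, t.mirna, t.mrna) for t in result.triples}
            planted = set(truth.triples)
            precisions.append(len(emitted & planted) / max(len(emitted), 1))
            recalls.append(len(emitted & planted) / len(planted))
        assert np.mean(precisions) >= 0.8
        assert np.mean(recalls) >= 0.8

    def test_noiseless_no_decoy_recovery_is_exact(self):
        design = ct.SimulationDesign(noise_sd=0.01, decoy_edge_rate=0.0, seed=12)
        matrices, truth = ct.generate_expression(design)
        evidence = ct.generate_evidence(truth, design)
        result = run_comparison(matrices, evidence, PipelineConfig())
        emitted = {(t.lncrna, t.mirna, t.mrna) for t in result.triples}
        assert emitted == set(truth.triples)
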