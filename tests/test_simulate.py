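"""Generator contracts: determinism, planted structure, decoys, survival."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cerna_texo import (PipelineConfig, PlantedTruth, SimulationDesign,
                        generate_annotation, generate_evidence,
                        generate_expression, generate_survival, km_logrank)
from cerna_texo.simulate import SizingError
from cerna_texo.targets import interval_gap


def _corr(matrices, a_cls, a_id, b_cls, b_id):
    x = matrices[a_cls].values.loc[a_id].to_numpy()
    y = matrices[b_cls].values.loc[b_id].to_numpy()
    return float(np.corrcoef(x, y)[0, 1])


class TestExpression:
    def test_same_seed_identical_different_seed_different(self):
        a1, _ = generate_expression(SimulationDesign(seed=5))
        a2, _ = generate_expression(SimulationDesign(seed=5))
        b, _ = generate_expression(SimulationDesign(seed=6))
        for cls in a1:
            pd.testing.assert_frame_equal(a1[cls].values, a2[cls].values)
        assert not a1["mRNA"].values.equals(b["mRNA"].values)

    def test_planted_triples_have_cerna_correlation_signs(self, dataset):
        matrices, truth = dataset["matrices"], dataset["truth"]
        for lnc, mir, mrna in truth.triples:
            assert _corr(matrices, "miRNA", mir, "mRNA", mrna) < 0
            assert _corr(matrices, "miRNA", mir, "lncRNA", lnc) < 0
            assert _corr(matrices, "lncRNA", lnc, "mRNA", mrna) > 0

    def test_planted_correlation_magnitude_near_target_when_noise_small(self):
        design = SimulationDesign(noise_sd=0.01, corr_strength=0.9, seed=3)
        matrices, truth = generate_expression(design)
        for lnc, mir, mrna in truth.triples:
            for r in (_corr(matrices, "miRNA", mir, "mRNA", mrna),
                      _corr(matrices, "miRNA", mir, "lncRNA", lnc)):
                assert abs(abs(r) - design.corr_strength) <= 0.15

    def test_planted_de_fold_change_reaches_effect(self, dataset):
        matrices, truth = dataset["matrices"], dataset["truth"]
        design = dataset["design"]
        for feature, cls, direction in truth.de_features:
            m = matrices[cls]
            case = m.values.loc[feature, m.samples_in_group("case")].mean()
            control = m.values.loc[feature, m.samples_in_group("control")].mean()
            ratio = case / control
            # multiplicative shift of exp(log fc) on every case sample;
            # sampling noise allowed around the planted effect
            if direction == "up":
                assert ratio > design.fc_effect / 1.5
            else:
                assert ratio < 1.5 / design.fc_effect

    def test_all_fpkm_nonnegative_and_dense(self, dataset):
        for m in dataset["matrices"].values():
            assert (m.values.to_numpy() >= 0).all()
            assert not m.values.isna().any().any()

    def test_empty_planting_gives_pure_noise(self):
        design = SimulationDesign(n_de_per_class=0, n_triples=0, n_prognostic=0, seed=2)
        matrices, truth = generate_expression(design)
        assert truth.de_features == [] and truth.triples == []
        assert matrices["mRNA"].n_features == design.n_mrna

    def test_sizing_errors(self):
        with pytest.raises(SizingError):
            SimulationDesign(n_case=1)
        with pytest.raises(SizingError):
            SimulationDesign(fc_effect=1.0)
        with pytest.raises(SizingError):
            SimulationDesign(n_triples=40, n_de_per_class=30)
        with pytest.raises(SizingError):
            SimulationDesign(n_mirna=10, n_de_per_class=30)


class TestAnnotation:
    @pytest.mark.parametrize("cis_fraction", [0.0, 1.0])
    def test_cis_fraction_controls_planted_pair_placement(self, cis_fraction):
        design = SimulationDesign(seed=4, cis_fraction=cis_fraction)
        _, truth = generate_expression(design)
        table = generate_annotation(design, truth, cis_fraction=cis_fraction)
        rows = table.set_index("feature")
        for lnc, _, mrna in truth.triples:
            a, b = rows.loc[lnc], rows.loc[mrna]
            if cis_fraction == 1.0:
                assert a["chrom"] == b["chrom"]
                assert interval_gap(a["start"], a["end"], b["start"], b["end"]) <= 100_000
            else:
                assert a["chrom"] != b["chrom"]

    def test_intervals_valid(self, dataset):
        table = dataset["annotation"]
        assert (table["start"] < table["end"]).all()
        assert (table["start"] >= 0).all()
        assert set(table["strand"]) <= {"+", "-"}
        # every mRNA and lncRNA is annotated
        assert len(table) == dataset["design"].n_mrna + dataset["design"].n_lncrna


class TestEvidence:
    def test_zero_decoy_rate_yields_exactly_planted_pairs(self):
        design = SimulationDesign(decoy_edge_rate=0.0, seed=8)
        _, truth = generate_expression(design)
        evidence = generate_evidence(truth, design)
        pairs = set(zip(evidence["mirna"], evidence["target"]))
        assert pairs == truth.planted_pairs()

    def test_planted_triples_contribute_both_edges_with_sources(self, dataset):
        evidence, truth = dataset["evidence"], dataset["truth"]
        design = dataset["design"]
        for lnc, mir, mrna in truth.triples:
            m_rows = evidence[(evidence.mirna == mir) & (evidence.target == mrna)]
            l_rows = evidence[(evidence.mirna == mir) & (evidence.target == lnc)]
            assert set(m_rows["source"]) == set(design.mrna_edge_sources)
            assert set(l_rows["source"]) == set(design.lncrna_edge_sources)

    def test_decoy_fraction_within_binomial_tolerance(self):
        # pool pairs over seeds; expected decoy fraction is the design rate
        rate, fractions = 0.3, []
        n_planted = n_total = 0
        for seed in range(6):
            design = SimulationDesign(decoy_edge_rate=rate, n_triples=10, seed=seed)
            _, truth = generate_expression(design)
            evidence = generate_evidence(truth, design)
            pairs = set(zip(evidence["mirna"], evidence["target"]))
            n_total += len(pairs)
            n_planted += len(pairs & truth.planted_pairs())
        n_decoy = n_total - n_planted
        # 99% binomial band around rate
        sd = np.sqrt(rate * (1 - rate) / n_total)
        assert abs(n_decoy / n_total - rate) < 3 * sd + 0.02


class TestSurvival:
    def test_event_indicator_binary_and_times_positive(self, dataset):
        table = dataset["survival"].table
        assert set(table["event"]) <= {0, 1}
        assert (table["time"] > 0).all()

    def test_null_logrank_pvalues_uniform(self):
        """beta=0 everywhere: screen p-values follow U(0,1) over replicates."""
        null_truth = PlantedTruth(de_features=[], triples=[], prognostic_mirnas=[])
        pvals = []
        for seed in range(200):
            design = SimulationDesign(n_prognostic=0, n_patients=60, seed=seed)
            surv = generate_survival(null_truth, design)
            res = km_logrank(surv.table, surv.mirna_expression.loc["mir0001"],
                            PipelineConfig(), mirna="mir0001")
            pvals.append(res.p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_prognostic_mirna_detected_with_high_power(self):
        truth = PlantedTruth(de_features=[], triples=[],
                             prognostic_mirnas=[("mir0001", "high-risk")])
        hits = 0
        n_rep = 20
        for seed in range(n_rep):
            design = SimulationDesign(n_patients=200, survival_beta=1.0, seed=seed)
            surv = generate_survival(truth, design)
            res = km_logrank(surv.table, surv.mirna_expression.loc["mir0001"],
                            PipelineConfig(), mirna="mir0001")
            hits += res.significant
        assert hits / n_rep > 0.95

    def test_hazard_direction_matches_planted_direction(self, dataset):
        surv, truth = dataset["survival"], dataset["truth"]
        for mir, direction in truth.prognostic_mirnas:
            res = km_logrank(surv.table, surv.mirna_expression.loc[mir],
                            PipelineConfig(), mirna=mir)
            assert res.hazard_direction == direction
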