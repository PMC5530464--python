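import math

import numpy as np
import pandas as pd
import pytest

from regnetdriver.genome_io import InputError
from regnetdriver.integrate import (
    build_alteration_table,
    differential_expression,
    driver_report,
    hub_enrichment,
    overlap_enrichment,
    sample_overlap,
    signature_enrichment,
    tf_methylation_correlation,
)
from regnetdriver.network_build import RegulatoryNetwork


def network_with_degrees(degrees, hubs=()):
    net = RegulatoryNetwork(
        tf_element={},
        element_genes={},
        tf_targets={tf: {f"g{i}": 1.0 for i in range(d)} for tf, d in degrees.items()},
    )
    net.hubs = set(hubs)
    return net


class TestHubEnrichment:
    def test_sv_vs_methylation_hub_table(self):
        """9 SV-altered TFs (6 hubs) vs 22 methylation-altered TFs (3 hubs)."""
        sv_tfs = {f"sv{i}" for i in range(9)}
        meth_tfs = {f"me{i}" for i in range(22)}
        hubs = {f"sv{i}" for i in range(6)} | {f"me{i}" for i in range(3)}
        res = hub_enrichment(sv_tfs, meth_tfs, hubs)
        assert res.odds_ratio == pytest.approx(11.28, abs=0.005)
        assert res.p_value == pytest.approx(0.0068, abs=5e-5)

    def test_identical_composition_is_null(self):
        a = {f"a{i}" for i in range(10)}
        b = {f"b{i}" for i in range(10)}
        hubs = {f"a{i}" for i in range(5)} | {f"b{i}" for i in range(5)}
        res = hub_enrichment(a, b, hubs)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_balanced_2x2_p_one(self):
        a = {"a1", "a2", "a3", "a4"}
        b = {"b1", "b2", "b3", "b4"}
        hubs = {"a1", "a2", "b1", "b2"}
        assert hub_enrichment(a, b, hubs).p_value == pytest.approx(1.0)

    def test_empty_margin_flagged(self):
        res = hub_enrichment({"a"}, {"b"}, set())
        assert res.degenerate and res.p_value == 1.0


class TestOverlapEnrichment:
    def test_shared_target_scale(self):
        """Overlap of two large target sets within a 17k-gene network."""
        universe = {f"g{i}" for i in range(17_087)}
        a = {f"g{i}" for i in range(8_931)}
        b = {f"g{i}" for i in range(8_931 - 3_443, 8_931 - 3_443 + 5_103)}
        assert len(a & b) == 3_443
        res = overlap_enrichment(a, b, universe)
        assert res.as_dict()["log10_p"] == pytest.approx(-150.82, abs=0.5)

    def test_small_case_exact(self):
        universe = {f"g{i}" for i in range(10)}
        a = {f"g{i}" for i in range(5)}
        b = {f"g{i}" for i in range(1, 5)}
        res = overlap_enrichment(a, b, universe)
        assert res.p_value == pytest.approx(5 / 210)

    def test_disjoint_sets_p_one(self):
        universe = {f"g{i}" for i in range(100)}
        res = overlap_enrichment({"g0"}, {"g99"}, universe)
        assert res.p_value == pytest.approx(1.0)

    def test_subset_violation_is_error(self):
        with pytest.raises(InputError):
            overlap_enrichment({"x"}, set(), {"y"})


class TestSignatureEnrichment:
    def test_knockdown_signature_vs_targets(self):
        """63-gene signature, 38 in a 5,103-gene target set of 17,087."""
        universe = {f"g{i}" for i in range(17_087)}
        targets = {f"g{i}" for i in range(5_103)}
        signature = {f"g{i}" for i in range(38)} | {f"g{i}" for i in range(5_103, 5_103 + 25)}
        res = signature_enrichment(signature, targets, universe)
        assert res.odds_ratio == pytest.approx(3.58, abs=0.02)
        assert res.p_value == pytest.approx(5.7e-7, rel=0.05)

    def test_signature_fully_inside_targets(self):
        universe = {f"g{i}" for i in range(40)}
        targets = {f"g{i}" for i in range(10)}
        signature = {f"g{i}" for i in range(5)}
        res = signature_enrichment(signature, targets, universe)
        assert res.odds_ratio == math.inf
        assert 0 < res.p_value < 1

    def test_random_signature_calibration(self, rng):
        universe = [f"g{i}" for i in range(400)]
        targets = set(universe[:100])
        n_sig = 0
        for _ in range(200):
            signature = set(rng.choice(universe, size=30, replace=False))
            if signature_enrichment(signature, targets, set(universe)).p_value < 0.05:
                n_sig += 1
        assert n_sig <= 0.12 * 200  # ~5% nominal, margin for discreteness


class TestDifferentialExpression:
    def cols(self, nt, nn):
        return [f"T{i}" for i in range(nt)] + [f"N{i}" for i in range(nn)]

    def labels(self, nt, nn):
        return pd.Series(["tumor"] * nt + ["normal"] * nn, index=self.cols(nt, nn))

    def test_identical_distribution_not_significant(self, rng):
        expr = pd.DataFrame([rng.normal(size=60)], index=["g"], columns=self.cols(30, 30))
        df = differential_expression(expr, self.labels(30, 30))
        assert not df.loc["g", "significant"]

    def test_two_fold_shift_detected(self, rng):
        n_hits = 0
        for _ in range(20):
            t = rng.normal(9.0, 0.25, size=30)
            n = rng.normal(8.0, 0.25, size=30)
            expr = pd.DataFrame([np.concatenate([t, n])], index=["g"], columns=self.cols(30, 30))
            df = differential_expression(expr, self.labels(30, 30))
            n_hits += bool(df.loc["g", "significant"]) and df.loc["g", "direction"] == "up"
        assert n_hits >= 19

    def test_constant_gene_p_one(self):
        expr = pd.DataFrame([np.ones(20)], index=["g"], columns=self.cols(10, 10))
        df = differential_expression(expr, self.labels(10, 10))
        assert df.loc["g", "p"] == 1.0

    def test_permuted_labels_calibrated(self, rng):
        """Label permutation: significant fraction at alpha stays near alpha."""
        expr = pd.DataFrame(
            rng.normal(size=(200, 60)), index=[f"g{i}" for i in range(200)],
            columns=self.cols(30, 30),
        )
        df = differential_expression(expr, self.labels(30, 30))
        assert (df["p"] < 0.05).mean() <= 0.10

    def test_too_few_samples(self, rng):
        expr = pd.DataFrame([np.ones(4)], index=["g"], columns=self.cols(2, 2))
        with pytest.raises(InputError):
            differential_expression(expr, self.labels(2, 2))


class TestSampleOverlap:
    def test_venn_partition_arithmetic(self):
        deleted = {f"s{i}" for i in range(88)}
        meth = {f"s{i}" for i in range(82, 82 + 67)}  # 6 shared
        res = sample_overlap(deleted, meth)
        assert res == {"n_del_only": 82, "n_meth_only": 61, "n_both": 6, "n_union": 149}

    def test_disjoint_and_identical(self):
        assert sample_overlap({"a"}, {"b"})["n_both"] == 0
        res = sample_overlap({"a", "b"}, {"a", "b"})
        assert (res["n_del_only"], res["n_meth_only"], res["n_both"]) == (0, 0, 2)


class TestTfMethylationCorrelation:
    def test_monotone_decreasing_beta(self):
        samples = [f"s{i}" for i in range(12)]
        expr = pd.Series(np.arange(12.0), index=samples)
        beta = pd.DataFrame([np.linspace(0.9, 0.1, 12)], index=["cg"], columns=samples)
        res = tf_methylation_correlation(expr, beta)
        assert res["rho"] == pytest.approx(-1.0)

    def test_single_probe_mean_is_itself(self):
        samples = [f"s{i}" for i in range(12)]
        expr = pd.Series(np.arange(12.0), index=samples)
        row = np.linspace(0.1, 0.9, 12)
        beta = pd.DataFrame([row], index=["cg"], columns=samples)
        res = tf_methylation_correlation(expr, beta)
        assert res["rho"] == pytest.approx(1.0)

    def test_constant_vector_flagged(self):
        samples = [f"s{i}" for i in range(12)]
        expr = pd.Series(np.ones(12), index=samples)
        beta = pd.DataFrame([np.linspace(0, 1, 12)], index=["cg"], columns=samples)
        assert tf_methylation_correlation(expr, beta)["undefined"]

    def test_too_few_samples(self):
        samples = [f"s{i}" for i in range(5)]
        expr = pd.Series(np.arange(5.0), index=samples)
        beta = pd.DataFrame([np.arange(5.0) / 5], index=["cg"], columns=samples)
        with pytest.raises(InputError):
            tf_methylation_correlation(expr, beta)


def hits_frame(rows):
    return pd.DataFrame(rows, columns=["element_id", "class", "gene", "q", "significant"])


class TestAlterationTableAndReport:
    def test_flags_from_significant_hits_only(self):
        snv = hits_frame([("e1", "CDS", "gA", 0.01, True), ("e2", "promoter", "gB", 0.2, False)])
        sv = hits_frame([("e3", "CDS", "gA", 0.005, True)])
        dm = [("gA", "hyper", "promoter", 0.001)]
        net = network_with_degrees({"gA": 5}, hubs={"gA"})
        records = build_alteration_table(snv, sv, dm, net)
        assert set(records) == {"gA"}
        r = records["gA"]
        assert set(r.flags) == {("SNV", "CDS"), ("SV", "CDS"), ("hyper-meth", "promoter")}
        assert r.is_tf and r.is_hub and r.best_q == pytest.approx(0.001)

    def test_empty_inputs_empty_table(self):
        assert build_alteration_table(None, None, None, network_with_degrees({})) == {}

    def test_report_ranks_hub_and_excludes_non_hub(self):
        sv = hits_frame(
            [("e1", "CDS", "hubTF", 0.001, True), ("e2", "CDS", "plainTF", 0.0001, True)]
        )
        net = network_with_degrees({"hubTF": 50, "plainTF": 2}, hubs={"hubTF"})
        records = build_alteration_table(None, sv, None, net)
        report = driver_report(records, {}, net)
        assert list(report.candidates["gene"]) == ["hubTF"]
        assert set(report.evidence["gene"]) == {"hubTF", "plainTF"}

    def test_report_is_deterministic(self):
        sv = hits_frame([("e1", "CDS", "a", 0.001, True), ("e2", "CDS", "b", 0.001, True)])
        net = network_with_degrees({"a": 5, "b": 9}, hubs={"a", "b"})
        records = build_alteration_table(None, sv, None, net)
        r1 = driver_report(records, {}, net)
        r2 = driver_report(records, {}, net)
        assert r1.to_json() == r2.to_json()
        # tie on q -> higher out-degree first
        assert list(r1.candidates["gene"]) == ["b", "a"]

    def test_empty_candidates_valid_report(self):
        net = network_with_degrees({"a": 1})
        report = driver_report({}, {}, net)
        assert len(report.candidates) == 0 and report.to_json()
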