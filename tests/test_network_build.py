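import numpy as np
import pytest

from regnetdriver.genome_io import GeneModel, GenomicInterval, InputError
from regnetdriver.network_build import (
    BindingCall,
    RegulatoryElement,
    RegulatoryNetwork,
    assemble_network,
    classify_enhancers,
    activate_by_dhs,
    define_promoters,
    evaluate_against_chip,
    filter_binding,
    link_enhancers_to_genes,
    pwm_scan,
    select_hubs,
)


def gene(gid, chrom, start, end, strand="+", is_tf=False):
    return GeneModel(gid, gid, GenomicInterval(chrom, start, end, strand), is_tf)


class TestDefinePromoters:
    def test_plus_strand_upstream_window(self):
        [p] = define_promoters([gene("g", "chr1", 10_000, 12_000, "+")])
        assert (p.interval.start, p.interval.end) == (7_500, 10_000)
        assert p.linked_genes == [("g", "promoter")]

    def test_minus_strand_clipped_at_chrom_end(self):
        [p] = define_promoters(
            [gene("g", "chr1", 8_000, 10_001, "-")], chrom_lengths={"chr1": 11_000}
        )
        # TSS at 10,000; upstream extends right, clipped at 11,000
        assert (p.interval.start, p.interval.end) == (10_001, 11_000)

    def test_clipped_at_chrom_start(self):
        [p] = define_promoters([gene("g", "chr1", 1_000, 3_000, "+")])
        assert (p.interval.start, p.interval.end) == (0, 1_000)

    def test_tss_beyond_chromosome_is_error(self):
        with pytest.raises(InputError):
            define_promoters(
                [gene("g", "chr1", 20_000, 21_000, "+")], chrom_lengths={"chr1": 15_000}
            )


class TestClassifyEnhancers:
    @pytest.mark.parametrize("gap,kept", [(999, False), (1000, True)])
    def test_gene_distance_boundary_is_inclusive(self, gap, kept):
        g = gene("g", "chr1", 0, 10_000)
        cand = GenomicInterval("chr1", 10_000 + gap, 10_000 + gap + 500)
        result = classify_enhancers([cand], [g])
        assert bool(result) is kept

    def test_overlapping_candidate_rejected(self):
        g = gene("g", "chr1", 0, 10_000)
        assert not classify_enhancers([GenomicInterval("chr1", 5_000, 5_500)], [g])


class TestActivateByDhs:
    def test_overlap_filter_and_uniqueness(self):
        els = [
            RegulatoryElement("e1", GenomicInterval("chr1", 0, 100), "enhancer"),
            RegulatoryElement("e2", GenomicInterval("chr1", 1_000, 1_100), "enhancer"),
        ]
        dhs = [GenomicInterval("chr1", 10, 20), GenomicInterval("chr1", 50, 60)]
        active = activate_by_dhs(els, dhs)
        assert [e.element_id for e in active] == ["e1"]  # e1 once despite two peaks

    def test_empty_dhs_gives_empty_output(self):
        els = [RegulatoryElement("e1", GenomicInterval("chr1", 0, 100), "enhancer")]
        assert activate_by_dhs(els, []) == []


class TestLinkEnhancers:
    def test_identical_signal_links_and_distance_excludes(self):
        import pandas as pd

        enh = RegulatoryElement("e1", GenomicInterval("chr1", 100_000, 101_000), "enhancer")
        near = gene("near", "chr1", 200_000, 210_000)
        far = gene("far", "chr1", 1_200_000, 1_210_000)  # 1.1 Mb away
        sig = np.arange(10.0)
        act = pd.DataFrame([sig], index=["e1"], columns=[f"c{i}" for i in range(10)])
        expr = pd.DataFrame(
            [sig, sig], index=["near", "far"], columns=[f"c{i}" for i in range(10)]
        )
        [linked] = link_enhancers_to_genes([enh], [near, far], act, expr)
        assert linked.linked_genes == [("near", "correlation")]

    def test_too_few_conditions_rejected(self):
        import pandas as pd

        enh = RegulatoryElement("e1", GenomicInterval("chr1", 0, 100), "enhancer")
        act = pd.DataFrame([[1, 2]], index=["e1"], columns=["a", "b"])
        expr = pd.DataFrame([[1, 2]], index=["g"], columns=["a", "b"])
        with pytest.raises(InputError):
            link_enhancers_to_genes([enh], [], act, expr)

    def test_permuted_signal_rarely_links(self, rng):
        """Calibration: an unrelated activity vector links at ~alpha rate."""
        import pandas as pd

        enh = RegulatoryElement("e1", GenomicInterval("chr1", 100_000, 101_000), "enhancer")
        g = gene("g", "chr1", 200_000, 210_000)
        cols = [f"c{i}" for i in range(20)]
        n_linked = 0
        for _ in range(200):
            act = pd.DataFrame([rng.normal(size=20)], index=["e1"], columns=cols)
            expr = pd.DataFrame([rng.normal(size=20)], index=["g"], columns=cols)
            [res] = link_enhancers_to_genes([enh], [g], act, expr, alpha=0.05)
            n_linked += bool(res.linked_genes)
        assert n_linked <= 0.1 * 200


class TestFilterBinding:
    def test_inclusive_threshold(self):
        calls = [BindingCall("tf", "e1", 0.70), BindingCall("tf", "e2", 0.699)]
        kept = filter_binding(calls)
        assert [(c.tf_id, c.element_id) for c in kept] == [("tf", "e1")]

    def test_duplicates_collapse_to_max(self):
        calls = [BindingCall("tf", "e1", 0.5), BindingCall("tf", "e1", 0.9)]
        [kept] = filter_binding(calls)
        assert kept.probability == 0.9


def simple_elements(spec):
    """spec: {element_id: (kind, [genes])} at arbitrary coordinates."""
    out = []
    for i, (eid, (kind, genes)) in enumerate(spec.items()):
        out.append(
            RegulatoryElement(
                eid,
                GenomicInterval("chr1", 1000 * (i + 1), 1000 * (i + 1) + 100),
                kind,
                [(g, "test") for g in genes],
            )
        )
    return out


class TestAssembleNetwork:
    def test_single_edge_chain(self):
        els = simple_elements({"p1": ("promoter", ["G"])})
        net = assemble_network([BindingCall("tf", "p1", 0.9)], els)
        assert net.tf_targets == {"tf": {"G": 0.9}}
        assert net.out_degree("tf") == 1

    def test_two_elements_one_gene_unique_edge(self):
        els = simple_elements({"e1": ("enhancer", ["G"]), "e2": ("enhancer", ["G"])})
        net = assemble_network(
            [BindingCall("tf", "e1", 0.8), BindingCall("tf", "e2", 0.95)], els
        )
        assert net.out_degree("tf") == 1
        assert net.tf_targets["tf"]["G"] == 0.95  # max supporting probability

    def test_cross_product_count(self):
        els = simple_elements({"e1": ("enhancer", ["g1", "g2", "g3"])})
        net = assemble_network(
            [BindingCall("a", "e1", 0.9), BindingCall("b", "e1", 0.9)], els
        )
        assert net.n_tf_gene_edges() == 6

    def test_dangling_element_is_error(self):
        with pytest.raises(InputError):
            assemble_network([BindingCall("tf", "ghost", 0.9)], [])

    def test_agrees_with_brute_force_triple_loop(self, rng):
        genes = [f"g{i}" for i in range(12)]
        els = []
        for i in range(8):
            linked = list(rng.choice(genes, size=rng.integers(1, 4), replace=False))
            els.append(
                RegulatoryElement(
                    f"e{i}",
                    GenomicInterval("chr1", 1000 * (i + 1), 1000 * (i + 1) + 50),
                    "enhancer",
                    [(g, "t") for g in linked],
                )
            )
        calls = [
            BindingCall(f"tf{t}", f"e{int(e)}", float(p))
            for t, e, p in zip(
                rng.integers(0, 4, 30), rng.integers(0, 8, 30), rng.random(30)
            )
        ]
        net = assemble_network(calls, els)
        # oracle: explicit loop over calls x element links
        expected: dict[str, set[str]] = {}
        for c in calls:
            for el in els:
                if el.element_id == c.element_id:
                    for g, _ in el.linked_genes:
                        expected.setdefault(c.tf_id, set()).add(g)
        assert {tf: set(t) for tf, t in net.tf_targets.items()} == expected

    def test_removing_element_never_increases_out_degree(self, rng):
        els = simple_elements(
            {f"e{i}": ("enhancer", [f"g{j}" for j in rng.integers(0, 5, 2)]) for i in range(5)}
        )
        calls = [BindingCall("tf", f"e{i}", 0.9) for i in range(5)]
        full = assemble_network(calls, els)
        for drop in range(5):
            reduced = assemble_network(
                [c for c in calls if c.element_id != f"e{drop}"],
                [e for e in els if e.element_id != f"e{drop}"],
            )
            assert reduced.out_degree("tf") <= full.out_degree("tf")


def network_with_degrees(degrees: dict[str, int]) -> RegulatoryNetwork:
    tf_targets = {
        tf: {f"g{i}": 1.0 for i in range(d)} for tf, d in degrees.items()
    }
    return RegulatoryNetwork(tf_element={}, element_genes={}, tf_targets=tf_targets)


class TestSelectHubs:
    def test_paper_scale_hub_count(self):
        net = network_with_degrees({f"tf{i:03d}": i + 1 for i in range(612)})
        assert len(select_hubs(net)) == 153

    def test_top_degree_wins(self):
        net = network_with_degrees({"a": 10, "b": 5, "c": 2, "d": 1})
        assert select_hubs(net) == {"a"}

    def test_ties_broken_lexicographically(self):
        net = network_with_degrees({f"tf{i}": 3 for i in range(8)})
        assert select_hubs(net) == {"tf0", "tf1"}

    @pytest.mark.parametrize("n_tf,frac,expected", [(612, 0.25, 153), (20, 0.25, 5), (7, 0.5, 3)])
    def test_floor_rule(self, n_tf, frac, expected):
        net = network_with_degrees({f"t{i:03d}": i + 1 for i in range(n_tf)})
        assert len(select_hubs(net, frac)) == expected


class TestEvaluateAgainstChip:
    def make_universe(self):
        els = []
        for i in range(10):
            els.append(
                RegulatoryElement(
                    f"e{i}",
                    GenomicInterval("chr1", 10_000 * i + 1000, 10_000 * i + 1100),
                    "promoter",
                    [(f"g{i}", "t")],
                )
            )
        return els

    def test_perfect_prediction(self):
        els = self.make_universe()
        peaks = [els[i].interval for i in range(4)]
        net = assemble_network([BindingCall("tf", f"e{i}", 0.9) for i in range(4)], els)
        m = evaluate_against_chip(net, "tf", peaks, els)
        assert (m.sensitivity, m.specificity, m.precision, m.f_score) == (1, 1, 1, 1)

    def test_confusion_matrix_arithmetic(self):
        els = self.make_universe()
        peaks = [els[i].interval for i in range(4)]  # gold = g0..g3
        predicted = [0, 1, 4]  # TP g0,g1; FP g4; FN g2,g3; TN g5..g9
        net = assemble_network([BindingCall("tf", f"e{i}", 0.9) for i in predicted], els)
        m = evaluate_against_chip(net, "tf", peaks, els)
        assert (m.tp, m.fp, m.fn, m.tn) == (2, 1, 2, 5)
        assert m.sensitivity == pytest.approx(0.5)
        assert m.specificity == pytest.approx(5 / 6)
        assert m.precision == pytest.approx(2 / 3)
        assert m.f_score == pytest.approx(4 / 7)
        # identities from the definitions
        assert m.sensitivity + m.fn / (m.tp + m.fn) == pytest.approx(1.0)
        assert m.precision * (m.tp + m.fp) == pytest.approx(m.tp)

    def test_empty_gold_standard_is_error(self):
        els = self.make_universe()
        net = assemble_network([BindingCall("tf", "e0", 0.9)], els)
        with pytest.raises(InputError):
            evaluate_against_chip(net, "tf", [GenomicInterval("chr2", 0, 10)], els)

    def test_random_scores_auroc_near_half(self, rng):
        els = []
        for i in range(1000):
            els.append(
                RegulatoryElement(
                    f"e{i}",
                    GenomicInterval("chr1", 2_000 * i + 100, 2_000 * i + 200),
                    "promoter",
                    [(f"g{i}", "t")],
                )
            )
        gold_idx = rng.choice(1000, size=300, replace=False)
        peaks = [els[i].interval for i in gold_idx]
        calls = [BindingCall("tf", f"e{i}", float(rng.random())) for i in range(1000)]
        net = assemble_network(calls, els)
        m = evaluate_against_chip(net, "tf", peaks, els)
        assert 0.45 <= m.auroc <= 0.55


class TestPwmScan:
    CONSENSUS = "ACGTACGTAC"

    def make_pwm(self):
        base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        pwm = np.full((len(self.CONSENSUS), 4), 0.01)
        for i, b in enumerate(self.CONSENSUS):
            pwm[i, base_idx[b]] = 0.97
        return pwm

    def test_consensus_hit_above_threshold(self):
        calls = pwm_scan(
            {"s": "TTTT" + self.CONSENSUS + "GGGG"}, {"tf": self.make_pwm()}, 5.0
        )
        assert calls[0].probability > 0.7

    def test_reverse_complement_symmetry(self):
        rc = self.CONSENSUS.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        fwd = pwm_scan({"s": self.CONSENSUS}, {"tf": self.make_pwm()}, 5.0)
        rev = pwm_scan({"s": rc}, {"tf": self.make_pwm()}, 5.0)
        assert fwd[0].probability == pytest.approx(rev[0].probability)

    def test_scrambled_sequences_rarely_call(self, rng):
        pwm = self.make_pwm()
        n_called = 0
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), size=40))
            [call] = pwm_scan({"s": seq}, {"tf": pwm}, 5.0)
            n_called += call.probability >= 0.7
        assert n_called <= 2

    def test_unnormalized_pwm_rejected(self):
        with pytest.raises(InputError):
            pwm_scan({"s": "ACGT"}, {"tf": np.ones((4, 4))}, 0.0)
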