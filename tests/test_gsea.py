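import numpy as np
import pytest

import isletkit as ik
from isletkit.gsea import GeneSet, RankedList, results_frame
from tests.conftest import make_de_frame


def simple_de(fcs):
    rows = [("m", g, fc, 0.01, 0.05, True) for g, fc in fcs.items()]
    return make_de_frame(rows)


class TestRankGenes:
    def test_absolute_mode_with_lexicographic_tie(self):
        ranked = ik.rank_genes(simple_de({"A": 4.0, "B": 0.25, "C": 1.1}), mode="absolute")
        assert ranked.genes == ("A", "B", "C")  # |log2FC| = 2, 2, 0.14; A before B

    def test_signed_mode(self):
        ranked = ik.rank_genes(simple_de({"A": 4.0, "B": 0.25, "C": 1.1}), mode="signed")
        assert ranked.genes == ("A", "C", "B")

    def test_single_gene(self):
        for mode in ("absolute", "signed"):
            assert ik.rank_genes(simple_de({"Z": 2.0}), mode=mode).genes == ("Z",)

    def test_absent_and_filtered_excluded(self):
        de = make_de_frame(
            [
                ("m", "A", 4.0, 0.01, 0.05, True),
                ("m", "B", np.nan, None, None, False),  # absent
            ]
        )
        de.loc[2] = de.loc[0]
        de.loc[2, ["gene", "tested"]] = ["C", False]  # low-expressed
        assert ik.rank_genes(de).genes == ("A",)

    def test_empty_raises(self):
        de = make_de_frame([("m", "B", np.nan, None, None, False)])
        with pytest.raises(ValueError):
            ik.rank_genes(de)


class TestEnrichmentScore:
    def test_all_hits_on_top_gives_one(self):
        rl = RankedList(
            genes=tuple("ABCDEFGHIJ"), metric=np.arange(10, 0, -1.0), mode="signed"
        )
        es, run = ik.enrichment_score(rl, GeneSet("top", "", ("A", "B")), weight=0.0)
        assert es == pytest.approx(1.0)
        assert np.argmax(run) == 1

    def test_bottom_gene_hand_computed(self):
        rl = RankedList(genes=tuple("ABCD"), metric=np.array([3.0, 2.0, 1.0, 0.5]), mode="signed")
        es, run = ik.enrichment_score(rl, GeneSet("bot", "", ("D",)), weight=0.0)
        assert es == pytest.approx(-1.0)
        np.testing.assert_allclose(run, [-1 / 3, -2 / 3, -1.0, 0.0])

    def test_es_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            N = int(rng.integers(4, 40))
            metric = np.sort(rng.normal(0, 2, N))[::-1]
            genes = tuple(f"g{i}" for i in range(N))
            rl = RankedList(genes=genes, metric=metric, mode="signed")
            k = int(rng.integers(1, N))
            members = tuple(rng.choice(genes, k, replace=False))
            for w in (0.0, 1.0):
                es, _ = ik.enrichment_score(rl, GeneSet("s", "", members), weight=w)
                assert -1.0 - 1e-12 <= es <= 1.0 + 1e-12

    def test_weight_zero_invariant_to_monotone_metric_transform(self):
        rng = np.random.default_rng(5)
        N = 30
        metric = np.sort(rng.uniform(0.1, 5, N))[::-1]
        genes = tuple(f"g{i}" for i in range(N))
        members = tuple(rng.choice(genes, 6, replace=False))
        rl1 = RankedList(genes=genes, metric=metric, mode="signed")
        rl2 = RankedList(genes=genes, metric=np.log(metric + 1), mode="signed")
        es1, _ = ik.enrichment_score(rl1, GeneSet("s", "", members), weight=0.0)
        es2, _ = ik.enrichment_score(rl2, GeneSet("s", "", members), weight=0.0)
        assert es1 == pytest.approx(es2)

    def test_empty_overlap_names_set(self):
        rl = RankedList(genes=("A", "B"), metric=np.array([1.0, 0.5]), mode="signed")
        with pytest.raises(ValueError, match="myset"):
            ik.enrichment_score(rl, GeneSet("myset", "", ("Z",)))


class TestPermutationP:
    def _ranked(self, N=60, seed=2):
        rng = np.random.default_rng(seed)
        metric = np.sort(rng.normal(0, 1, N))[::-1]
        return RankedList(
            genes=tuple(f"g{i}" for i in range(N)), metric=metric, mode="signed"
        ), rng

    def test_addone_floor(self):
        # observed ES above every null ES at B=99 gives exactly 1/100
        rl, _ = self._ranked()
        top = GeneSet("top", "", tuple(rl.genes[:5]))
        p, es, null = ik.permutation_p(rl, top, B=99, seed=0)
        assert es > max(null)
        assert p == pytest.approx(0.01)

    def test_same_seed_reproducible(self):
        rl, rng = self._ranked()
        gs = GeneSet("s", "", tuple(rng.choice(rl.genes, 8, replace=False)))
        p1, _, _ = ik.permutation_p(rl, gs, B=200, seed=42)
        p2, _, _ = ik.permutation_p(rl, gs, B=200, seed=42)
        assert p1 == p2

    def test_p_decreases_with_effect_size(self):
        # stochastically smaller p as the set concentrates at the top
        rl, _ = self._ranked(N=100, seed=3)
        weak = GeneSet("w", "", tuple(rl.genes[i] for i in (5, 20, 40, 60, 80)))
        strong = GeneSet("s", "", tuple(rl.genes[:5]))
        pw, _, _ = ik.permutation_p(rl, weak, B=500, seed=1)
        ps, _, _ = ik.permutation_p(rl, strong, B=500, seed=1)
        assert ps <= pw

    def test_invalid_B_raises(self):
        rl, _ = self._ranked()
        with pytest.raises(ValueError):
            ik.permutation_p(rl, GeneSet("s", "", (rl.genes[0],)), B=0)


class TestGseaSuite:
    def test_skipped_and_significance_calls(self, preset_de, preset_study):
        _, truth = preset_study
        de = preset_de["Ins1LKB1KO"]
        sets = [
            GeneSet("neuronal", "", tuple(truth.group_members("neuronal"))),
            GeneSet("nowhere", "", ("not_a_gene_1", "not_a_gene_2")),
        ]
        res = ik.gsea_suite(de, sets, B=200, seed=0)
        by_name = {r.set_name: r for r in res}
        assert by_name["nowhere"].skipped
        assert np.isnan(by_name["nowhere"].p)
        r = by_name["neuronal"]
        assert r.significant == (r.fdr <= 0.30)
        assert r.p >= 1.0 / 201.0

    def test_no_testable_set_raises(self, preset_de):
        with pytest.raises(ValueError):
            ik.gsea_suite(preset_de["Ins1LKB1KO"], [GeneSet("x", "", ("zzz",))], B=10)

    def test_results_frame_shape(self, preset_de, preset_study):
        _, truth = preset_study
        sets = [GeneSet("neuronal", "", tuple(truth.group_members("neuronal")))]
        res = ik.gsea_suite(preset_de["Ins1LKB1KO"], sets, B=100, seed=1)
        df = results_frame(res)
        assert list(df.columns) == [
            "set", "size", "es", "p", "fdr", "significant", "tail", "skipped",
        ]
        assert len(df) == 1
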