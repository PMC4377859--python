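import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

import isletkit as ik


class TestSimulateCounts:
    def test_same_seed_bit_identical(self):
        cfg = ik.default_config(seed=11, n_genes=300)
        s1, t1 = ik.simulate_counts(cfg)
        s2, t2 = ik.simulate_counts(cfg)
        for m in s1.model_names:
            pd.testing.assert_frame_equal(s1[m].counts, s2[m].counts)
        pd.testing.assert_frame_equal(t1.fold_changes, t2.fold_changes)

    def test_library_size_conservation(self):
        cfg = ik.default_config(seed=2, n_genes=500)
        study, _ = ik.simulate_counts(cfg)
        for m in study.model_names:
            totals = study[m].counts.sum(axis=0)
            np.testing.assert_array_equal(totals.to_numpy(), study[m].totals.to_numpy())
            # the realized total fluctuates with the dominant genes' replicate
            # noise (long-tailed baseline), but stays near the target depth
            assert (np.abs(totals / cfg.library_size - 1.0) < 0.30).all()

    def test_no_effect_proportions_ratio_near_one(self):
        # dispersion 0, no planting: pooled KO/WT ratios concentrate at 1
        cfg = ik.default_config(
            seed=1,
            n_genes=1000,
            dispersion=0.0,
            absence_rate=0.0,
            planted_groups=(),
            models=(ik.ModelSpec("m", "LKB1"),),
        )
        study, _ = ik.simulate_counts(cfg)
        cm = study["m"]
        ko = cm.counts[cm.condition_columns("KO")].sum(axis=1)
        wt = cm.counts[cm.condition_columns("WT")].sum(axis=1)
        keep = (ko + wt) >= 50
        ratio = np.log2((ko[keep] + 0.5) / (wt[keep] + 0.5))
        assert np.median(np.abs(ratio)) < 0.1

    def test_planted_effect_restricted_to_affected_kinase(self, preset_study):
        study, truth = preset_study
        members = truth.group_members("neuronal")
        cm = study["Ins1AMPKdKO"]  # LKB1-only group: no effect here
        ko = cm.counts.loc[members, cm.condition_columns("KO")].sum(axis=1)
        wt = cm.counts.loc[members, cm.condition_columns("WT")].sum(axis=1)
        ratio = (ko.sum() + 1) / (wt.sum() + 1)
        assert 0.8 < ratio < 1.25
        assert (truth.fold_changes.loc[members, "Ins1AMPKdKO"] == 1.0).all()

    def test_absent_genes_all_zero_and_flagged(self, preset_study):
        study, truth = preset_study
        for m in study.model_names:
            ab = truth.absent[m]
            assert (study[m].counts.loc[ab].to_numpy() == 0).all()
            pd.testing.assert_series_equal(
                study[m].absent, ab, check_names=False
            )

    def test_unplanted_truth_is_fold_one(self, preset_study):
        _, truth = preset_study
        unplanted = truth.groups == ""
        assert (truth.fold_changes.loc[unplanted] == 1.0).all().all()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_genes": 0},
            {"library_size": 0},
            {"dispersion": -0.1},
            {"absence_rate": 1.0},
            {"planted_groups": (ik.PlantedGroup("g", 5000, 2.0, ("LKB1",)),)},
        ],
    )
    def test_invalid_config_raises(self, kwargs):
        with pytest.raises(ValueError):
            ik.default_config(seed=0, **kwargs)

    def test_nonpositive_fold_effect_raises(self):
        with pytest.raises(ValueError):
            ik.PlantedGroup("g", 5, 0.0, ("LKB1",))


class TestSimulateGeneSets:
    def test_planted_set_copies_membership(self, preset_study):
        _, truth = preset_study
        sets = {s.name: s for s in ik.simulate_gene_sets(truth, seed=3)}
        assert len(sets["disallowed"]) == 16
        assert set(sets["disallowed"].members) == set(truth.group_members("disallowed"))

    def test_fixed_size_range(self, preset_study):
        _, truth = preset_study
        sets = ik.simulate_gene_sets(truth, n_null_sets=10, set_size_range=(5, 5), seed=0)
        assert all(len(s) == 5 for s in sets if s.name.startswith("null_"))

    def test_null_sets_not_enriched_for_planted_genes(self, preset_study):
        # overlap with planted genes stays within hypergeometric expectation
        _, truth = preset_study
        sets = ik.simulate_gene_sets(truth, n_null_sets=100, seed=5)
        planted = set(truth.groups.index[truth.groups != ""])
        G = len(truth.genes)
        pvals = []
        for s in sets:
            if not s.name.startswith("null_"):
                continue
            k = len(planted.intersection(s.members))
            pvals.append(hypergeom.sf(k - 1, G, len(planted), len(s)))
        assert (np.array(pvals) < 0.001).sum() <= 2

    def test_oversized_sets_raise(self, preset_study):
        _, truth = preset_study
        with pytest.raises(ValueError):
            ik.simulate_gene_sets(truth, set_size_range=(10, len(truth.genes) + 1))


class TestSimulateAtlas:
    def test_noise_off_perfect_recovery(self, preset_study):
        _, truth = preset_study
        atlas = ik.simulate_atlas(truth, enrichment_factor=10.0, noise_sd=0.0, seed=4)
        genes = list(truth.genes[:200])
        hits = sum(
            ik.classify_tissue(atlas, g, factor=5.0) == atlas.home_class[g] for g in genes
        )
        assert hits == len(genes)

    def test_noisy_recovery_rate(self, preset_study):
        _, truth = preset_study
        atlas = ik.simulate_atlas(truth, enrichment_factor=10.0, noise_sd=0.5, seed=1)
        genes = list(truth.genes[:1000])
        hits = sum(
            ik.classify_tissue(atlas, g, factor=5.0) == atlas.home_class[g] for g in genes
        )
        assert hits / len(genes) >= 0.95

    def test_planted_groups_map_to_matching_class(self, preset_study):
        _, truth = preset_study
        atlas = ik.simulate_atlas(truth, seed=0)
        assert (atlas.home_class[truth.group_members("neuronal")] == "neuronal").all()
        assert (
            atlas.home_class[truth.group_members("hepatic")] == "hepatic_intestinal"
        ).all()

    def test_single_class_raises(self, preset_study):
        _, truth = preset_study
        with pytest.raises(ValueError):
            ik.simulate_atlas(truth, tissue_classes=[("neuronal", ("cortex",))])

    def test_factor_at_most_one_raises(self, preset_study):
        _, truth = preset_study
        with pytest.raises(ValueError):
            ik.simulate_atlas(truth, enrichment_factor=1.0)


class TestSimulatePromoterHits:
    def test_planted_tf_ranks_first(self):
        hits = ik.simulate_promoter_hits(
            n_tfs=100, n_submitted=2000, genome_promoters=50_000,
            planted=[("Zfp206", 5.0)], seed=1,
        )
        ranked = ik.tfbs_enrichment(hits)
        assert ranked.iloc[0]["tf"] == "Zfp206"

    def test_submitted_exceeding_genome_raises(self):
        with pytest.raises(ValueError):
            ik.simulate_promoter_hits(10, 200, 100, seed=0)

    def test_nonpositive_multiplier_raises(self):
        with pytest.raises(ValueError):
            ik.simulate_promoter_hits(10, 50, 100, planted=[("x", 0.0)], seed=0)
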