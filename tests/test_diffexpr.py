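import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar
from scipy.stats import binom, chi2

import isletkit as ik
from isletkit.quantify import CountMatrix


def binomial_lrt_oracle(ko, ko_n, wt, wt_n):
    """Independent brute-force binomial LRT: numeric likelihood maximization."""

    def nll(counts, totals):
        def f(pi):
            return -binom.logpmf(counts, totals, pi).sum()

        res = minimize_scalar(f, bounds=(1e-12, 1 - 1e-12), method="bounded",
                              options={"xatol": 1e-14})
        return -res.fun

    l1 = nll(np.asarray(ko), np.asarray(ko_n)) + nll(np.asarray(wt), np.asarray(wt_n))
    l0 = nll(np.concatenate([ko, wt]), np.concatenate([ko_n, wt_n]))
    return float(chi2.sf(max(2 * (l1 - l0), 0.0), 1))


class TestBetabinTest:
    def test_identical_data_gives_p_one(self):
        assert ik.betabin_test([50, 50], [10**4] * 2, [50, 50], [10**4] * 2, 0.0) == 1.0

    def test_phi_zero_matches_binomial_oracle(self):
        p = ik.betabin_test([90], [1000], [30], [1000], 0.0)
        assert p == pytest.approx(binomial_lrt_oracle([90], [1000], [30], [1000]), abs=1e-6)

    def test_replicated_phi_zero_matches_oracle(self):
        ko, wt = [12, 19, 7], [30, 28, 35]
        n = [500, 520, 480]
        p = ik.betabin_test(ko, n, wt, n, 0.0)
        assert p == pytest.approx(binomial_lrt_oracle(ko, n, wt, n), abs=1e-6)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            ik.betabin_test([5], [3], [1], [10], 0.0)  # count > total
        with pytest.raises(ValueError):
            ik.betabin_test([0], [0], [0], [0], 0.0)  # all-zero totals
        with pytest.raises(ValueError):
            ik.betabin_test([1], [10], [1], [10], 1.0)  # phi out of range

    def test_dispersion_widens_p(self):
        # the same count difference is less surprising under more dispersion
        p0 = ik.betabin_test([80], [1000], [50], [1000], 0.0)
        p1 = ik.betabin_test([80], [1000], [50], [1000], 0.05)
        assert p1 > p0


class TestBhAdjust:
    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(
            ik.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_value(self):
        np.testing.assert_allclose(ik.bh_adjust([1.0]), [1.0])

    def test_e_at_least_p_and_monotone(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, 50)
        e = ik.bh_adjust(p)
        assert (e >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(e[order]) >= -1e-12).all()

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariance(self, p):
        p = np.asarray(p)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(p))
        np.testing.assert_allclose(ik.bh_adjust(p)[perm], ik.bh_adjust(p[perm]))

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            ik.bh_adjust([0.5, 1.2])


def _simulated_counts(phi, n_genes=2000, depth=10**5, reps=3, seed=1):
    """Two-condition null study at a known squared-CV dispersion."""
    rng = np.random.default_rng(seed)
    base = rng.lognormal(0.0, 2.0, n_genes)
    pi = base / base.sum()
    cols, data, meta = [], [], []
    for cond in ("KO", "WT"):
        for r in range(reps):
            p = pi
            if phi > 0:
                rho = np.clip(phi * pi / (1 - pi), 1e-12, 0.99)
                a, b = pi * (1 - rho) / rho, (1 - pi) * (1 - rho) / rho
                p = rng.beta(a, b)
            cols.append(f"m:{cond}:{r + 1}")
            data.append(rng.binomial(depth, p))
            meta.append(("m", cond, r + 1))
    genes = pd.Index([f"g{i:05d}" for i in range(n_genes)], name="gene")
    counts = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    samples = pd.DataFrame(meta, index=cols, columns=["model", "condition", "replicate"])
    lengths = pd.Series(1500, index=genes, name="length")
    return CountMatrix(counts=counts, samples=samples, lengths=lengths, name="m")


class TestEstimateDispersion:
    def test_binomial_data_estimates_near_zero(self):
        est = ik.estimate_dispersion(_simulated_counts(0.0))
        assert est.phi < 0.005
        assert est.n_genes_used > 100

    def test_recovers_planted_dispersion(self):
        est = ik.estimate_dispersion(_simulated_counts(0.05))
        assert 0.03 <= est.phi <= 0.07

    def test_single_replicate_falls_back_with_warning(self, tiny_counts):
        single = CountMatrix(
            counts=tiny_counts.counts[["m:KO:1", "m:WT:1"]],
            samples=tiny_counts.samples.loc[["m:KO:1", "m:WT:1"]],
            lengths=tiny_counts.lengths,
        )
        with pytest.warns(UserWarning, match="dispersion"):
            est = ik.estimate_dispersion(single)
        assert est.phi == 0.0


class TestDeTable:
    def test_deterministic(self, tiny_counts):
        t1 = ik.de_table(tiny_counts)
        t2 = ik.de_table(tiny_counts)
        pd.testing.assert_frame_equal(t1, t2)

    def test_flags_and_invariants(self, tiny_counts):
        de = ik.de_table(tiny_counts).set_index("gene")
        assert not de.loc["gC", "present"]  # all-zero gene is absent
        assert np.isnan(de.loc["gC", "p"]) and np.isnan(de.loc["gC", "fc"])
        tested = de[de["tested"]]
        assert (tested["e"] >= tested["p"] - 1e-12).all()
        # BH consistency: recomputing step-up from the raw p reproduces E
        np.testing.assert_allclose(
            tested["e"].to_numpy(), ik.bh_adjust(tested["p"].to_numpy())
        )

    def test_missing_condition_raises(self, tiny_counts):
        ko_only = CountMatrix(
            counts=tiny_counts.counts[["m:KO:1", "m:KO:2"]],
            samples=tiny_counts.samples.loc[["m:KO:1", "m:KO:2"]],
            lengths=tiny_counts.lengths,
        )
        with pytest.raises(ValueError, match="KO and WT"):
            ik.de_table(ko_only)

    def test_null_study_controls_fdr(self):
        de = ik.de_table(_simulated_counts(0.05, seed=7), dispersion=0.05)
        frac = (de.loc[de["tested"], "e"] < 0.1).mean()
        assert frac <= 0.10

    def test_planted_fold_change_recovery(self, preset_study):
        # median estimated FC of planted 3-fold genes within 15% of 3
        study, truth = preset_study
        de = ik.de_table(study["Ins1LKB1KO"]).set_index("gene")
        planted = truth.genes[truth.fold_changes["Ins1LKB1KO"] == 3.0]
        med = de.loc[planted, "fc"].median()
        assert abs(med - 3.0) / 3.0 < 0.15
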