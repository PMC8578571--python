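import math

import numpy as np
import pytest

from samnet.sam_de import (SamParams, call_degs, compute_d_scores, estimate_s0,
                           n_distinct_assignments, permutation_null,
                           permutation_p, q_values, sam_analysis)

from conftest import make_design, make_matrix


def naive_r_s(ctrl, expt):
    """Pooled-SE formula computed with plain Python, no vectorisation."""
    n1, n2 = len(ctrl), len(expt)
    m1 = sum(ctrl) / n1
    m2 = sum(expt) / n2
    ss = sum((x - m1) ** 2 for x in ctrl) + sum((x - m2) ** 2 for x in expt)
    s = math.sqrt((1 / n1 + 1 / n2) * ss / (n1 + n2 - 2))
    return m2 - m1, s


class TestDScores:
    def test_hand_computed_example(self):
        # control (1,1,1), experimental (2,2,2), s0 = 0.5: r=1, s=0, d=2
        m = make_matrix([[1, 1, 1, 2, 2, 2]])
        res = compute_d_scores(m, make_design(3, 3), s0=0.5)
        assert res.loc["g0", "r"] == pytest.approx(1.0)
        assert res.loc["g0", "s"] == 0.0
        assert res.loc["g0", "d"] == pytest.approx(2.0)

    def test_identical_group_means_give_zero_d(self):
        m = make_matrix([[1.0, 3.0, 2.0, 2.0, 1.0, 3.0]])
        res = compute_d_scores(m, make_design(3, 3), s0=0.1)
        assert res.loc["g0", "d"] == 0.0

    def test_doubling_s0_halves_d_when_s_zero(self):
        m = make_matrix([[1, 1, 1, 2, 2, 2]])
        d1 = compute_d_scores(m, make_design(3, 3), s0=0.5).loc["g0", "d"]
        d2 = compute_d_scores(m, make_design(3, 3), s0=1.0).loc["g0", "d"]
        assert d1 == pytest.approx(2 * d2)

    def test_zero_variance_with_zero_s0_errors(self):
        m = make_matrix([[1, 1, 1, 2, 2, 2]])
        with pytest.raises(ValueError, match="s0"):
            compute_d_scores(m, make_design(3, 3), s0=0.0)

    def test_matches_naive_formula(self, rng):
        X = rng.normal(8, 0.5, size=(25, 7))
        design = make_design(3, 4)
        res = compute_d_scores(make_matrix(X), design, s0=0.2)
        for i in range(25):
            r, s = naive_r_s(X[i, :3], X[i, 3:])
            assert res["r"].iloc[i] == pytest.approx(r, abs=1e-12)
            assert res["s"].iloc[i] == pytest.approx(s, abs=1e-12)
            assert res["d"].iloc[i] == pytest.approx(r / (s + 0.2), abs=1e-12)


class TestEstimateS0:
    def test_all_equal_returns_that_value(self):
        assert estimate_s0(np.full(50, 3.0), np.ones(50), "percentile") == 3.0
        assert estimate_s0(np.full(50, 3.0), np.ones(50), "cv_minimisation") == 3.0

    def test_percentile_median_of_1_to_100(self):
        s = np.arange(1.0, 101.0)
        assert estimate_s0(s, np.ones(100), "percentile", percentile=50) == 50.5

    def test_cv_minimisation_within_bounds(self, rng):
        s = rng.uniform(0.1, 2.0, size=300)
        r = rng.normal(0, 1, size=300)
        s0 = estimate_s0(s, r, "cv_minimisation")
        assert s.min() <= s0 <= s.max()


class TestPermutationNull:
    def test_2v2_enumerates_6_assignments(self, rng):
        m = make_matrix(rng.normal(size=(10, 4)))
        null = permutation_null(m, make_design(2, 2), SamParams(), s0=0.1)
        assert null.shape == (6, 10)
        assert n_distinct_assignments(2, 2) == 6

    def test_identity_assignment_reproduces_observed_d(self, rng):
        m = make_matrix(rng.normal(size=(10, 4)))
        design = make_design(2, 2)
        obs = compute_d_scores(m, design, s0=0.1)["d"].to_numpy()
        null = permutation_null(m, design, SamParams(), s0=0.1)
        found = any(np.allclose(null[i], obs, atol=1e-12) for i in range(6))
        assert found

    def test_null_symmetric_under_full_enumeration(self, rng):
        # each assignment's complement negates d, so the pooled null is
        # symmetric about 0 for equal group sizes
        m = make_matrix(rng.normal(size=(8, 6)))
        null = permutation_null(m, make_design(3, 3), SamParams(), s0=0.1)
        pooled = np.sort(null.ravel())
        np.testing.assert_allclose(pooled, -pooled[::-1], atol=1e-12)

    def test_sampling_when_enumeration_too_large(self, rng):
        m = make_matrix(rng.normal(size=(5, 12)))
        params = SamParams(n_permutations=100, seed=7)
        null = permutation_null(m, make_design(6, 6), params, s0=0.1)
        assert null.shape == (100, 5)
        null2 = permutation_null(m, make_design(6, 6), params, s0=0.1)
        np.testing.assert_array_equal(null, null2)


class TestPermutationP:
    def test_observed_zero_gives_p_one(self, rng):
        null = rng.normal(size=(10, 20))
        assert permutation_p(0.0, null) == 1.0

    def test_largest_observed_gives_minimal_p(self, rng):
        null = rng.normal(size=(10, 20))
        n = null.size
        assert permutation_p(np.abs(null).max() + 1.0, null) == pytest.approx(1 / (1 + n))

    def test_deterministic_on_frozen_pool(self, rng):
        null = rng.normal(size=(6, 15))
        obs = rng.normal(size=15)
        np.testing.assert_array_equal(permutation_p(obs, null), permutation_p(obs, null))


class TestQValues:
    def brute_force_q(self, d_obs, null_d):
        """Literal min-over-thresholds recomputation with Python loops."""
        obs = np.abs(d_obs)
        null_abs = np.abs(null_d)
        med = float(np.median(null_abs))
        pi0 = min(1.0, 2.0 * float(np.mean(obs <= med)))
        thresholds = sorted(obs)
        fdr_at = {}
        for t in thresholds:
            O = sum(1 for x in obs if x >= t)
            counts = [sum(1 for x in row if x >= t) for row in null_abs]
            F = float(np.median(counts))
            fdr_at[t] = min(1.0, max(0.0, pi0 * F / max(O, 1)))
        q = np.empty_like(obs)
        for i, x in enumerate(obs):
            q[i] = min(fdr_at[t] for t in thresholds if t <= x)
        return q

    def test_matches_brute_force_on_50_genes(self, rng):
        d_obs = rng.normal(0, 2, size=50)
        null_d = rng.normal(0, 1, size=(30, 50))
        np.testing.assert_allclose(q_values(d_obs, null_d),
                                   self.brute_force_q(d_obs, null_d), atol=1e-12)

    def test_q_non_increasing_in_abs_d(self, rng):
        d_obs = rng.normal(0, 2, size=80)
        null_d = rng.normal(0, 1, size=(40, 80))
        q = q_values(d_obs, null_d)
        order = np.argsort(-np.abs(d_obs))
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_null_data_gives_large_q(self, rng):
        # observed drawn from the same distribution as the null: no signal
        null_d = rng.normal(size=(50, 100))
        d_obs = rng.normal(size=100)
        q = q_values(d_obs, null_d)
        assert np.median(q) > 0.5

    def test_extreme_gene_gets_zero_q(self, rng):
        null_d = rng.normal(size=(20, 50))
        d_obs = np.append(rng.normal(size=49), 1000.0)
        q = q_values(d_obs, null_d)
        assert q[-1] == 0.0


class TestAntisymmetry:
    def test_label_swap_negates_r_d_and_fold_change(self, small_two_group):
        m, design = small_two_group
        params = SamParams(seed=1, s0_strategy="percentile")
        a = sam_analysis(m, design, params)
        b = sam_analysis(m, design.swapped(), params)
        b = b.loc[a.index]
        np.testing.assert_allclose(b["r"], -a["r"], atol=1e-12)
        np.testing.assert_allclose(b["d"], -a["d"], atol=1e-12)
        np.testing.assert_allclose(b["p"], a["p"], atol=1e-12)
        np.testing.assert_allclose(b["q"], a["q"], atol=1e-12)
        big = np.abs(a["fold_change"]) > 1
        np.testing.assert_allclose(b["fold_change"][big], -a["fold_change"][big],
                                   rtol=1e-12)


class TestCallDegs:
    def make_results(self):
        import pandas as pd
        return pd.DataFrame(
            {"p": [0.001, 0.002, 0.003, 0.004, 0.5],
             "q": [0.04, 0.04, 0.04, 0.2, 0.9],
             "fold_change": [1.4, -2.5, 2.0, 3.0, 1.0]},
            index=pd.Index(["a", "b", "c", "d", "e"], name="gene"))

    def test_gates(self):
        up, down = call_degs(self.make_results(), SamParams())
        assert list(up.index) == ["c"]          # a fails FC, d fails q
        assert list(down.index) == ["b"]

    def test_ranks_follow_increasing_p(self):
        import pandas as pd
        res = pd.DataFrame(
            {"p": np.linspace(0.001, 0.01, 10),
             "q": np.full(10, 0.01),
             "fold_change": np.full(10, 2.0)},
            index=pd.Index([f"g{i}" for i in range(10)], name="gene"))
        up, down = call_degs(res, SamParams())
        assert list(up["rank"]) == list(range(1, 11))
        assert len(down) == 0
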