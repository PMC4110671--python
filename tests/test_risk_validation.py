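import numpy as np
import pandas as pd
import pytest
from scipy import stats

import methylrisk as mr
from conftest import make_signature


def _pair_counting_auc(scores, y):
    """Exhaustive all-pairs oracle: (concordant + 0.5 tied) / (n1 n0)."""
    cases = scores[y == 1]
    controls = scores[y == 0]
    total = 0.0
    for c in cases:
        for d in controls:
            total += 1.0 if c > d else (0.5 if c == d else 0.0)
    return total / (len(cases) * len(controls))


class TestScoreSamples:
    def test_training_mean_profile_scores_zero(self):
        sig = make_signature(["cg1", "cg2"], [2.0, -1.0],
                             means=[0.4, 0.6], scales=[0.1, 0.2])
        df = pd.DataFrame({"s1": [0.4, 0.6], "s2": [0.5, 0.6]},
                          index=pd.Index(["cg1", "cg2"], name="cpg_id"))
        table = mr.score_samples(mr.BetaMatrix(df), sig)
        assert table.scores["s1"] == pytest.approx(0.0)
        assert table.scores["s2"] == pytest.approx(2.0 * 0.1 / 0.1)

    def test_identical_profiles_identical_scores(self):
        sig = make_signature(["cg1", "cg2"], [1.0, 1.0])
        df = pd.DataFrame({"s1": [0.3, 0.7], "s2": [0.3, 0.7]},
                          index=pd.Index(["cg1", "cg2"], name="cpg_id"))
        table = mr.score_samples(mr.BetaMatrix(df), sig)
        assert table.scores["s1"] == table.scores["s2"]

    def test_platform_intersection_counts(self):
        # drop 107 of 1,829 signature CpGs -> 1,722 used, 107 missing
        n = 1829
        cpgs = [f"cg{i:07d}" for i in range(n)]
        rng = np.random.default_rng(0)
        sig = make_signature(cpgs, rng.uniform(0.1, 1.0, n),
                             means=np.full(n, 0.5), scales=np.full(n, 0.1))
        df = pd.DataFrame(rng.uniform(0.01, 0.99, (n, 3)),
                          index=pd.Index(cpgs, name="cpg_id"),
                          columns=["a", "b", "c"])
        subset = mr.platform_subset(mr.BetaMatrix(df), 1722 / 1829, seed=9)
        table = mr.score_samples(subset, sig)
        assert table.n_cpgs_used == 1722
        assert table.n_cpgs_missing == 107

    def test_zero_overlap_names_both_universes(self):
        sig = make_signature(["cgA"], [1.0])
        df = pd.DataFrame({"s1": [0.5]}, index=pd.Index(["cgB"],
                                                        name="cpg_id"))
        with pytest.raises(ValueError, match="1 CpGs.*1 CpGs"):
            mr.score_samples(mr.BetaMatrix(df), sig)

    def test_affine_stability_of_scoring(self):
        """Adding a constant to one CpG's betas shifts every score by
        coefficient * constant / scale."""
        sig = make_signature(["cg1", "cg2"], [2.0, -3.0],
                             means=[0.4, 0.5], scales=[0.2, 0.25])
        rng = np.random.default_rng(2)
        vals = rng.uniform(0.2, 0.6, size=(2, 5))
        idx = pd.Index(["cg1", "cg2"], name="cpg_id")
        cols = [f"s{i}" for i in range(5)]
        base = mr.score_samples(
            mr.BetaMatrix(pd.DataFrame(vals, index=idx, columns=cols)), sig)
        shifted = vals.copy()
        const = 0.05
        shifted[0] += const
        after = mr.score_samples(
            mr.BetaMatrix(pd.DataFrame(shifted, index=idx, columns=cols)), sig)
        expected = 2.0 * const / 0.2
        assert np.allclose(after.scores - base.scores, expected)


class TestSomersAuc:
    def test_perfect_separation(self):
        rep = mr.somers_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert rep.auc == 1.0 and rep.dxy == 1.0

    def test_all_tied_scores(self):
        rep = mr.somers_auc([5.0] * 8, [0, 1] * 4)
        assert rep.auc == 0.5 and rep.dxy == 0.0 and rep.p_value == 0.5

    @pytest.mark.parametrize("seed,n", [(0, 20), (1, 75), (2, 200)])
    def test_matches_exhaustive_pair_counting_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 15, n).astype(float)  # many ties
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]
        rep = mr.somers_auc(scores, y)
        assert rep.auc == pytest.approx(_pair_counting_auc(scores, y),
                                        abs=1e-12)
        assert rep.dxy == pytest.approx(2 * rep.auc - 1)

    def test_antisymmetric_under_negation(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=50)  # tie-free
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        a1 = mr.somers_auc(scores, y)
        a2 = mr.somers_auc(-scores, y)
        assert a1.auc + a2.auc == pytest.approx(1.0)
        assert a1.dxy == pytest.approx(-a2.dxy)

    def test_one_class_absent_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            mr.somers_auc([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])


class TestDichotomize:
    def test_strict_mean_split(self):
        assert list(mr.dichotomize_scores([1.0, 2.0, 3.0])) == [0, 0, 1]

    def test_all_equal_scores_all_low(self):
        assert list(mr.dichotomize_scores([2.0, 2.0, 2.0])) == [0, 0, 0]

    def test_two_samples(self):
        assert list(mr.dichotomize_scores([0.0, 10.0])) == [0, 1]


class TestKmLogrank:
    def test_no_events_curves_constant_at_one(self):
        with pytest.warns(RuntimeWarning, match="log-rank undefined"):
            curves, p = mr.km_logrank([1, 2, 3, 4], [0, 0, 0, 0],
                                      [0, 0, 1, 1])
        assert np.isnan(p)
        for _t, s in curves.values():
            assert np.all(s == 1.0)

    def test_identical_groups_logrank_null(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        e = np.array([1, 0, 1, 1, 0])
        curves, p = mr.km_logrank(np.concatenate([t, t]),
                                  np.concatenate([e, e]),
                                  np.array([0] * 5 + [1] * 5))
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_product_limit_matches_hand_computation(self):
        # 6 subjects: deaths at 1, 3, 5; censored at 2, 4, 6
        t = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        e = [1, 0, 1, 0, 1, 0]
        curves, _ = mr.km_logrank(t + t, e + e, [0] * 6 + [1] * 6)
        times, surv = curves["low"]
        # hand product-limit: S(1)=5/6, S(3)=5/6*3/4, S(5)=5/6*3/4*1/2
        expected = {1.0: 5 / 6, 3.0: 5 / 6 * 3 / 4, 5.0: 5 / 6 * 3 / 4 * 1 / 2}
        lookup = dict(zip(times, surv))
        for tt, ss in expected.items():
            assert lookup[tt] == pytest.approx(ss, abs=1e-12)


def _breslow_loglik(beta, t, e, g):
    """Independent brute-force Breslow partial log-likelihood."""
    ll = 0.0
    for tk in np.unique(t[e == 1]):
        at = t >= tk
        dead = (t == tk) & (e == 1)
        d, s = dead.sum(), (dead & (g == 1)).sum()
        n1, n0 = (at & (g == 1)).sum(), (at & (g == 0)).sum()
        ll += s * beta - d * np.log(n1 * np.exp(beta) + n0)
    return ll


class TestCoxBinaryHr:
    def _simulate(self, hr, n, seed, event_frac=0.4):
        rng = np.random.default_rng(seed)
        g = rng.integers(0, 2, n)
        t = rng.exponential(1.0 / np.where(g == 1, hr, 1.0))
        c = rng.exponential(np.quantile(t, event_frac) * 2.5, n)
        time = np.minimum(t, c)
        event = (t <= c).astype(int)
        return time, event, g

    def test_matches_grid_search_oracle(self):
        time, event, g = self._simulate(2.0, 120, seed=1)
        rep = mr.cox_binary_hr(time, event, g, logrank=False)
        grid = np.linspace(-3, 3, 60001)
        lls = [_breslow_loglik(b, time, event, g) for b in grid]
        beta_grid = grid[int(np.argmax(lls))]
        assert np.log(rep.hr) == pytest.approx(beta_grid, abs=1e-4)

    def test_single_event_is_monotone_non_estimable(self):
        # with one event the partial likelihood is monotone in beta (the
        # score is strictly positive or negative everywhere), so no finite
        # MLE exists; the fit must say so rather than return a number
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 0, 0, 0])
        g = np.array([1, 0, 1, 0])
        rep = mr.cox_binary_hr(time, event, g, logrank=False)
        assert rep.monotone and np.isnan(rep.hr)
        # the grid oracle confirms: likelihood increases to the boundary
        grid = np.linspace(-6, 6, 2001)
        lls = [_breslow_loglik(b, time, event, g) for b in grid]
        assert int(np.argmax(lls)) == len(grid) - 1

    def test_planted_hazard_ratio_recovered(self):
        hrs = []
        for seed in range(50):
            time, event, g = self._simulate(3.0, 500, seed)
            rep = mr.cox_binary_hr(time, event, g, logrank=False)
            hrs.append(rep.hr)
        assert 2.5 <= np.median(hrs) <= 3.6

    def test_events_confined_to_one_group_non_estimable(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        rep = mr.cox_binary_hr(time, np.array([1, 1, 0, 0]),
                               np.array([1, 1, 0, 0]), logrank=False)
        assert rep.monotone and np.isnan(rep.hr)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            mr.cox_binary_hr([1.0, 2.0], [0, 0], [0, 1])


class TestFisherExact:
    @pytest.mark.parametrize("table,expected,tol", [
        ([[2, 7], [125, 107]], 0.0887, 0.0005),   # grandmother history
        ([[5, 11], [122, 103]], 0.118, 0.001),    # sister history
        ([[12, 6], [115, 108]], 0.233, 0.001),    # aunt history
        ([[14, 11], [113, 103]], 0.833, 0.001),   # mother history
    ])
    def test_printed_epidemiology_tables(self, table, expected, tol):
        assert mr.fisher_exact_2x2(table) == pytest.approx(expected, abs=tol)

    def test_degenerate_single_table(self):
        assert mr.fisher_exact_2x2([[0, 5], [0, 5]]) == 1.0

    def test_agrees_with_scipy_oracle_on_random_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            tab = rng.integers(0, 150, size=(2, 2))
            if tab.sum(axis=0).min() == 0 and tab.sum(axis=1).min() == 0:
                continue
            mine = mr.fisher_exact_2x2(tab)
            ref = stats.fisher_exact(tab)[1]
            assert mine == pytest.approx(ref, rel=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            mr.fisher_exact_2x2([[-1, 2], [3, 4]])


class TestWelchT:
    def test_identical_summaries(self):
        assert mr.welch_t(1.0, 2.0, 30, 1.0, 2.0, 30) == 1.0

    def test_matches_scipy_summary_oracle(self):
        ref = stats.ttest_ind_from_stats(0.0, 1.0, 50, 1.0, 1.0, 50,
                                         equal_var=False).pvalue
        assert mr.welch_t(0.0, 1.0, 50, 1.0, 1.0, 50) == pytest.approx(
            ref, rel=1e-12)

    def test_zero_variance_unequal_means_degenerate(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            assert mr.welch_t(0.0, 0.0, 5, 1.0, 0.0, 5) == 0.0

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            mr.welch_t(0.0, 1.0, 1, 1.0, 1.0, 5)
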