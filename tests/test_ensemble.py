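import warnings

import numpy as np
import pytest
from scipy.special import logit

import methylrisk as mr
from methylrisk._enet import binomial_deviance, enet_logistic_path, lambda_grid
from methylrisk.ensemble_signature import _meta_weights, cv_elastic_net


def _toy_problem(seed=0, n=80, p=10, informative=3):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    eta = X[:, :informative] @ np.linspace(1.5, 0.5, informative)
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return X, y


class TestEnetPath:
    def test_full_penalty_gives_intercept_only_model(self):
        X, y = _toy_problem(1)
        lam_max = lambda_grid(X, y, 0.1)[0]
        b0s, coefs = enet_logistic_path(X, y, 0.1,
                                        np.array([lam_max * 1.01]))
        assert np.all(coefs == 0.0)
        assert b0s[0] == pytest.approx(logit(y.mean()), abs=1e-6)

    def test_tiny_penalty_matches_unpenalized_ml_oracle(self):
        # n >> p, well-conditioned: lambda -> 0 recovers plain logistic ML
        import statsmodels.api as sm
        rng = np.random.default_rng(5)
        n, p = 400, 3
        X = rng.normal(size=(n, p))
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.8 * X[:, 0] - X[:, 1])))
             ).astype(float)
        b0s, coefs = enet_logistic_path(X, y, 0.1, np.array([1e-8]),
                                        tol=1e-10, max_outer=200)
        ml = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert b0s[0] == pytest.approx(ml.params[0], rel=1e-4)
        assert np.allclose(coefs[0], ml.params[1:], rtol=1e-4)

    def test_matches_sklearn_saga_at_matched_penalty(self):
        # independent solver oracle for the penalized objective
        from sklearn.linear_model import LogisticRegression
        X, y = _toy_problem(2, n=120, p=8)
        lam = 0.02
        b0s, coefs = enet_logistic_path(X, y, 0.5, np.array([lam]),
                                        tol=1e-9, max_outer=200)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sk = LogisticRegression(penalty="elasticnet", solver="saga",
                                    l1_ratio=0.5, C=1.0 / (len(y) * lam),
                                    tol=1e-10, max_iter=50_000).fit(X, y)
        assert np.allclose(coefs[0], sk.coef_[0], atol=2e-4)
        assert b0s[0] == pytest.approx(sk.intercept_[0], abs=2e-4)

    def test_support_shrinks_with_penalty(self):
        # exact step-by-step monotonicity is not guaranteed for L1 paths
        # (coordinates can re-enter); compare well-separated penalties
        X, y = _toy_problem(3, n=100, p=30)
        lams = lambda_grid(X, y, 0.9, n_lambda=12)
        _, coefs = enet_logistic_path(X, y, 0.9, lams)
        support = [(c != 0).sum() for c in coefs]
        for i in range(len(lams)):
            for j in range(i + 1, len(lams)):
                if lams[i] >= 4 * lams[j]:
                    assert support[i] <= support[j]
        assert support[0] < support[-1]


class TestCvElasticNet:
    def test_out_of_fold_predictor_covers_every_sample(self):
        X, y = _toy_problem(4, n=60, p=12)
        cfg = mr.EnsembleConfig(n_base=1, n_folds=5)
        fit = cv_elastic_net(X, y, cfg, fold_seed=9)
        assert fit.oof_eta.shape == (60,)
        assert np.all(np.isfinite(fit.oof_eta))
        assert fit.lambda_selected in fit.lambdas

    def test_fewer_samples_than_folds_rejected(self):
        X, y = _toy_problem(0, n=6, p=3)
        with pytest.raises(ValueError, match="folds"):
            cv_elastic_net(X, y, mr.EnsembleConfig(n_folds=10), 0)

    def test_constant_features_give_zero_fit_with_warning(self):
        y = np.array([0.0, 1.0] * 10)
        X = np.ones((20, 4))
        with pytest.warns(RuntimeWarning, match="constant"):
            fit = cv_elastic_net(X, y, mr.EnsembleConfig(n_folds=4), 0)
        assert np.all(fit.coefficients == 0)
        assert fit.intercept == pytest.approx(0.0)  # logit(0.5)

    def test_permuted_labels_no_better_than_intercept_model(self):
        # CV deviance at the selected penalty must not beat the null
        wins = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(60, 30))
            y = np.array([0.0, 1.0] * 30)
            rng.shuffle(y)
            fit = cv_elastic_net(X, y, mr.EnsembleConfig(n_folds=5), seed)
            null_dev = binomial_deviance(y, np.full(60, logit(y.mean())))
            best = fit.cv_deviance.min()
            wins.append(best <= null_dev * 1.10)
        assert np.mean(wins) >= 0.8


class TestStackEnsemble:
    def test_single_base_stack_is_the_base_fit_up_to_scale(self, small_cohort,
                                                           small_scan):
        _, cand = small_scan
        cfg = mr.EnsembleConfig(n_base=1, n_folds=5, seed=2)
        sig = mr.stack_ensemble(small_cohort["beta"],
                                small_cohort["sheet"].group, cfg, cand)
        # recompute the single base fit exactly as the stack does
        sub = small_cohort["beta"].subset_cpgs(cand.cpg_ids)
        X = sub.values.to_numpy().T
        Xs = (X - X.mean(0)) / X.std(0)
        sub_seed = int(np.random.SeedSequence(2).generate_state(1)[0])
        base = cv_elastic_net(Xs, small_cohort["sheet"].group.astype(float),
                              cfg, sub_seed)
        nz = base.coefficients != 0
        assert set(sig.cpg_ids) == set(sub.cpg_ids[nz])
        ratio = sig.coefficients.to_numpy() / base.coefficients[nz]
        assert np.allclose(ratio, ratio[0], rtol=1e-9)
        assert ratio[0] > 0  # meta weight is non-negative

    def test_deterministic_bit_for_bit(self, small_cohort, small_scan):
        _, cand = small_scan
        cfg = mr.EnsembleConfig(n_base=3, n_folds=5, seed=8)
        args = (small_cohort["beta"], small_cohort["sheet"].group, cfg, cand)
        s1 = mr.stack_ensemble(*args)
        s2 = mr.stack_ensemble(*args)
        assert s1.coefficients.equals(s2.coefficients)
        assert s1.means.equals(s2.means)

    def test_stacked_score_is_weighted_sum_of_base_scores(self, small_cohort,
                                                          small_scan):
        """Linearity identity: combined-coefficient scores equal the
        w-weighted sum of base linear predictors, machine precision."""
        _, cand = small_scan
        cfg = mr.EnsembleConfig(n_base=3, n_folds=5, seed=8)
        y = small_cohort["sheet"].group.astype(float)
        sub = small_cohort["beta"].subset_cpgs(cand.cpg_ids)
        X = sub.values.to_numpy().T
        Xs = (X - X.mean(0)) / X.std(0)
        seeds = np.random.SeedSequence(8).generate_state(3)
        fits = [cv_elastic_net(Xs, y, cfg, int(s)) for s in seeds]
        Z = np.column_stack([f.oof_eta for f in fits])
        w, _c = _meta_weights(Z, y, "nonneg_stack")
        combined = np.array([f.coefficients for f in fits]).T @ w
        lhs = Xs @ combined
        rhs = sum(wj * (Xs @ f.coefficients) for wj, f in zip(w, fits))
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_meta_rules_agree_on_held_out_auc(self, small_cohort, small_scan):
        _, cand = small_scan
        y = small_cohort["sheet"].group
        aucs = {}
        for rule in ("nonneg_stack", "mean"):
            cfg = mr.EnsembleConfig(n_base=3, n_folds=5, seed=4,
                                    meta_rule=rule)
            sig = mr.stack_ensemble(small_cohort["beta"], y, cfg, cand)
            pbeta, psheet = mr.simulate_prospective(
                small_cohort["config"], small_cohort["truth"])
            scores = mr.score_samples(pbeta, sig)
            aucs[rule] = mr.somers_auc(scores.scores, psheet.group).auc
        assert abs(aucs["nonneg_stack"] - aucs["mean"]) < 0.05

    def test_null_labels_give_uninformative_or_empty_signature(self,
                                                               small_cohort):
        y = small_cohort["sheet"].group.copy()
        aucs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y_perm = rng.permutation(y)
            cfg = mr.EnsembleConfig(n_base=2, n_folds=5, seed=seed)
            try:
                sig = mr.stack_ensemble(small_cohort["beta"], y_perm, cfg)
            except RuntimeError:
                aucs.append(0.5)  # all-zero base fits: no signal retained
                continue
            pbeta, psheet = mr.simulate_prospective(
                small_cohort["config"], small_cohort["truth"])
            rng2 = np.random.default_rng(seed + 100)
            perm_outcome = rng2.permutation(psheet.group)
            scores = mr.score_samples(pbeta, sig)
            aucs.append(mr.somers_auc(scores.scores, perm_outcome).auc)
        assert 0.45 <= np.median(aucs) <= 0.55

    def test_too_few_samples_rejected(self, small_cohort):
        beta = mr.BetaMatrix(small_cohort["beta"].values.iloc[:, :10])
        with pytest.raises(ValueError, match="20 samples"):
            mr.stack_ensemble(beta, small_cohort["sheet"].group[:10],
                              mr.EnsembleConfig(n_folds=2))


class TestSignatureSummary:
    def test_counts_by_sign(self):
        from conftest import make_signature
        sig = make_signature(["a", "b", "c"], [1.0, -2.0, 3.0])
        assert mr.signature_summary(sig) == (3, 2, 1)

    def test_canonical_split_is_consistent(self):
        # published-scale split: 1,829 total = 1,074 hyper + 755 hypo
        rng = np.random.default_rng(1)
        from conftest import make_signature
        coefs = np.concatenate([rng.uniform(0.1, 1, 1074),
                                -rng.uniform(0.1, 1, 755)])
        sig = make_signature([f"cg{i}" for i in range(1829)], coefs)
        assert mr.signature_summary(sig) == (1829, 1074, 755)

    def test_all_positive_has_no_hypo(self):
        from conftest import make_signature
        sig = make_signature(["a", "b"], [0.5, 1.5])
        assert mr.signature_summary(sig) == (2, 2, 0)
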