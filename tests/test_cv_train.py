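import numpy as np
import pandas as pd
import pytest

from bmigap.imaging_io import ValidationError
from bmigap.normative import (Candidate, balanced_accuracy, build_cv,
                              permutation_test, predict_ensemble,
                              train_ensemble)
from bmigap.normative.cv import SizingError
from bmigap.normative.stats import permutation_pvalue
from bmigap.normative.train import cv_metric_frozen, train_nusvr, train_svm


def _tabular_sets(rng, n=60, p=8, signal=True):
    X = rng.normal(size=(n, p))
    y = X[:, 0] * 3.0 + rng.normal(0, 0.5, n) + 25.0 if signal \
        else rng.normal(25.0, 3.0, n)
    age = rng.uniform(20, 60, n)
    sites = np.array(["A", "B"] * (n // 2))
    return {0.0: X}, y, age, sites


class TestBuildCV:
    def test_counts_n10_k5_p5(self):
        cv = build_cv(10, 5, 5, seed=0)
        assert len(cv) == 25
        for f in cv:
            assert len(f.train_idx) == 8
            assert len(f.test_idx) == 2
            assert not set(f.train_idx) & set(f.test_idx)

    def test_partition_within_repeat(self):
        cv = build_cv(23, 5, 3, seed=1)
        for rep in range(3):
            test = np.concatenate([f.test_idx for f in cv if f.repeat == rep])
            assert sorted(test) == list(range(23))

    def test_leave_one_out_limit(self):
        cv = build_cv(6, 6, 1, seed=0)
        assert len(cv) == 6
        assert all(len(f.test_idx) == 1 for f in cv)

    def test_determinism(self):
        a = build_cv(20, 5, 2, seed=9)
        b = build_cv(20, 5, 2, seed=9)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.train_idx, fb.train_idx)

    def test_stratified_classification(self):
        y = np.array([0] * 10 + [1] * 10)
        cv = build_cv(20, 5, 2, seed=0, stratify_on=y)
        for f in cv:
            assert set(y[f.test_idx]) == {0, 1}

    def test_n_below_k(self):
        with pytest.raises(SizingError):
            build_cv(3, 5, 1, seed=0)


class TestTrainNuSVR:
    def test_collinear_toy_reproduces_line(self, rng):
        n = 40
        x = rng.uniform(0, 1, n)
        X = np.column_stack([x, np.zeros(n)])
        y = 20 + 10 * x
        fs = {0.0: X}
        age = np.full(n, 40.0)  # constant: residualization passes through
        sites = np.array(["A"] * n)
        with pytest.warns(UserWarning):
            state, coef, b0, cand, _, _ = train_nusvr(
                fs, y, age, sites, np.arange(n),
                [Candidate(0.0, 1.0, 0.5, 100.0)], K2=5, P2=1, seed=0)
        from bmigap.normative.preprocess import apply_preproc
        Z = apply_preproc(state, X, age, sites)
        pred = Z @ coef + b0
        assert np.abs(pred - y).mean() < 0.5  # within the eps-tube tolerance

    def test_single_candidate_selected(self, rng):
        fs, y, age, sites = _tabular_sets(rng)
        only = Candidate(0.0, 0.75, 0.5, 1.0)
        _, _, _, cand, _, _ = train_nusvr(fs, y, age, sites, np.arange(60),
                                          [only], K2=5, P2=1, seed=0)
        assert cand == only

    def test_kkt_conditions_tiny_instance(self):
        """Brute-force support-vector constraint check on an n=6 fit."""
        from sklearn.svm import NuSVR
        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 2))
        y = X @ [1.0, -2.0] + rng.normal(0, 0.1, 6)
        m = NuSVR(kernel="linear", nu=0.5, C=1.0).fit(X, y)
        # stationarity: w = sum_i alpha_i x_i over support vectors
        w = (m.dual_coef_ @ m.support_vectors_).ravel()
        np.testing.assert_allclose(w, m.coef_.ravel(), atol=1e-10)
        resid = np.abs(y - m.predict(X))
        alpha = np.zeros(6)
        alpha[m.support_] = m.dual_coef_.ravel()
        bound = np.max(np.abs(alpha))
        free = (np.abs(alpha) > 1e-9) & (np.abs(alpha) < bound - 1e-9)
        eps = resid[free].mean() if free.any() else resid[m.support_].min()
        # non-SVs lie inside the eps-tube; bounded SVs on or outside it
        assert (resid[alpha == 0] <= eps + 1e-6).all()
        at_bound = np.abs(np.abs(alpha) - bound) < 1e-9
        assert (resid[at_bound] >= eps - 1e-6).all()


class TestTrainSVM:
    def test_separable_toy_perfect_bac(self, rng):
        n = 60
        X = np.vstack([rng.normal(-3, 0.3, size=(n // 2, 2)),
                       rng.normal(3, 0.3, size=(n // 2, 2))])
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        fs = {0.0: X}
        age = rng.uniform(20, 60, n)
        sites = np.array(["A"] * n)
        state, coef, b0, _, score, _ = train_svm(
            fs, y, age, sites, np.arange(n),
            [Candidate(0.0, 1.0, None, 10.0)], K2=3, P2=1, seed=0)
        assert score == 100.0

    def test_orientation_disease_scores_higher(self, rng):
        n = 40
        X = np.vstack([rng.normal(0, 0.2, size=(n // 2, 2)),
                       rng.normal(2, 0.2, size=(n // 2, 2))])
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        fs = {0.0: X}
        age = rng.uniform(20, 60, n)
        sites = np.array(["A"] * n)
        state, coef, b0, _, _, _ = train_svm(
            fs, y, age, sites, np.arange(n),
            [Candidate(0.0, 1.0, None, 10.0)], K2=2, P2=1, seed=0)
        from bmigap.normative.preprocess import apply_preproc
        proto = np.array([[2.0, 2.0], [0.0, 0.0]])  # disease, HC prototypes
        Z = apply_preproc(state, proto, np.array([30.0, 30.0]),
                          np.array(["A", "A"]))
        scores = Z @ coef + b0
        assert scores[0] > scores[1]


class TestEnsemble:
    def test_every_subject_gets_oof(self, rng):
        fs, y, age, sites = _tabular_sets(rng)
        ids = [f"s{i}" for i in range(60)]
        ens = train_ensemble(fs, y, age, sites, ids,
                             grid=[Candidate(0.0, 0.75, 0.5, 1.0)],
                             K1=5, P1=2, K2=3, P2=1, seed=0)
        assert len(ens.models) == 10
        assert ens.oof_predictions.notna().all()
        assert list(ens.oof_predictions.index) == ids

    def test_oof_is_mean_of_per_fold_test_predictions(self, rng):
        fs, y, age, sites = _tabular_sets(rng)
        ids = [f"s{i}" for i in range(60)]
        ens = train_ensemble(fs, y, age, sites, ids,
                             grid=[Candidate(0.0, 0.75, 0.5, 1.0)],
                             K1=5, P1=2, K2=3, P2=1, seed=0)
        # recompute: each subject is held out once per repeat
        sums = np.zeros(60)
        cnts = np.zeros(60)
        for m in ens.models:
            pred = m.apply({0.0: fs[0.0][m.test_idx]}, age[m.test_idx],
                           sites[m.test_idx])
            sums[m.test_idx] += pred
            cnts[m.test_idx] += 1
        np.testing.assert_array_equal(cnts, 2)
        np.testing.assert_allclose(ens.oof_predictions.to_numpy(),
                                   sums / cnts, atol=1e-10)

    def test_ensemble_mean_invariance(self, rng):
        fs, y, age, sites = _tabular_sets(rng)
        ids = [f"s{i}" for i in range(60)]
        ens = train_ensemble(fs, y, age, sites, ids,
                             grid=[Candidate(0.0, 0.75, 0.5, 1.0)],
                             K1=5, P1=1, K2=3, P2=1, seed=0)
        newX = {0.0: rng.normal(size=(4, 8))}
        a = predict_ensemble(ens, newX, [30] * 4, ["A"] * 4, list("wxyz"))
        ens.models = ens.models[::-1]
        b = predict_ensemble(ens, newX, [30] * 4, ["A"] * 4, list("wxyz"))
        pd.testing.assert_series_equal(a.per_subject, b.per_subject)

    def test_identical_models_mean_equals_single(self, rng):
        fs, y, age, sites = _tabular_sets(rng)
        ens = train_ensemble(fs, y, age, sites, [f"s{i}" for i in range(60)],
                             grid=[Candidate(0.0, 0.75, 0.5, 1.0)],
                             K1=5, P1=1, K2=3, P2=1, seed=0)
        ens.models = [ens.models[0]] * 5
        newX = {0.0: rng.normal(size=(3, 8))}
        res = predict_ensemble(ens, newX, [30] * 3, ["A"] * 3, list("abc"))
        single = ens.models[0].apply(newX, np.array([30.0] * 3),
                                     np.array(["A"] * 3))
        np.testing.assert_allclose(res.per_subject.to_numpy(), single,
                                   atol=1e-12)


class TestLeakage:
    def test_mutating_test_subject_changes_nothing_fitted(self, rng):
        """Models whose training partition excludes a subject are unchanged
        when that subject's features and label are perturbed."""
        fs, y, age, sites = _tabular_sets(rng)
        ids = [f"s{i}" for i in range(60)]
        grid = [Candidate(0.0, 0.75, 0.5, 1.0)]
        ens = train_ensemble(fs, y, age, sites, ids, grid=grid,
                             K1=5, P1=1, K2=3, P2=1, seed=0)
        victim = 7
        fs2 = {0.0: fs[0.0].copy()}
        fs2[0.0][victim] += 100.0
        y2 = y.copy()
        y2[victim] += 50.0
        ens2 = train_ensemble(fs2, y2, age, sites, ids, grid=grid,
                              K1=5, P1=1, K2=3, P2=1, seed=0)
        checked = 0
        for m1, m2 in zip(ens.models, ens2.models):
            if victim in m1.train_idx:
                continue
            np.testing.assert_array_equal(m1.coef, m2.coef)
            assert m1.intercept == m2.intercept
            np.testing.assert_array_equal(m1.state.pca_mean, m2.state.pca_mean)
            np.testing.assert_array_equal(m1.state.age_slope, m2.state.age_slope)
            np.testing.assert_array_equal(m1.state.scale_lo, m2.state.scale_lo)
            checked += 1
        assert checked >= 1
        # untouched subjects held out alongside the victim keep their
        # predictions (their fold's model never saw the mutation)
        victim_fold = next(m for m in ens.models if victim in m.test_idx)
        peers = [i for i in victim_fold.test_idx if i != victim]
        for i in peers:
            assert ens.oof_predictions.iloc[i] == ens2.oof_predictions.iloc[i]


class TestPermutationTest:
    def test_formula_floor(self):
        assert permutation_pvalue(0.0, np.ones(1000)) == 1 / 1001

    def test_p_never_exceeds_one(self, rng):
        null = rng.normal(size=50)
        assert permutation_pvalue(np.inf, null) <= 1.0

    def test_strong_signal_small_p(self, rng):
        fs, y, age, sites = _tabular_sets(rng, n=40, signal=True)
        p, obs, null = permutation_test(fs, y, age, sites,
                                        Candidate(0.0, 0.9, 0.5, 10.0),
                                        n_perm=49, K=4, P=1, seed=0)
        assert p == 1 / 50
        assert obs < null.min()

    def test_null_calibration(self, rng):
        """Rejection rate at alpha=0.05 stays within the binomial bound."""
        rejections = 0
        for rep in range(20):
            r = np.random.default_rng(100 + rep)
            X = r.normal(size=(30, 5))
            y = r.normal(25, 3, 30)
            age = r.uniform(20, 60, 30)
            sites = np.array(["A"] * 30)
            p, _, _ = permutation_test({0.0: X}, y, age, sites,
                                       Candidate(0.0, 0.75, 0.5, 1.0),
                                       n_perm=99, K=3, P=1, seed=rep)
            rejections += p <= 0.05
        assert rejections <= 5  # 0.25 * 20


class TestClassifierNullCalibration:
    def test_null_features_random_labels_bac_near_chance(self, rng):
        """Mean outer BAC stays within [45, 55] on null data (n=200)."""
        from bmigap.normative.stats import bac_from_predictions
        n = 200
        X = rng.normal(size=(n, 6))
        y = np.array([0, 1] * (n // 2))
        ens = train_ensemble({0.0: X}, y, rng.uniform(20, 60, n),
                             np.array(["A"] * n), [f"s{i}" for i in range(n)],
                             task="classification",
                             grid=[Candidate(0.0, 0.75, None, 1.0)],
                             K1=5, P1=2, K2=3, P2=1, seed=0)
        pred = (ens.oof_predictions.to_numpy() > 0).astype(int)
        bac = bac_from_predictions(y, pred)
        assert 45.0 <= bac <= 55.0


class TestBalancedAccuracy:
    @pytest.mark.parametrize("sens,spec,expected", [
        (72.2, 72.6, 72.4),
        (64.9, 53.5, 59.2),
        (48.6, 63.6, 56.1),
        (100.0, 0.0, 50.0),
    ])
    def test_values(self, sens, spec, expected):
        assert balanced_accuracy(sens, spec) == pytest.approx(expected)

    def test_out_of_range(self):
        with pytest.raises(ValidationError):
            balanced_accuracy(101.0, 50.0)
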