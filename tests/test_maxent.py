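"""Maximum-entropy model: oracles, invariants, and the replicate protocol."""

import itertools

import numpy as np
import pytest

from hydrofowl.maxent import (
    MaxentConvergenceError,
    auto_feature_classes,
    build_features,
    fit_maxent,
    predict_surface,
    replicate_fit,
)


class TestFeatureConstruction:
    def test_class_thresholds(self):
        assert auto_feature_classes(5) == ("linear",)
        assert auto_feature_classes(10) == ("linear", "quadratic")
        assert auto_feature_classes(15) == ("linear", "quadratic", "hinge")
        assert auto_feature_classes(80) == ("linear", "quadratic", "hinge", "product")

    def test_counts_m12(self):
        X = np.random.default_rng(0).random((12, 2))
        fs = build_features(X, ["a", "b"], classes="auto", n_presences=12)
        assert fs.n_features == 4  # linear + quadratic

    def test_counts_m100(self):
        X = np.random.default_rng(0).random((100, 2))
        fs = build_features(X, ["a", "b"], classes="auto", n_presences=100)
        # linear(2) + quadratic(2) + product(1) + hinge(2*2*10)
        assert fs.n_features == 45

    def test_constant_covariate_dropped(self):
        X = np.column_stack([np.random.default_rng(0).random(30), np.full(30, 7.0)])
        fs = build_features(X, ["a", "const"], classes=("linear",), n_presences=30)
        assert fs.dropped == ("const",)
        assert fs.covariate_names == ("a",)

    def test_features_scaled_to_unit_interval(self):
        X = np.random.default_rng(1).normal(100, 25, size=(60, 3))
        fs = build_features(X, ["a", "b", "c"], classes="auto", n_presences=60)
        F = fs.transform(X)
        assert F.min() >= 0.0 and F.max() <= 1.0

    def test_hinge_knots_strictly_inside(self):
        X = np.random.default_rng(0).random((20, 1))
        fs = build_features(X, ["a"], classes=("hinge",), n_presences=20)
        knots = fs._knots()
        assert np.all(knots > 0) and np.all(knots < 1)


class TestFitOracles:
    def test_two_cell_l1_worked_example(self):
        # all presences at the binary feature's 1-cell, beta = 0.1: the L1
        # penalty shrinks the constraint E_q f = 1 to 0.9, so lambda = ln 9
        model = fit_maxent(
            np.array([[1.0]]),
            np.array([[0.0], [1.0]]),
            ["f"],
            classes=("linear",),
            beta=0.1,
            tol=1e-12,
        )
        assert model.weights[0] == pytest.approx(np.log(9.0), abs=1e-6)
        q = model.predict_raw(np.array([[0.0], [1.0]]))
        assert q[1] == pytest.approx(0.9, abs=1e-6)

    def test_huge_beta_gives_uniform_model(self):
        rng = np.random.default_rng(2)
        Xb = rng.random((20, 2))
        model = fit_maxent(Xb[:5], Xb, ["a", "b"], classes=("linear",), beta=1e6)
        assert np.all(model.weights == 0.0)
        q = model.predict_raw(Xb)
        assert np.allclose(q, 1.0 / 20)
        assert np.allclose(model.predict_logistic(Xb), 0.5)

    def test_brute_force_objective_equivalence(self):
        # 5 cells, 2 features: compare with exhaustive grid search + refinement
        rng = np.random.default_rng(4)
        Xb = rng.random((5, 1))
        Xp = Xb[[0, 1, 1]]
        beta = 0.05
        model = fit_maxent(
            Xp, Xb, ["a"], classes=("linear", "quadratic"), beta=beta, tol=1e-13,
            max_iter=200000,
        )
        fs = model.feature_set
        Fb = fs.transform(Xb)
        Fp = fs.transform(Xp)
        fbar = Fp.mean(axis=0)

        def objective(lam):
            lam = np.asarray(lam)
            return (
                float(fbar @ lam)
                - float(np.log(np.sum(np.exp(Fb @ lam))))
                - beta * float(np.abs(lam).sum())
            )

        # coarse grid then local refinement around the best point
        grid = np.arange(-10.0, 10.0 + 1e-9, 0.25)
        best = max(itertools.product(grid, grid), key=objective)
        for width in (0.25, 0.05, 0.01, 0.002):
            local = [np.linspace(b - width, b + width, 21) for b in best]
            best = max(itertools.product(*local), key=objective)
        assert objective(model.weights.tolist()) >= objective(best) - 1e-6

    def test_beta_zero_matches_presence_means(self):
        rng = np.random.default_rng(1)
        Xb = rng.random((50, 2))
        Xp = Xb[rng.choice(50, 30)]  # presences are background cells: non-separable
        model = fit_maxent(
            Xp, Xb, ["a", "b"], classes=("linear", "quadratic"), beta=0.0,
            tol=1e-12, max_iter=100000,
        )
        F = model.feature_set.transform(Xb)
        Fp = model.feature_set.transform(Xp)
        q = model.predict_raw(Xb)
        assert np.abs(q @ F - Fp.mean(axis=0)).max() < 1e-4

    def test_zero_presences_rejected(self):
        with pytest.raises(ValueError):
            fit_maxent(np.empty((0, 1)), np.ones((3, 1)), ["a"], classes=("linear",))

    def test_nonconvergence_raises_with_trace(self):
        rng = np.random.default_rng(0)
        Xb = rng.random((30, 2))
        with pytest.raises(MaxentConvergenceError) as err:
            fit_maxent(Xb[:10], Xb, ["a", "b"], classes=("linear",), beta=0.0,
                       max_iter=2, tol=1e-15)
        assert len(err.value.trace) >= 1


class TestModelInvariants:
    def fit_example(self, beta_multiplier=1.0, shift=0.0, scale=1.0):
        rng = np.random.default_rng(7)
        Xb = rng.random((80, 2)) * scale + shift
        Xp = Xb[rng.choice(80, 25, replace=False)]
        return fit_maxent(Xp, Xb, ["a", "b"], classes=("linear", "quadratic", "hinge"),
                          beta_multiplier=beta_multiplier), Xb

    def test_q_sums_to_one_over_fitting_cells(self):
        model, Xb = self.fit_example()
        assert model.predict_raw(Xb).sum() == pytest.approx(1.0, abs=1e-8)

    def test_objective_monotone_nondecreasing(self):
        model, _ = self.fit_example()
        trace = np.array(model.objective_trace)
        assert np.all(np.diff(trace) >= -1e-12)

    def test_objective_invariant_to_affine_covariate_rescaling(self):
        m1, _ = self.fit_example()
        m2, _ = self.fit_example(shift=100.0, scale=37.0)
        assert m1.objective == pytest.approx(m2.objective, abs=1e-6)

    def test_training_predictions_consistent_with_fit(self):
        model, Xb = self.fit_example()
        F = model.feature_set.transform(Xb)
        q_direct = np.exp(F @ model.weights - model.log_z)
        assert np.abs(model.predict_raw(Xb) - q_direct).max() < 1e-10

    def test_logistic_monotone_in_raw(self):
        model, Xb = self.fit_example()
        raw = model.predict_raw(Xb)
        logi = model.predict_logistic(Xb)
        order = np.argsort(raw)
        assert np.all(np.diff(logi[order]) >= -1e-15)

    def test_predict_surface_propagates_nodata(self):
        model, _ = self.fit_example()
        layers = {
            "a": np.array([[0.2, np.nan], [0.5, 0.9]]),
            "b": np.array([[0.3, 0.4], [np.nan, 0.1]]),
        }
        surf = predict_surface(model, layers)
        assert np.isnan(surf[0, 1]) and np.isnan(surf[1, 0])
        assert np.isfinite(surf[0, 0]) and 0 < surf[0, 0] < 1


class TestReplicateProtocol:
    def make_world(self):
        rng = np.random.default_rng(10)
        cells = list(range(400))
        env = rng.random((400, 2))
        weight = np.exp(-3 * env[:, 0])
        pres = rng.choice(400, size=60, replace=False, p=weight / weight.sum())
        cand = sorted(set(cells) - set(pres.tolist()))
        values_at = lambda cs: env[np.asarray(list(cs), dtype=int)]
        return [int(p) for p in pres], cand, values_at

    def test_deterministic_given_master_seed(self):
        pres, cand, values_at = self.make_world()
        r1 = replicate_fit(pres, cand, values_at, ["a", "b"], n_runs=5, seed=3)
        r2 = replicate_fit(pres, cand, values_at, ["a", "b"], n_runs=5, seed=3)
        assert [x.auc for x in r1] == [x.auc for x in r2]

    def test_single_run_reduces_to_one_fit(self):
        pres, cand, values_at = self.make_world()
        r = replicate_fit(pres, cand, values_at, ["a", "b"], n_runs=1, seed=0)
        assert len(r) == 1 and 0.0 <= r[0].auc <= 1.0

    def test_paired_runs_share_splits_across_covariate_sets(self):
        pres, cand, values_at = self.make_world()
        # same master seed, different covariate subsets: identical backgrounds
        r1 = replicate_fit(pres, cand, lambda c: values_at(c)[:, :1], ["a"],
                           n_runs=3, seed=9)
        r2 = replicate_fit(pres, cand, values_at, ["a", "b"], n_runs=3, seed=9)
        assert [x.seed for x in r1] == [x.seed for x in r2]

    def test_too_few_presences_rejected(self):
        _, cand, values_at = self.make_world()
        with pytest.raises(ValueError):
            replicate_fit([1, 2, 3], cand, values_at, ["a", "b"], n_runs=2, seed=0)
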