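"""Epsilon-SVR engine: grids, folds, nested CV hygiene, metrics."""

import numpy as np
import pytest

from neglectprog.engine import (
    CVPlan,
    FoldCompositionError,
    SvrSpec,
    full_grid,
    grid_search,
    make_folds,
    nested_cv,
    performance_metrics,
    reduced_grid,
    repeat_and_average,
    svr_fit,
    svr_predict,
)


class TestGrids:
    def test_full_grid_cardinality_from_printed_ranges(self):
        # 21 powers of C (2^-5 .. 2^15) x 21 powers of gamma (2^-15 .. 2^5)
        grid = full_grid()
        assert len(grid) == 441
        assert min(s.C for s in grid) == 2.0**-5
        assert max(s.C for s in grid) == 2.0**15
        assert min(s.gamma for s in grid) == 2.0**-15
        assert max(s.gamma for s in grid) == 2.0**5

    def test_reduced_grid_within_printed_ranges(self):
        for s in reduced_grid():
            assert 2.0**-5 <= s.C <= 2.0**15
            assert 2.0**-15 <= s.gamma <= 2.0**5

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SvrSpec(C=-1, gamma=0.5)


class TestSvr:
    def test_constant_target_predicted_within_epsilon(self, rng):
        X = rng.random((20, 3))
        y = np.full(20, 0.4)
        model = svr_fit(X, y, SvrSpec(C=10, gamma=1, epsilon=0.1))
        np.testing.assert_allclose(svr_predict(model, X), 0.4, atol=0.1 + 1e-9)

    def test_epsilon_tube_on_smooth_function(self):
        # noiseless smooth 1-D target with generous C: training residuals
        # bounded by the epsilon insensitivity width
        x = np.linspace(0, 1, 40)[:, None]
        y = 0.5 + 0.3 * np.sin(2 * np.pi * x[:, 0])
        model = svr_fit(x, y, SvrSpec(C=1000, gamma=10, epsilon=0.05))
        assert np.abs(svr_predict(model, x) - y).max() <= 0.05 + 1e-3

    def test_duplicated_rows_do_not_change_predictions(self, rng):
        # multiset invariance holds when no dual variable sits at the box
        # bound, i.e. with C generous relative to the (smooth) target
        x = np.linspace(0, 1, 15)[:, None]
        y = 0.5 + 0.3 * np.sin(2 * np.pi * x[:, 0])
        spec = SvrSpec(C=1000, gamma=5, epsilon=0.05)
        base = svr_predict(svr_fit(x, y, spec), x)
        doubled = svr_predict(svr_fit(np.vstack([x, x]), np.hstack([y, y]), spec), x)
        np.testing.assert_allclose(doubled, base, atol=1e-4)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            svr_fit(np.array([[0.5]]), np.array([0.5]), SvrSpec(C=1, gamma=1))


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([0.1, 0.4, 0.9, 0.3])
        m = performance_metrics(y, y)
        assert m == pytest.approx((0.0, 0.0, 1.0, 1.0))

    def test_predicting_the_mean_gives_r_squared_zero(self):
        y = np.array([0.0, 0.5, 1.0, 0.5])
        m = performance_metrics(y, np.full(4, y.mean()))
        assert m.r_squared == pytest.approx(0.0)

    def test_worse_than_mean_is_negative(self):
        y = np.array([0.0, 0.5, 1.0])
        m = performance_metrics(y, np.array([1.0, 0.5, 0.0]))
        assert m.r_squared < 0

    def test_restricted_to_eval_mask(self, rng):
        y = rng.random(10)
        pred = y.copy()
        mask = np.zeros(10, bool)
        mask[:4] = True
        pred[~mask] = 99.0  # wildly wrong outside the mask
        m = performance_metrics(y, pred, mask)
        assert m.mse_mean == 0.0 and m.r_squared == 1.0

    def test_mse_sd_is_sd_of_squared_errors(self, rng):
        y, pred = rng.random(8), rng.random(8)
        m = performance_metrics(y, pred)
        sq = (y - pred) ** 2
        assert m.mse_mean == pytest.approx(sq.mean())
        assert m.mse_sd == pytest.approx(sq.std(ddof=1))

    def test_zero_variance_actual_rejected(self):
        with pytest.raises(ValueError):
            performance_metrics(np.full(5, 0.5), np.zeros(5))


class TestFolds:
    def test_folds_partition_all_patients(self, rng):
        folds = make_folds(23, 5, rng)
        all_idx = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(all_idx, np.arange(23))

    def test_stratified_folds_spread_small_strata(self, rng):
        strata = np.array(["chronic"] * 10 + ["recovered"] * 30 + ["control"] * 30)
        folds = make_folds(70, 5, rng, strata=strata)
        for fold in folds:
            assert (strata[fold] == "chronic").sum() == 2

    def test_every_fold_contains_eval_patient(self, rng):
        eval_mask = np.zeros(40, bool)
        eval_mask[:10] = True
        folds = make_folds(40, 5, rng, eval_mask=eval_mask)
        assert all(eval_mask[f].any() for f in folds)

    def test_impossible_eval_composition_raises(self, rng):
        eval_mask = np.zeros(20, bool)
        eval_mask[0] = True  # one eval patient cannot cover 5 folds
        with pytest.raises(FoldCompositionError):
            make_folds(20, 5, rng, eval_mask=eval_mask)


def linear_problem(n=72, n_eval=42, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.random((n, 1))
    y = X[:, 0].copy()
    eval_mask = np.zeros(n, bool)
    eval_mask[:n_eval] = True
    return X, y, eval_mask


class TestGridSearch:
    def test_single_point_grid_returns_it(self, rng):
        X, y, mask = linear_problem()
        spec = SvrSpec(C=1, gamma=1)
        plan = CVPlan(grid=(spec,), n_repetitions=1)
        assert grid_search(X, y, mask, plan, rng) == spec

    def test_selected_spec_minimizes_inner_mse(self):
        X, y, mask = linear_problem(seed=3)
        plan = CVPlan(grid=tuple(reduced_grid()), n_repetitions=1)
        # replicate the inner split deterministically and check argmin
        best = grid_search(X, y, mask, plan, np.random.default_rng(42))
        folds = make_folds(len(y), plan.inner_folds, np.random.default_rng(42),
                           eval_mask=mask)
        mses = {}
        for spec in sorted(plan.grid):
            errs = []
            for f, val in enumerate(folds):
                train = np.concatenate([folds[g] for g in range(4) if g != f])
                val_eval = val[mask[val]]
                model = svr_fit(X[train], y[train], spec)
                errs.append((svr_predict(model, X[val_eval]) - y[val_eval]) ** 2)
            mses[spec] = float(np.concatenate(errs).mean())
        assert mses[best] == min(mses.values())

    def test_tie_break_prefers_smallest_c_then_gamma(self, rng):
        # constant target: every grid point predicts it within epsilon, so
        # all MSEs tie and the smallest (C, gamma) must win
        X = np.random.default_rng(1).random((24, 2))
        y = np.full(24, 0.5)
        mask = np.ones(24, bool)
        grid = (SvrSpec(4, 4), SvrSpec(0.5, 8), SvrSpec(0.5, 2), SvrSpec(2, 1))
        best = grid_search(X, y, mask, CVPlan(grid=grid, n_repetitions=1), rng)
        assert best == SvrSpec(0.5, 2)


class TestNestedCV:
    def test_each_patient_predicted_exactly_once(self, rng):
        X, y, mask = linear_problem()
        plan = CVPlan(grid=(SvrSpec(1, 1),), n_repetitions=1)
        preds, chosen = nested_cv(X, y, mask, plan, rng)
        assert preds.shape == (72,)
        assert not np.isnan(preds).any()
        assert len(chosen) == plan.outer_folds

    def test_no_test_patient_in_its_own_training_folds(self, monkeypatch, rng):
        X, y, mask = linear_problem(n=30, n_eval=20)
        plan = CVPlan(grid=(SvrSpec(1, 1),), n_repetitions=1, outer_folds=3)
        train_rows: list[np.ndarray] = []
        import neglectprog.engine as engine

        real_fit = engine.svr_fit

        def spy(Xtr, ytr, spec):
            train_rows.append(np.asarray(Xtr))
            return real_fit(Xtr, ytr, spec)

        monkeypatch.setattr(engine, "svr_fit", spy)
        preds, _ = engine.nested_cv(X, y, mask, plan, rng)
        # outer-fold fits are the largest training sets; confirm the rows of
        # each held-out patient never appear in the fold that predicted it
        outer_fits = [t for t in train_rows if len(t) == 20]
        assert len(outer_fits) == 3
        for t in outer_fits:
            held_out = [i for i in range(30)
                        if not (np.isclose(t, X[i]).all(axis=1)).any()]
            assert len(held_out) == 10

    def test_noiseless_linear_target_recovered(self):
        X, y, mask = linear_problem(seed=5)
        plan = CVPlan(grid=tuple(reduced_grid()), n_repetitions=1)
        preds, _ = nested_cv(X, y, mask, plan, np.random.default_rng(8))
        m = performance_metrics(y, preds, mask)
        assert m.r_squared >= 0.9

    def test_bit_identical_across_runs_with_same_seed(self):
        X, y, mask = linear_problem(seed=2)
        plan = CVPlan(grid=tuple(reduced_grid())[:5], n_repetitions=2, seed=3)
        r1 = repeat_and_average(X, y, mask, plan)
        r2 = repeat_and_average(X, y, mask, plan)
        np.testing.assert_array_equal(r1.predictions, r2.predictions)
        assert r1.metrics == r2.metrics


class TestRepetitionAveraging:
    def test_single_repetition_averaging_is_identity(self):
        X, y, mask = linear_problem(seed=4)
        plan = CVPlan(grid=(SvrSpec(1, 1),), n_repetitions=1, seed=9)
        res = repeat_and_average(X, y, mask, plan)
        np.testing.assert_array_equal(res.predictions, res.per_repetition[0])

    def test_identical_repetition_seeds_collapse_to_one(self):
        X, y, mask = linear_problem(seed=4)
        plan = CVPlan(grid=(SvrSpec(1, 1),), n_repetitions=3,
                      repetition_seeds=(7, 7, 7))
        res = repeat_and_average(X, y, mask, plan)
        for rep in res.per_repetition:
            np.testing.assert_array_equal(rep, res.per_repetition[0])
        # averaging identical repetitions is the identity up to float summation
        np.testing.assert_allclose(res.predictions, res.per_repetition[0], rtol=1e-12)

    def test_averaging_reduces_variance(self):
        rng = np.random.default_rng(0)
        X = rng.random((60, 2))
        y = np.clip(X[:, 0] * 0.5 + rng.normal(0, 0.2, 60), 0, 1)
        mask = np.ones(60, bool)
        plan = CVPlan(grid=tuple(reduced_grid())[:8], n_repetitions=5, seed=2)
        res = repeat_and_average(X, y, mask, plan)
        sq_avg = ((res.predictions - y) ** 2).mean()
        sq_each = ((res.per_repetition - y) ** 2).mean(axis=1)
        assert sq_avg <= sq_each.mean() + 1e-12
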