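import numpy as np
import pandas as pd
import pytest

from celldrift import (
    DriftDiffusionFit,
    PureDiffusionFit,
    compute_distances,
    f_test,
    fit_drift_diffusion,
    fit_drift_linear,
    fit_pure_diffusion,
    pool_subjects,
    population_summary,
)
from celldrift.errors import FitError, ValidationError
from celldrift.estimators import fits_to_frame
from celldrift.synthetic_data import PointInit, SimulationParams, simulate_cells
from celldrift.tracks import WoundGeometry

from conftest import make_series, make_summary


def normal_equations(y, X):
    """Hand-coded OLS oracle: solve X'X b = X'y, classical SEs."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    dof = len(y) - X.shape[1]
    sigma2 = rss / dof
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtX)))
    return beta, se, rss


class TestFitDriftLinear:
    def test_noiseless_line_exact(self):
        t = np.arange(0, 100, 10.0)
        mean = 100 - 0.35 * t
        ps = make_summary(t, mean, mean**2 + 1.0)
        fit = fit_drift_linear(ps)
        assert fit.v == pytest.approx(-0.35, abs=1e-12)
        assert fit.intercept == pytest.approx(100.0, abs=1e-9)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_constant_mean_gives_zero_drift(self):
        t = np.arange(0, 50, 10.0)
        ps = make_summary(t, np.full(t.size, 40.0), np.full(t.size, 1700.0))
        assert fit_drift_linear(ps).v == pytest.approx(0.0, abs=1e-12)

    def test_too_few_rows(self):
        ps = make_summary([0.0, 10.0], [1.0, 2.0], [2.0, 5.0])
        with pytest.raises(FitError, match=">= 3"):
            fit_drift_linear(ps)

    def test_identical_times_rejected(self):
        ps = make_summary([5.0], [1.0], [2.0])
        with pytest.raises(FitError):
            fit_drift_linear(ps)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(0, 100, 12))
        mean = 5 + 0.2 * t + rng.normal(0, 2, t.size)
        ps = make_summary(t, mean, mean**2 + 50.0)
        fit = fit_drift_linear(ps)
        beta, se, rss = normal_equations(mean, np.column_stack([np.ones_like(t), t]))
        assert fit.v == pytest.approx(beta[1], rel=1e-8)
        assert fit.v_se == pytest.approx(se[1], rel=1e-8)
        assert fit.rss == pytest.approx(rss, rel=1e-8)


class TestFitPureDiffusion:
    def test_noiseless_line_exact(self):
        t = np.arange(0, 100, 10.0)
        s = 1000 + 83.6 * t
        ps = make_summary(t, np.sqrt(s) * 0.9, s)
        fit = fit_pure_diffusion(ps)
        assert fit.D == pytest.approx(41.8, abs=1e-9)

    def test_constant_msd_gives_zero_D(self):
        t = np.arange(0, 50, 10.0)
        ps = make_summary(t, np.full(t.size, 3.0), np.full(t.size, 100.0))
        assert fit_pure_diffusion(ps).D == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(4)
        t = np.sort(rng.uniform(0, 200, 15))
        s = 300 + 60 * t + rng.normal(0, 40, t.size)
        ps = make_summary(t, np.sqrt(np.maximum(s, 0)) * 0.8, s)
        fit = fit_pure_diffusion(ps)
        beta, se, rss = normal_equations(s, np.column_stack([np.ones_like(t), t]))
        assert fit.D == pytest.approx(beta[1] / 2, rel=1e-8)
        assert fit.D_se == pytest.approx(se[1] / 2, rel=1e-8)
        assert fit.rss == pytest.approx(rss, rel=1e-8)


class TestFitDriftDiffusion:
    def test_noiseless_quadratic_exact(self):
        # s(t) = 16 t + 0.0676 t^2  ->  D = 8, v = 0.26 (increasing mean)
        t = np.arange(0, 200, 10.0)
        s = 16.0 * t + 0.0676 * t**2
        ps = make_summary(t, 0.26 * t, s)
        fit = fit_drift_diffusion(ps)
        assert fit.v == pytest.approx(0.26, abs=1e-9)
        assert fit.D == pytest.approx(8.0, abs=1e-9)

    def test_sign_follows_mean_distance_trend(self):
        t = np.arange(0, 200, 10.0)
        s = 1e5 - 16.0 * t + 0.09 * t**2
        ps = make_summary(t, 300 - 0.3 * t, s)
        assert fit_drift_diffusion(ps).v == pytest.approx(-0.3, abs=1e-9)

    def test_negative_quadratic_coefficient_gives_zero_v(self):
        t = np.arange(0, 200, 10.0)
        s = 1e5 + 50.0 * t - 0.01 * t**2
        ps = make_summary(t, 300 + 0.1 * t, s)
        fit = fit_drift_diffusion(ps)
        assert fit.v == 0.0
        assert np.isnan(fit.v_se)

    def test_unconstrained_D_may_be_negative(self):
        t = np.arange(0, 200, 10.0)
        s = 1e4 - 4.0 * t + 0.05 * t**2
        ps = make_summary(t, 10 + 0.01 * t, s)
        assert fit_drift_diffusion(ps).D == pytest.approx(-2.0, abs=1e-9)

    def test_too_few_rows(self):
        ps = make_summary([0.0, 10, 20], [1, 2, 3], [10, 20, 30])
        with pytest.raises(FitError, match=">= 4"):
            fit_drift_diffusion(ps)

    def test_collinear_design_rejected(self):
        ps = make_summary([0.0, 0.0, 10.0, 10.0], [1, 1, 2, 2], [10, 10, 20, 20])
        with pytest.raises(FitError, match="collinear|identical"):
            fit_drift_diffusion(ps)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(5)
        t = np.sort(rng.uniform(0, 300, 20))
        s = 100 + 30 * t + 0.04 * t**2 + rng.normal(0, 25, t.size)
        ps = make_summary(t, 1 + 0.2 * t, s)
        fit = fit_drift_diffusion(ps)
        X = np.column_stack([np.ones_like(t), t, t**2])
        beta, se, rss = normal_equations(s, X)
        assert fit.D == pytest.approx(beta[1] / 2, rel=1e-8)
        assert fit.v == pytest.approx(np.sqrt(beta[2]), rel=1e-8)
        assert fit.v_se == pytest.approx(se[2] / (2 * np.sqrt(beta[2])), rel=1e-8)
        assert fit.rss == pytest.approx(rss, rel=1e-8)

    def test_v_consistent_with_zero_under_pure_diffusion_truth(self):
        # beta2 = 0 in the population: v estimates are Monte-Carlo noise
        # (v = sqrt(beta2) folds the noise, so compare to the replicate
        # spread rather than an absolute threshold)
        from celldrift.synthetic_data import replicate_seeds

        wound = WoundGeometry((0, 0), (0, 1), 1)
        ests = []
        for s in replicate_seeds(21, 8):
            p = SimulationParams(v=0.0, D=30.0, n_cells=2000, seed=int(s),
                                 times=np.arange(0, 481, 20.0))
            ps = population_summary(compute_distances(simulate_cells(p), wound))
            ests.append(fit_drift_diffusion(ps).v)
        ests = np.asarray(ests)
        assert abs(ests.mean()) <= 3 * ests.std(ddof=1)
        assert np.abs(ests).max() < 0.26 / 2  # far below the real drift scale


class TestFTest:
    def test_equal_rss_gives_zero(self):
        pure = PureDiffusionFit(D=1, D_se=0.1, intercept=0, rss=50.0, n=23)
        dd = DriftDiffusionFit(v=0, D=1, v_se=0.1, D_se=0.1, intercept=0,
                               rss=50.0, n=23)
        res = f_test(pure, dd)
        assert res.F == 0.0
        assert not res.prefer_drift

    def test_arithmetic_example(self):
        # rss_pure = 2 rss_dd, n = 23 -> F = (100-50)/(50/20) = 20
        pure = PureDiffusionFit(D=1, D_se=0.1, intercept=0, rss=100.0, n=23)
        dd = DriftDiffusionFit(v=0, D=1, v_se=0.1, D_se=0.1, intercept=0,
                               rss=50.0, n=23)
        res = f_test(pure, dd)
        assert res.F == pytest.approx(20.0)
        assert res.df1 == 1 and res.df2 == 20
        assert res.prefer_drift

    def test_mismatched_n_rejected(self):
        pure = PureDiffusionFit(D=1, D_se=0.1, intercept=0, rss=100.0, n=23)
        dd = DriftDiffusionFit(v=0, D=1, v_se=0.1, D_se=0.1, intercept=0,
                               rss=50.0, n=22)
        with pytest.raises(ValidationError, match="different"):
            f_test(pure, dd)

    def test_n_too_small_rejected(self):
        pure = PureDiffusionFit(D=1, D_se=0.1, intercept=0, rss=100.0, n=3)
        dd = DriftDiffusionFit(v=0, D=1, v_se=0.1, D_se=0.1, intercept=0,
                               rss=50.0, n=3)
        with pytest.raises(FitError):
            f_test(pure, dd)

    def test_nesting_on_fit_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            t = np.arange(0, 200, 10.0)
            s = 500 + 20 * t + rng.normal(0, 30, t.size)
            ps = make_summary(t, 1 + 0.1 * t, s + (1 + 0.1 * t) ** 2)
            pure = fit_pure_diffusion(ps)
            dd = fit_drift_diffusion(ps)
            assert dd.rss <= pure.rss + 1e-9
            assert f_test(pure, dd).F >= -1e-12


class TestSignConvention:
    def test_toward_wound_negative_away_positive(self):
        wound = WoundGeometry((0, 0), (0, 1), 1)
        base = dict(D=10.0, n_cells=500, seed=17,
                    times=np.arange(0, 241, 10.0), init=PointInit(500.0))
        for v_true in (-0.4, 0.4):
            p = SimulationParams(v=v_true, **base)
            ps = population_summary(compute_distances(simulate_cells(p), wound))
            assert np.sign(fit_drift_linear(ps).v) == np.sign(v_true)
            assert np.sign(fit_drift_diffusion(ps).v) == np.sign(v_true)


class TestPoolSubjects:
    def test_self_pool_doubles_counts_keeps_means(self):
        ds = make_series(["a", "b"], [0.0, 0.0], [10.0, 30.0])
        pooled = pool_subjects([ds, ds])
        ps = population_summary(pooled)
        assert ps.rows.iloc[0]["n_cells"] == 4
        assert ps.rows.iloc[0]["mean_dist"] == pytest.approx(20.0)

    def test_two_single_cell_series(self):
        a = make_series(["a"], [0.0], [10.0])
        b = make_series(["a"], [0.0], [30.0])
        ps = population_summary(pool_subjects([a, b]))
        assert ps.rows.iloc[0]["mean_dist"] == pytest.approx(20.0)

    def test_namespacing_avoids_collisions(self):
        a = make_series(["a"], [0.0], [10.0])
        pooled = pool_subjects([a, a])
        assert len(pooled) == 2
        assert len(set(pooled.data["cell_id"])) == 2

    def test_incompatible_grids_rejected(self):
        a = make_series(["a", "a"], [0.0, 10.0], [1.0, 2.0])
        b = make_series(["b", "b"], [0.0, 13.0], [1.0, 2.0])
        with pytest.raises(ValidationError, match="grid"):
            pool_subjects([a, b], tolerance=1.0)

    def test_nearest_time_alignment_within_tolerance(self):
        a = make_series(["a", "a"], [0.0, 10.0], [1.0, 2.0])
        b = make_series(["b", "b"], [0.2, 9.9], [3.0, 4.0])
        pooled = pool_subjects([a, b], tolerance=0.5)
        assert set(pooled.times) == {0.0, 10.0}

    def test_matches_concatenate_oracle(self):
        rng = np.random.default_rng(8)
        series = []
        t = np.arange(0, 40, 10.0)
        for s in range(3):
            n = rng.integers(2, 6)
            ids = np.repeat([f"c{i}" for i in range(n)], t.size)
            times = np.tile(t, n)
            series.append(make_series(ids, times, rng.uniform(0, 100, n * t.size)))
        pooled = population_summary(pool_subjects(series))
        # oracle: concatenate all distances then summarise per time with a loop
        alld = np.concatenate([ds.data["distance_um"].to_numpy() for ds in series])
        allt = np.concatenate([ds.data["time_min"].to_numpy() for ds in series])
        for _, row in pooled.rows.iterrows():
            vals = alld[allt == row["time_min"]]
            assert row["n_cells"] == len(vals)
            assert row["mean_dist"] == pytest.approx(vals.mean())
            assert row["mean_sq_dist"] == pytest.approx((vals**2).mean())

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            pool_subjects([])


def test_fits_to_frame_handles_missing_fits():
    pure = PureDiffusionFit(D=1, D_se=0.1, intercept=0, rss=100.0, n=23)
    frame = fits_to_frame([("s1", None, pure, None, None)])
    assert frame.loc[0, "subject"] == "s1"
    assert frame.loc[0, "pure_D"] == 1
    assert "dd_v" not in frame.columns or pd.isna(frame.loc[0, "dd_v"])
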