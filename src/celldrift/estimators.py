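"""Regression estimators for drift and diffusion coefficients.

Three models are fitted to the per-timepoint population moments:

* mean distance vs time, linear  -> drift coefficient ``v`` (slope);
* mean squared distance vs time, linear -> pure-diffusion ``D`` (the
  1-D relation MSD slope = 2D);
* mean squared distance vs time, quadratic -> drift-diffusion ``(v, D)``
  with ``v**2`` the quadratic coefficient and ``2D`` the linear one.

The quadratic coefficient only determines ``v`` up to sign, so the sign
is taken from the trend of the mean distance.  ``D`` is deliberately not
constrained to be non-negative: the fits are plain unweighted OLS, so a
noisy concave-up MSD curve can produce a negative ``D`` estimate.

The nested comparison of the two MSD models is a one-degree-of-freedom
F-test on residual sums of squares with a configurable decision
threshold (default 5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from celldrift.errors import FitError, ValidationError
from celldrift.tracks import DistanceSeries, PopulationSummary


@dataclass(frozen=True)
class DriftFit:
    """Linear fit of mean distance vs time.

    ``v`` is the slope in μm/min; negative values mean net motion
    toward the wound.
    """

    v: float
    intercept: float
    v_se: float
    rss: float
    n: int


@dataclass(frozen=True)
class PureDiffusionFit:
    """Linear fit of mean squared distance vs time; D = slope / 2 (μm²/min)."""

    D: float
    D_se: float
    intercept: float
    rss: float
    n: int


@dataclass(frozen=True)
class DriftDiffusionFit:
    """Quadratic fit of mean squared distance vs time.

    ``v = sign(mean-distance trend) * sqrt(max(beta2, 0))`` in μm/min;
    ``D = beta1 / 2`` in μm²/min (may be negative, see module docstring).
    ``v_se`` is the delta-method standard error ``se(beta2)/(2 sqrt(beta2))``
    and is NaN when ``beta2 <= 0``.
    """

    v: float
    D: float
    v_se: float
    D_se: float
    intercept: float
    rss: float
    n: int


@dataclass(frozen=True)
class FTestResult:
    """Nested-model F statistic comparing the two MSD fits.

    ``F = (rss_pure - rss_dd) / (rss_dd / (n - 3))`` with 1 and n-3
    degrees of freedom; ``prefer_drift`` is True when F exceeds the
    decision threshold.
    """

    F: float
    df1: int
    df2: int
    threshold: float
    prefer_drift: bool


def _ols(y: np.ndarray, X: np.ndarray):
    model = sm.OLS(y, X)
    res = model.fit()
    return res.params, res.bse, float(res.ssr)


def _check_summary(ps: PopulationSummary, min_rows: int) -> None:
    if len(ps) < min_rows:
        raise FitError(f"need >= {min_rows} summary rows, got {len(ps)}")
    t = ps.time
    if np.ptp(t) == 0:
        raise FitError("all observation times identical; slope undefined")


def fit_drift_linear(ps: PopulationSummary) -> DriftFit:
    """OLS of mean distance on time; the slope is the drift coefficient."""
    _check_summary(ps, 3)
    t = ps.time
    X = sm.add_constant(t)
    params, bse, rss = _ols(ps.mean_dist, X)
    return DriftFit(
        v=float(params[1]),
        intercept=float(params[0]),
        v_se=float(bse[1]),
        rss=rss,
        n=len(ps),
    )


def fit_pure_diffusion(ps: PopulationSummary) -> PureDiffusionFit:
    """OLS of mean squared distance on time; D is half the slope."""
    _check_summary(ps, 3)
    t = ps.time
    X = sm.add_constant(t)
    params, bse, rss = _ols(ps.mean_sq_dist, X)
    return PureDiffusionFit(
        D=float(params[1]) / 2.0,
        D_se=float(bse[1]) / 2.0,
        intercept=float(params[0]),
        rss=rss,
        n=len(ps),
    )


def fit_drift_diffusion(ps: PopulationSummary) -> DriftDiffusionFit:
    """OLS of mean squared distance on {1, t, t²}.

    The drift magnitude comes from the quadratic coefficient, its sign
    from the mean-distance trend; D is half the linear coefficient.
    """
    _check_summary(ps, 4)
    t = ps.time
    X = np.column_stack([np.ones_like(t), t, t**2])
    if np.linalg.matrix_rank(X) < 3:
        raise FitError("collinear design: need >= 3 distinct times")
    params, bse, rss = _ols(ps.mean_sq_dist, X)
    beta1, beta2 = float(params[1]), float(params[2])
    trend = fit_drift_linear(ps).v
    sign = -1.0 if trend < 0 else 1.0
    if beta2 > 0:
        v = sign * float(np.sqrt(beta2))
        v_se = float(bse[2]) / (2.0 * float(np.sqrt(beta2)))
    else:
        v, v_se = 0.0, float("nan")
    return DriftDiffusionFit(
        v=v,
        D=beta1 / 2.0,
        v_se=v_se,
        D_se=float(bse[1]) / 2.0,
        intercept=float(params[0]),
        rss=rss,
        n=len(ps),
    )


def f_test(
    pure: PureDiffusionFit, dd: DriftDiffusionFit, threshold: float = 5.0
) -> FTestResult:
    """Nested F-test of the quadratic MSD model against the linear one."""
    if pure.n != dd.n:
        raise ValidationError(
            f"fits computed on different summaries: n={pure.n} vs n={dd.n}"
        )
    n = dd.n
    if n <= 3:
        raise FitError("F-test needs n > 3 (df2 = n - 3 >= 1)")
    if dd.rss == 0.0:
        F = float("inf") if pure.rss > 0.0 else 0.0
    else:
        F = (pure.rss - dd.rss) / (dd.rss / (n - 3))
    return FTestResult(
        F=float(F),
        df1=1,
        df2=n - 3,
        threshold=float(threshold),
        prefer_drift=bool(F > threshold),
    )


def pool_subjects(
    series: Sequence[DistanceSeries], tolerance: float = 1e-6
) -> DistanceSeries:
    """Pool several subjects' distance series into one cell population.

    Cell ids are namespaced by subject index so identical ids in
    different subjects stay distinct.  Observation times of every series
    are snapped to the first series' grid; a time farther than
    ``tolerance`` minutes from any grid point is an error.
    """
    if not series:
        raise ValidationError("nothing to pool")
    grid = series[0].times
    frames = []
    for i, ds in enumerate(series):
        df = ds.data.copy()
        if len(df):
            idx = np.searchsorted(grid, df["time_min"].to_numpy())
            idx = np.clip(idx, 0, len(grid) - 1)
            left = np.clip(idx - 1, 0, len(grid) - 1)
            nearer_left = np.abs(grid[left] - df["time_min"].to_numpy()) <= np.abs(
                grid[idx] - df["time_min"].to_numpy()
            )
            idx = np.where(nearer_left, left, idx)
            off = np.abs(grid[idx] - df["time_min"].to_numpy())
            if (off > tolerance).any():
                t_bad = float(df["time_min"].to_numpy()[off.argmax()])
                raise ValidationError(
                    f"subject {i}: time {t_bad} min is {off.max():.3g} min from "
                    f"the reference grid (tolerance {tolerance})"
                )
            df["time_min"] = grid[idx]
        df["cell_id"] = [f"s{i}:{c}" for c in df["cell_id"]]
        frames.append(df)
    return DistanceSeries(pd.concat(frames, ignore_index=True))


def fits_to_frame(
    rows: Sequence[tuple[str, DriftFit | None, PureDiffusionFit | None, DriftDiffusionFit | None, FTestResult | None]],
) -> pd.DataFrame:
    """Flatten fit results into a per-subject report table.

    Each input row is ``(subject, drift_fit, pure_fit, dd_fit, ftest)``
    with ``None`` for anything that could not be computed; the output
    mirrors a coefficients-table layout (one row per subject).
    """
    out = []
    for subject, drift, pure, dd, ft in rows:
        rec: dict = {"subject": subject}
        if drift is not None:
            rec.update(
                drift_v=drift.v, drift_v_se=drift.v_se,
                drift_rss=drift.rss, drift_n=drift.n,
            )
        if pure is not None:
            rec.update(
                pure_D=pure.D, pure_D_se=pure.D_se,
                pure_rss=pure.rss, pure_n=pure.n,
            )
        if dd is not None:
            rec.update(
                dd_v=dd.v, dd_v_se=dd.v_se, dd_D=dd.D, dd_D_se=dd.D_se,
                dd_rss=dd.rss, dd_n=dd.n,
            )
        if ft is not None:
            rec.update(F=ft.F, df1=ft.df1, df2=ft.df2, prefer_drift=ft.prefer_drift)
        out.append(rec)
    return pd.DataFrame(out)
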