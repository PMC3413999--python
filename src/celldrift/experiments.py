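"""Reusable synthetic-benchmark workflows.

These glue the simulator and estimators into the replicated experiments
used for parameter-recovery checks and F-test behaviour studies:
simulate a cohort, push it through the full track pipeline
(distances -> population summary), fit, repeat.

The null-calibration experiment needs independent, equal-variance
observations per timepoint (the OLS F-test's premise).  Full simulated
trajectories cannot provide that — the population's mean squared
distance is a sum over persistent random walks, so its deviations are
strongly autocorrelated in time and the nominal F distribution does not
apply to them.  ``null_f_statistics`` therefore draws an independent
cohort for every timepoint and sizes it as n_t ∝ t², which exactly
equalises Var[s(t)] = 2 (2 D t)² / n_t for cells released at the wound.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from celldrift.estimators import f_test, fit_drift_diffusion, fit_pure_diffusion
from celldrift.synthetic_data import (
    PointInit,
    SimulationParams,
    replicate_seeds,
    simulate_cells,
    simulate_positions,
)
from celldrift.tracks import (
    PopulationSummary,
    WoundGeometry,
    compute_distances,
    population_summary,
)

#: Wound along the y axis with tissue at positive x; recovers the
#: simulator's 1-D distance coordinate exactly.
AXIS_WOUND = WoundGeometry(p1=(0.0, 0.0), p2=(0.0, 1.0), interior_sign=1)


def pipeline_summary(p: SimulationParams) -> PopulationSummary:
    """simulate -> compute_distances -> population_summary."""
    return population_summary(compute_distances(simulate_cells(p), AXIS_WOUND))


def replicate_estimates(
    p: SimulationParams,
    n_reps: int,
    estimate: Callable[[PopulationSummary], float],
) -> np.ndarray:
    """Run ``estimate`` on ``n_reps`` independent pipeline replicates."""
    seeds = replicate_seeds(p.seed, n_reps)
    return np.array(
        [estimate(pipeline_summary(replace(p, seed=int(s)))) for s in seeds]
    )


def nested_f(ps: PopulationSummary) -> float:
    """F statistic of the quadratic vs linear MSD fit on one summary."""
    return f_test(fit_pure_diffusion(ps), fit_drift_diffusion(ps)).F


def null_f_statistics(
    D: float,
    times: Sequence[float],
    base_cells: int,
    n_reps: int,
    seed: int,
    substeps: int = 4,
) -> np.ndarray:
    """F statistics under the zero-drift null with iid summary noise.

    Each timepoint t gets an independent cohort of
    ``base_cells * (t / t_min)**2`` cells released at the wound and
    observed only at t, so the per-timepoint mean squared distances are
    independent with equal variance (see module docstring).  Returned
    array has one F statistic per replicate.
    """
    times = np.asarray(times, dtype=float)
    if (times <= 0).any():
        raise ValueError("calibration times must be positive")
    rep_seeds = replicate_seeds(seed, n_reps)
    out = np.empty(n_reps)
    for r, rs in enumerate(rep_seeds):
        t_seeds = np.random.SeedSequence(int(rs)).generate_state(times.size)
        rows = []
        for t, ts in zip(times, t_seeds):
            n_t = max(4, int(round(base_cells * (t / times[0]) ** 2)))
            p = SimulationParams(
                v=0.0, D=D, n_cells=n_t, seed=int(ts),
                times=np.array([0.0, t]), init=PointInit(0.0),
                substeps=substeps,
            )
            x = simulate_positions(p)[:, -1]
            rows.append((t, n_t, x.mean(), float(np.mean(x**2))))
        ps = PopulationSummary(
            pd.DataFrame(
                rows, columns=["time_min", "n_cells", "mean_dist", "mean_sq_dist"]
            )
        )
        out[r] = nested_f(ps)
    return out
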