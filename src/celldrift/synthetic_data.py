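"""Synthetic track generation from a 1-D reflected drift-diffusion walk.

Cells live on the non-negative distance-from-wound coordinate.  Between
consecutive observation times each cell takes Gaussian increments

    x <- | x + v dt + sqrt(2 D dt) xi |,   xi ~ N(0, 1),

split into ``substeps`` equal sub-intervals so the reflecting boundary
at the wound (x = 0) is honoured within observation intervals, not just
at observation times.  Simulated cells are emitted as 2-D track records
with y = 0, so applying a wound line x = 0 downstream recovers the 1-D
coordinate exactly.

Randomness is fully determined by an integer seed; ensemble replicates
derive per-replicate seeds from the master seed via
``numpy.random.SeedSequence(seed).generate_state(n_reps)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np
import pandas as pd

from celldrift.errors import ValidationError
from celldrift.tracks import ObservationSet


@dataclass(frozen=True)
class UniformInit:
    """Initial distances drawn uniformly from [low, high) μm."""

    low: float = 0.0
    high: float = 80.0

    def __post_init__(self) -> None:
        if not (0 <= self.low < self.high):
            raise ValidationError("uniform init needs 0 <= low < high")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.low, self.high, size=n)


@dataclass(frozen=True)
class PointInit:
    """All cells start at distance x0 μm."""

    x0: float = 0.0

    def __post_init__(self) -> None:
        if self.x0 < 0:
            raise ValidationError("point init needs x0 >= 0")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.full(n, float(self.x0))


Init = Union[UniformInit, PointInit]


def default_times(t_end: float = 960.0, dt: float = 10.0) -> np.ndarray:
    """Default observation grid: every ``dt`` minutes from 0 to ``t_end``."""
    return np.arange(0.0, t_end + dt / 2, dt)


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of one simulated cohort.

    ``v`` is the signed drift (μm/min; negative = toward the wound),
    ``D`` the diffusion coefficient (μm²/min, must be >= 0 to simulate).
    ``dropout_rate`` is the per-observation probability that a cell goes
    unrecorded at a timepoint, mimicking sparse late frames.
    """

    v: float
    D: float
    n_cells: int
    times: np.ndarray = field(default_factory=default_times)
    init: Init = field(default_factory=UniformInit)
    dropout_rate: float = 0.0
    seed: int = 0
    substeps: int = 10
    channel: str = "photoconverted"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        if times.size == 0:
            raise ValidationError("empty observation time grid")
        if times.size > 1 and not (np.diff(times) > 0).all():
            raise ValidationError("observation times must be strictly increasing")
        object.__setattr__(self, "times", times)
        if self.D < 0:
            raise ValidationError("D must be >= 0 for simulation")
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")
        if not (0 <= self.dropout_rate < 1):
            raise ValidationError("dropout_rate must be in [0, 1)")
        if self.substeps < 1:
            raise ValidationError("substeps must be >= 1")


def simulate_positions(p: SimulationParams) -> np.ndarray:
    """Simulate distance trajectories, shape (n_cells, n_times).

    Low-level path used by :func:`simulate_cells`; no dropout is applied
    here (dropout only removes records, never alters dynamics).
    """
    rng = np.random.default_rng(p.seed)
    x = p.init.draw(p.n_cells, rng)
    out = np.empty((p.n_cells, p.times.size))
    out[:, 0] = x
    for k in range(1, p.times.size):
        dt_sub = (p.times[k] - p.times[k - 1]) / p.substeps
        drift = p.v * dt_sub
        sd = np.sqrt(2.0 * p.D * dt_sub)
        for _ in range(p.substeps):
            if sd > 0:
                x = x + drift + sd * rng.standard_normal(p.n_cells)
            else:
                x = x + drift
            x = np.abs(x)  # reflect at the wound
        out[:, k] = x
    return out


def simulate_cells(p: SimulationParams) -> ObservationSet:
    """Simulate a cohort and emit it as a track table.

    Records carry x = simulated distance, y = 0; identical parameters
    (including ``seed``) give identical output.
    """
    pos = simulate_positions(p)
    # dropout mask drawn from a child stream so the dynamics above are
    # unchanged by the dropout setting
    if p.dropout_rate > 0:
        drop_rng = np.random.default_rng(
            np.random.SeedSequence([int(p.seed), 0xD120]).generate_state(1)[0]
        )
        keep = drop_rng.random(pos.shape) >= p.dropout_rate
    else:
        keep = np.ones(pos.shape, dtype=bool)
    cell_idx, time_idx = np.nonzero(keep)
    width = len(str(max(p.n_cells - 1, 1)))
    ids = np.array([f"c{i:0{width}d}" for i in range(p.n_cells)])
    df = pd.DataFrame(
        {
            "cell_id": ids[cell_idx],
            "time_min": p.times[time_idx],
            "x_um": pos[cell_idx, time_idx],
            "y_um": 0.0,
            "channel": p.channel,
        }
    )
    return ObservationSet(df)


def replicate_seeds(master_seed: int, n_reps: int) -> np.ndarray:
    """Deterministic per-replicate seeds derived from a master seed."""
    return np.random.SeedSequence(master_seed).generate_state(n_reps)


def simulate_ensemble(p: SimulationParams, n_reps: int) -> list[ObservationSet]:
    """``n_reps`` independent replicates of :func:`simulate_cells`.

    Replicate ``i`` uses the i-th derived seed of ``p.seed``; the whole
    ensemble is bit-reproducible from ``(p, n_reps)``.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    seeds = replicate_seeds(p.seed, n_reps)
    return [simulate_cells(replace(p, seed=int(s))) for s in seeds]
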