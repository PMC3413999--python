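"""Track tables, wound geometry, and population summaries.

The canonical track table is a long-format CSV with header
``cell_id,time_min,x_um,y_um,channel`` where ``channel`` is ``red``
(photoconverted) or ``green`` (nonphotoconverted).  All positions are in
micrometres; times are minutes from the start of observation.

Distances from the wound are perpendicular distances to a straight
wound-edge line, clamped at zero on the wound side, so downstream
modelling lives on a single non-negative coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from celldrift.errors import FormatError, ValidationError

#: Column order of the canonical track CSV dialect.
TRACK_COLUMNS = ("cell_id", "time_min", "x_um", "y_um", "channel")

#: Internal channel labels keyed by the CSV colour labels.
CSV_TO_CHANNEL = {"red": "photoconverted", "green": "nonphotoconverted"}
CHANNEL_TO_CSV = {v: k for k, v in CSV_TO_CHANNEL.items()}
CHANNELS = tuple(CSV_TO_CHANNEL.values())


def _canonical(df: pd.DataFrame) -> pd.DataFrame:
    df = df.loc[:, list(TRACK_COLUMNS)].copy()
    df["time_min"] = df["time_min"].astype(float)
    df["x_um"] = df["x_um"].astype(float)
    df["y_um"] = df["y_um"].astype(float)
    return df.sort_values(["cell_id", "time_min"], kind="mergesort").reset_index(
        drop=True
    )


@dataclass(frozen=True, eq=False)
class ObservationSet:
    """Validated long-format table of cell centroid observations.

    One row per (cell, timepoint): ``cell_id``, ``time_min``, ``x_um``,
    ``y_um``, ``channel``.  Rows are kept in canonical (cell_id, time)
    order; each (cell_id, time) pair occurs at most once and all
    coordinates are finite.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in TRACK_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing column(s): {', '.join(missing)}")
        df = _canonical(df)
        if not np.isfinite(df["x_um"]).all() or not np.isfinite(df["y_um"]).all():
            raise ValidationError("non-finite coordinate in observation set")
        if df.duplicated(subset=["cell_id", "time_min"]).any():
            dup = df[df.duplicated(subset=["cell_id", "time_min"])].iloc[0]
            raise ValidationError(
                f"duplicate observation for cell {dup['cell_id']!r} "
                f"at t={dup['time_min']} min"
            )
        bad = set(df["channel"].unique()) - set(CHANNELS)
        if bad:
            raise ValidationError(
                f"unknown channel label(s) {sorted(bad)}; expected one of {CHANNELS}"
            )
        object.__setattr__(self, "data", df)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def times(self) -> np.ndarray:
        """Sorted unique observation times (minutes)."""
        return np.sort(self.data["time_min"].unique())

    @property
    def cell_ids(self) -> list:
        return sorted(self.data["cell_id"].unique())

    def equals(self, other: "ObservationSet") -> bool:
        """Field-by-field equality on the canonical representation."""
        return self.data.equals(other.data)


@dataclass(frozen=True)
class WoundGeometry:
    """Wound edge as an infinite straight line through ``p1`` and ``p2``.

    ``interior_sign`` selects the tissue side of the line.  With the
    line's direction ``d = p2 - p1``, the outward unit normal used here
    is ``n = (d_y, -d_x) / |d|``; a cell at point ``q`` has signed
    offset ``s = (q - p1) . n`` and reported distance
    ``max(0, interior_sign * s)``.  For the vertical line p1=(0,0),
    p2=(0,1), ``interior_sign=+1`` places the tissue at positive x.
    """

    p1: tuple[float, float]
    p2: tuple[float, float]
    interior_sign: int = 1

    def __post_init__(self) -> None:
        if tuple(map(float, self.p1)) == tuple(map(float, self.p2)):
            raise ValidationError("degenerate wound line: p1 == p2")
        if self.interior_sign not in (1, -1):
            raise ValidationError("interior_sign must be +1 or -1")

    def signed_distance(self, x, y) -> np.ndarray:
        """Signed perpendicular offset, positive on the interior side."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        (x1, y1), (x2, y2) = self.p1, self.p2
        dx, dy = x2 - x1, y2 - y1
        norm = float(np.hypot(dx, dy))
        s = ((x - x1) * dy - (y - y1) * dx) / norm
        return self.interior_sign * s


@dataclass(frozen=True, eq=False)
class DistanceSeries:
    """Per-cell distance-from-wound versus time.

    Columns: ``cell_id``, ``time_min``, ``distance_um`` (and ``channel``
    when derived from an :class:`ObservationSet`).  Distances are
    non-negative by construction.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in ("cell_id", "time_min", "distance_um"):
            if col not in df.columns:
                raise FormatError(f"missing column(s): {col}")
        df = df.copy()
        df["time_min"] = df["time_min"].astype(float)
        df["distance_um"] = df["distance_um"].astype(float)
        if (df["distance_um"] < 0).any():
            raise ValidationError("negative distance in distance series")
        df = df.sort_values(["cell_id", "time_min"], kind="mergesort").reset_index(
            drop=True
        )
        object.__setattr__(self, "data", df)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.data["time_min"].unique())


@dataclass(frozen=True, eq=False)
class PopulationSummary:
    """Per-timepoint population moments of the distance coordinate.

    Columns: ``time_min``, ``n_cells``, ``mean_dist``, ``mean_sq_dist``.
    Rows are sorted by time and satisfy Jensen's inequality
    ``mean_sq_dist >= mean_dist**2``.
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.rows
        for col in ("time_min", "n_cells", "mean_dist", "mean_sq_dist"):
            if col not in df.columns:
                raise FormatError(f"missing column(s): {col}")
        df = df.copy().sort_values("time_min", kind="mergesort").reset_index(drop=True)
        # small float slack: the moments are computed in floating point
        jensen = df["mean_sq_dist"] >= df["mean_dist"] ** 2 * (1 - 1e-12) - 1e-9
        if not jensen.all():
            raise ValidationError("mean_sq_dist < mean_dist**2 violates Jensen")
        object.__setattr__(self, "rows", df)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def time(self) -> np.ndarray:
        return self.rows["time_min"].to_numpy()

    @property
    def mean_dist(self) -> np.ndarray:
        return self.rows["mean_dist"].to_numpy()

    @property
    def mean_sq_dist(self) -> np.ndarray:
        return self.rows["mean_sq_dist"].to_numpy()


def load_tracks(path: str | Path) -> ObservationSet:
    """Read a canonical track CSV into a validated :class:`ObservationSet`.

    Raises :class:`FormatError` naming any missing column and a
    row-level error (with the 1-based file line number) for non-numeric
    coordinates or unknown channel labels.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TRACK_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
    out = pd.DataFrame({"cell_id": raw["cell_id"]})
    for col in ("time_min", "x_um", "y_um"):
        bad = pd.to_numeric(raw[col], errors="coerce").isna()
        if bad.any():
            idx = int(bad.idxmax())
            raise FormatError(
                f"{path}, line {idx + 2}: non-numeric value "
                f"{raw.loc[idx, col]!r} in column {col!r}"
            )
        # python float() parses correctly rounded; pandas' fast parser
        # can be off by one ulp, which breaks exact round-tripping
        out[col] = np.array([float(x) for x in raw[col]], dtype=float)
    chan = raw["channel"].str.strip().str.lower()
    unknown = ~chan.isin(CSV_TO_CHANNEL)
    if unknown.any():
        idx = int(unknown.idxmax())
        raise FormatError(
            f"{path}, line {idx + 2}: unknown channel {raw.loc[idx, 'channel']!r}; "
            f"expected one of {sorted(CSV_TO_CHANNEL)}"
        )
    out["channel"] = chan.map(CSV_TO_CHANNEL)
    return ObservationSet(out)


def save_tracks(obs: ObservationSet, path: str | Path) -> Path:
    """Write an :class:`ObservationSet` as a canonical track CSV.

    ``load_tracks(save_tracks(obs, p))`` reproduces ``obs`` exactly
    (float values are written with full round-trip precision).
    """
    path = Path(path)
    df = obs.data.copy()
    df["channel"] = df["channel"].map(CHANNEL_TO_CSV)
    # repr() is the shortest exact decimal form of a float64, so the
    # written text reparses to the identical value
    for col in ("time_min", "x_um", "y_um"):
        df[col] = df[col].map(repr)
    df.to_csv(path, index=False, columns=list(TRACK_COLUMNS))
    return path


def compute_distances(obs: ObservationSet, wound: WoundGeometry) -> DistanceSeries:
    """Distance-from-wound for every observation.

    The distance is the perpendicular offset from the wound line with
    the interior sign applied, clamped at 0: cells on the line or beyond
    it (outside the tissue) report distance 0.
    """
    df = obs.data
    s = wound.signed_distance(df["x_um"].to_numpy(), df["y_um"].to_numpy())
    out = pd.DataFrame(
        {
            "cell_id": df["cell_id"].to_numpy(),
            "time_min": df["time_min"].to_numpy(),
            "distance_um": np.maximum(s, 0.0),
            "channel": df["channel"].to_numpy(),
        }
    )
    return DistanceSeries(out)


def population_summary(ds: DistanceSeries, min_cells: int = 1) -> PopulationSummary:
    """Per-timepoint cell count, mean distance and mean squared distance.

    Timepoints with fewer than ``min_cells`` observed cells are dropped
    (sparse late frames produce gaps rather than unstable moments).  An
    empty series yields an empty summary.
    """
    if min_cells < 1:
        raise ValidationError("min_cells must be >= 1")
    df = ds.data
    if df.empty:
        empty = pd.DataFrame(
            columns=["time_min", "n_cells", "mean_dist", "mean_sq_dist"]
        ).astype({"time_min": float, "n_cells": int})
        return PopulationSummary(empty)
    g = df.groupby("time_min")["distance_um"]
    rows = pd.DataFrame(
        {
            "time_min": g.size().index.to_numpy(dtype=float),
            "n_cells": g.size().to_numpy(),
            "mean_dist": g.mean().to_numpy(),
            "mean_sq_dist": g.apply(lambda v: float(np.mean(v**2))).to_numpy(),
        }
    )
    rows = rows[rows["n_cells"] >= min_cells].reset_index(drop=True)
    return PopulationSummary(rows)
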