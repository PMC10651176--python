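"""Per-cell motility metrics, per-embryo aggregation and rose histograms.

All metrics are computed on drift-corrected, side-canonicalized tracks
(medial = +x).  The per-cell quantities follow the conventions used in
time-lapse studies of collective myocardial movement:

* displacement -- net Euclidean distance between first and last position;
* path length  -- sum of inter-frame step distances;
* velocity     -- displacement / elapsed time;
* speed        -- path length / elapsed time;
* efficiency   -- displacement / path length (1 for a straight path);
* direction    -- folded angle of the net displacement with respect to
  the medial axis, ``atan(|dy| / dx) * 180/pi``, ignoring the
  anterior/posterior sign of dy.  Cells with net lateral movement
  (dx <= 0) are mapped to (90, 180] by reflection so the scale stays a
  single scalar.

Elapsed time uses the recorded timestamps, not frame index times a
nominal interval, to tolerate acquisition jitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .track_io import TrackSet

#: Metric columns carried through per-cell tables and embryo aggregation.
METRIC_COLUMNS = [
    "displacement", "path_length", "velocity", "speed", "efficiency",
    "direction", "dx_net", "dy_net_abs", "ml_velocity", "ap_velocity",
]


@dataclass
class CellMotilityMetrics:
    """Motility metrics of one cell track (units: µm, minutes, degrees)."""

    embryo_id: str
    condition: str
    cell_id: str
    displacement: float
    path_length: float
    velocity: float
    speed: float
    efficiency: float          # NaN (flagged) when path_length == 0
    direction: float           # degrees in [0, 180]
    dx_net: float              # signed medial displacement
    dy_net_abs: float          # |anterior-posterior displacement|
    ml_velocity: float
    ap_velocity: float
    elapsed_min: float
    n_frames: int
    zero_path: bool = False


@dataclass
class RoseHistogram:
    """Angular histogram with closed-open bins and per-bin percentages.

    ``percentages`` are relative to ``n_total`` (all values, including
    any overflow), so in-range percentages plus ``overflow_percentage``
    sum to 100.
    """

    bin_edges: np.ndarray      # degrees, length n_bins + 1
    percentages: np.ndarray    # % of n_total per bin
    counts: np.ndarray
    n_total: int
    n_overflow: int = 0

    @property
    def overflow_percentage(self) -> float:
        return 100.0 * self.n_overflow / self.n_total if self.n_total else 0.0

    def to_dict(self) -> dict:
        return {
            "bin_edges_deg": [float(e) for e in self.bin_edges],
            "percentages": [float(p) for p in self.percentages],
            "counts": [int(c) for c in self.counts],
            "n_total": int(self.n_total),
            "n_overflow": int(self.n_overflow),
            "overflow_percentage": float(self.overflow_percentage),
        }


def direction_angle(dx_net: float, dy_net: float) -> float:
    """Folded direction angle in degrees.

    dx > 0 (net medial): ``atan(|dy|/dx)`` in [0, 90); dx == 0: 90
    exactly; dx < 0 (net lateral): reflected to ``180 - atan(|dy|/|dx|)``
    in (90, 180].  Anterior and posterior are never distinguished.
    """
    if dx_net == 0.0 and dy_net == 0.0:
        raise ValueError("direction undefined for zero net displacement")
    ady = abs(dy_net)
    if dx_net > 0:
        return math.degrees(math.atan(ady / dx_net))
    if dx_net == 0:
        return 90.0
    return 180.0 - math.degrees(math.atan(ady / abs(dx_net)))


def compute_cell_metrics(track: pd.DataFrame, use_z: bool = False) -> CellMotilityMetrics:
    """Compute motility metrics for one frame-sorted track table.

    ``use_z`` includes z in the path length; the net direction and all
    displacement components remain planar (x-y) regardless.
    """
    if len(track) < 2:
        raise ValueError("track must have at least 2 frames")
    t = track["t_min"].to_numpy(dtype=float)
    elapsed = t[-1] - t[0]
    if elapsed <= 0:
        raise ValueError("elapsed time must be positive")
    x = track["x_um"].to_numpy(dtype=float)
    y = track["y_um"].to_numpy(dtype=float)
    dx_net = x[-1] - x[0]
    dy_net = y[-1] - y[0]
    displacement = math.hypot(dx_net, dy_net)
    steps = np.hypot(np.diff(x), np.diff(y))
    if use_z and "z_um" in track.columns:
        z = track["z_um"].to_numpy(dtype=float)
        steps = np.sqrt(np.diff(x) ** 2 + np.diff(y) ** 2 + np.diff(z) ** 2)
    path_length = float(steps.sum())
    zero_path = path_length == 0.0
    efficiency = float("nan") if zero_path else displacement / path_length
    direction = float("nan") if displacement == 0.0 else direction_angle(dx_net, dy_net)
    return CellMotilityMetrics(
        embryo_id=str(track["embryo_id"].iloc[0]),
        condition=str(track["condition"].iloc[0]),
        cell_id=str(track["cell_id"].iloc[0]),
        displacement=displacement,
        path_length=path_length,
        velocity=displacement / elapsed,
        speed=path_length / elapsed,
        efficiency=efficiency,
        direction=direction,
        dx_net=dx_net,
        dy_net_abs=abs(dy_net),
        ml_velocity=dx_net / elapsed,
        ap_velocity=abs(dy_net) / elapsed,
        elapsed_min=float(elapsed),
        n_frames=len(track),
        zero_path=zero_path,
    )


def compute_metrics_table(trackset: TrackSet, use_z: bool = False) -> pd.DataFrame:
    """Per-cell metrics for every track in the set, one row per cell."""
    if trackset.axis_convention != "medial_positive_x":
        raise ValueError(
            "tracks must be side-canonicalized (medial = +x) before computing metrics; "
            "run canonicalize_sides first"
        )
    rows = [vars(compute_cell_metrics(grp, use_z=use_z)) for _, grp in trackset.iter_tracks()]
    return pd.DataFrame(rows)


def windowed_speed(track: pd.DataFrame, window: float) -> pd.DataFrame:
    """Speed per non-overlapping time window along one track.

    Each inter-frame step is assigned to the window containing its start
    time.  Full windows have duration ``window``; the trailing partial
    window is reported with its actual duration (last timestamp minus
    window start).  Returns columns window_start, duration, speed.
    """
    if len(track) < 2:
        raise ValueError("track must have at least 2 frames")
    t = track["t_min"].to_numpy(dtype=float)
    dt = np.diff(t)
    if window < 2.0 * np.median(dt):
        raise ValueError("window must span at least two sampling intervals")
    x = track["x_um"].to_numpy(dtype=float)
    y = track["y_um"].to_numpy(dtype=float)
    steps = np.hypot(np.diff(x), np.diff(y))
    t0, t_end = t[0], t[-1]
    idx = np.floor((t[:-1] - t0) / window).astype(int)
    n_windows = idx.max() + 1
    rows = []
    for k in range(n_windows):
        start = t0 + k * window
        duration = min(window, t_end - start)
        dist = steps[idx == k].sum()
        rows.append({"window_start": start, "duration": duration,
                     "speed": dist / duration if duration > 0 else float("nan")})
    return pd.DataFrame(rows)


def aggregate_per_embryo(metrics: pd.DataFrame) -> pd.DataFrame:
    """Unweighted per-embryo means and SEMs of every metric column.

    Direction is averaged arithmetically on the folded [0, 180] degree
    scale (matching how per-embryo averages are reported for this
    quantity), not as a circular mean.  SEM is NaN for single-cell
    embryos.  Also reports ``n_lateral``, the number of cells with net
    lateral movement (direction > 90).
    """
    if metrics.empty:
        raise ValueError("no metrics to aggregate")
    rows = []
    for (emb, cond), grp in metrics.groupby(["embryo_id", "condition"], sort=False):
        n = len(grp)
        row: dict = {"embryo_id": emb, "condition": cond, "n_cells": n,
                     "n_lateral": int((grp["direction"] > 90).sum())}
        for col in METRIC_COLUMNS:
            vals = grp[col].to_numpy(dtype=float)
            row[f"{col}_mean"] = float(np.nanmean(vals))
            row[f"{col}_sem"] = (
                float(np.nanstd(vals, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)


def rose_histogram(angles, n_bins: int, angle_range: tuple[float, float]) -> RoseHistogram:
    """Closed-open angular histogram; values beyond the range overflow."""
    angles = np.asarray(list(angles), dtype=float)
    angles = angles[np.isfinite(angles)]
    lo, hi = angle_range
    width = (hi - lo) / n_bins
    in_range = (angles >= lo) & (angles < hi)
    over = int((~in_range).sum())
    idx = np.floor((angles[in_range] - lo) / width).astype(int)
    counts = np.bincount(idx, minlength=n_bins)
    n_total = int(len(angles))
    pct = 100.0 * counts / n_total if n_total else np.zeros(n_bins)
    return RoseHistogram(
        bin_edges=lo + width * np.arange(n_bins + 1),
        percentages=pct, counts=counts, n_total=n_total, n_overflow=over,
    )


def direction_rose(metrics: pd.DataFrame, n_bins: int = 6,
                   angle_range: tuple[float, float] = (0.0, 90.0)) -> RoseHistogram:
    """Rose histogram of per-cell net direction angles (default 6 bins
    over [0, 90); net-lateral cells land in the overflow bin)."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    return rose_histogram(metrics["direction"], n_bins, angle_range)
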