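"""Membrane-protrusion morphology, orientation and dynamics.

Protrusion events arrive as annotated geometry (base and tip points,
length/width, frame span) in the canonicalized frame where the medial
direction is +x (0 degrees).  Unlike the folded cell direction angle,
protrusion orientation is a full circular angle in [0, 360) measured
counterclockwise from the medial axis, so anterior and posterior
protrusions are distinguished.

Conventions:

* morphology -- thin if longer than wide, wide if wider than long;
  equality is classed thin (deterministic tie rule, measure-zero in
  practice);
* orientation -- forward (medial-facing) for angles in [270, 360) or
  [0, 90); backward for [90, 270).  The half-open sectors give every
  angle exactly one class: 90 is backward, 270 is forward;
* persistence -- (end_frame - start_frame + 1) * frame_interval, i.e.
  lifetime measured in whole frames;
* events still active at the end of the movie are censored: they count
  toward frequency but are excluded from mean persistence by default,
  which would otherwise be biased low.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats_engine
from .stats_engine import GroupComparison
from .track_metrics import RoseHistogram, rose_histogram


@dataclass
class ProtrusionCellSummary:
    """Protrusion dynamics of one cell over one movie."""

    embryo_id: str
    condition: str
    cell_id: str
    n_events: int
    frequency: float           # events per hour
    mean_persistence: float    # minutes; NaN when no uncensored events
    forward_fraction: float    # NaN when no events
    thin_fraction: float       # NaN when no events
    n_censored: int


def protrusion_angle(base, tip) -> float:
    """Full circular angle (degrees in [0, 360)) of the base-to-tip vector,
    measured counterclockwise from the medial (+x) axis."""
    dx = tip[0] - base[0]
    dy = tip[1] - base[1]
    if dx == 0.0 and dy == 0.0:
        raise ValueError("protrusion angle undefined for zero-length vector")
    return math.degrees(math.atan2(dy, dx)) % 360.0


def classify_morphology(length: float, width: float) -> str:
    """'thin' (longer than wide, ties included) or 'wide' (wider than long)."""
    if length <= 0 or width <= 0:
        raise ValueError("length and width must be positive")
    return "thin" if length >= width else "wide"


def classify_orientation(angle: float) -> str:
    """'forward' for [270, 360) and [0, 90); 'backward' for [90, 270)."""
    if not 0.0 <= angle < 360.0:
        raise ValueError(f"angle must be in [0, 360), got {angle}")
    return "forward" if (angle < 90.0 or angle >= 270.0) else "backward"


def annotate_events(events: pd.DataFrame, frame_interval: float) -> pd.DataFrame:
    """Add angle, orientation, morphology and persistence columns."""
    df = events.copy()
    if (df["end_frame"] < df["start_frame"]).any():
        raise ValueError("end_frame must be >= start_frame")
    df["angle"] = [
        protrusion_angle((bx, by), (tx, ty))
        for bx, by, tx, ty in zip(df["base_x"], df["base_y"], df["tip_x"], df["tip_y"])
    ]
    df["orientation"] = df["angle"].map(classify_orientation)
    df["morphology"] = [
        classify_morphology(l, w) for l, w in zip(df["length_um"], df["width_um"])
    ]
    df["persistence_min"] = (df["end_frame"] - df["start_frame"] + 1) * frame_interval
    return df


def summarize_cell(events: pd.DataFrame, movie_duration: float, frame_interval: float,
                   include_censored_persistence: bool = False) -> ProtrusionCellSummary:
    """Per-cell frequency, persistence and orientation/morphology fractions.

    ``events`` holds all protrusions of one cell; an empty table yields
    frequency 0 with the fraction fields flagged NaN.
    """
    if movie_duration <= 0:
        raise ValueError("movie_duration must be > 0")
    n = len(events)
    hours = movie_duration / 60.0
    if n == 0:
        return ProtrusionCellSummary("", "", "", 0, 0.0,
                                     float("nan"), float("nan"), float("nan"), 0)
    ann = annotate_events(events, frame_interval)
    censored = ann["censored"].astype(bool)
    persist = ann["persistence_min"] if include_censored_persistence else ann.loc[~censored, "persistence_min"]
    return ProtrusionCellSummary(
        embryo_id=str(ann["embryo_id"].iloc[0]),
        condition=str(ann["condition"].iloc[0]),
        cell_id=str(ann["cell_id"].iloc[0]),
        n_events=n,
        frequency=n / hours,
        mean_persistence=float(persist.mean()) if len(persist) else float("nan"),
        forward_fraction=float((ann["orientation"] == "forward").mean()),
        thin_fraction=float((ann["morphology"] == "thin").mean()),
        n_censored=int(censored.sum()),
    )


def summarize_cells(events: pd.DataFrame, movie_duration: float,
                    frame_interval: float) -> pd.DataFrame:
    """One :class:`ProtrusionCellSummary` row per (embryo, cell)."""
    rows = [
        vars(summarize_cell(grp, movie_duration, frame_interval))
        for _, grp in events.groupby(["embryo_id", "cell_id"], sort=False)
    ]
    return pd.DataFrame(rows)


def protrusion_rose(events: pd.DataFrame, n_bins: int = 12,
                    frame_interval: float = 1.5) -> RoseHistogram:
    """Rose histogram of protrusion angles over the full circle."""
    if 360 % n_bins != 0:
        raise ValueError("n_bins must divide 360 evenly")
    ann = events if "angle" in events.columns else annotate_events(events, frame_interval)
    return rose_histogram(ann["angle"], n_bins, (0.0, 360.0))


def orientation_table(events_by_condition: dict[str, pd.DataFrame],
                      frame_interval: float) -> tuple[np.ndarray, list[str]]:
    """Pooled forward/backward counts per condition (rows = conditions)."""
    labels = list(events_by_condition)
    table = []
    for lab in labels:
        ann = annotate_events(events_by_condition[lab], frame_interval)
        fwd = int((ann["orientation"] == "forward").sum())
        table.append([fwd, len(ann) - fwd])
    return np.asarray(table, dtype=int), labels


def compare_conditions(events_by_condition: dict[str, pd.DataFrame],
                       movie_duration: float, frame_interval: float,
                       unit: str = "cell") -> dict:
    """Orientation Fisher test plus frequency/persistence t-tests.

    The 2x2 forward/backward table pools event counts across cells and
    embryos within each condition (exactly two conditions for the Fisher
    and t layers).  Frequency and persistence are compared per cell (or
    per embryo mean with ``unit="embryo"``) by Welch t-test.
    """
    labels = list(events_by_condition)
    if len(labels) < 2:
        raise ValueError("need >= 2 conditions to compare")
    for lab, ev in events_by_condition.items():
        if len(ev) == 0:
            raise ValueError(f"condition {lab!r} has no events")
    table, _ = orientation_table(events_by_condition, frame_interval)
    out: dict = {}
    if len(labels) == 2:
        fisher = stats_engine.fisher_exact(table, unit="event")
        fisher.groups = tuple(labels)
        out["orientation_fisher"] = fisher
        summaries = {
            lab: summarize_cells(ev, movie_duration, frame_interval)
            for lab, ev in events_by_condition.items()
        }
        if unit == "embryo":
            summaries = {
                lab: s.groupby("embryo_id", sort=False)
                      .agg({"frequency": "mean", "mean_persistence": "mean"})
                      .reset_index()
                for lab, s in summaries.items()
            }
        for metric in ("frequency", "mean_persistence"):
            x = summaries[labels[0]][metric].dropna()
            y = summaries[labels[1]][metric].dropna()
            if len(x) >= 2 and len(y) >= 2:
                out[f"{metric}_t"] = stats_engine.two_sample_t(
                    x, y, unit=unit, groups=(labels[0], labels[1])
                )
    out["orientation_counts"] = {lab: row.tolist() for lab, row in
                                 zip(labels, table)}
    return out
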