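"""Reading, writing and geometric normalisation of cell-track tables.

Tracks are time-lapse point lists (one row per cell per frame) in the
embryo's imaging frame: x along the medial--lateral axis, y along the
anterior--posterior axis, both in micrometres, time in minutes.  Two
geometric corrections are applied before any motility metric is computed:

* **drift correction** -- whole-embryo translation is estimated from a
  fixed anatomical landmark (the notochord tip) tracked through the movie
  and subtracted frame by frame, so that only cell movement relative to
  the embryo remains;
* **side canonicalisation** -- the heart forms from bilateral cell
  populations that move toward the midline in opposite x directions;
  right-side tracks are mirrored about the midline so that medial
  movement is +x for every cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

#: Native track table schema (z_um optional).
TRACK_COLUMNS = ["embryo_id", "condition", "cell_id", "frame", "t_min", "x_um", "y_um"]

#: Native protrusion event table schema.
PROTRUSION_COLUMNS = [
    "embryo_id", "condition", "cell_id", "event_id",
    "start_frame", "end_frame",
    "base_x", "base_y", "tip_x", "tip_y",
    "length_um", "width_um", "censored",
]

#: Reference (landmark) trajectory table schema.
REFERENCE_COLUMNS = ["embryo_id", "frame", "x_um", "y_um"]


class SchemaError(ValueError):
    """A table is missing required columns."""


class TrackValidationError(ValueError):
    """A table violates the track invariants (ordering, finiteness, duplicates)."""


@dataclass
class TrackSet:
    """A set of cell tracks plus bookkeeping about their coordinate frame.

    Parameters
    ----------
    points
        Long-format table with :data:`TRACK_COLUMNS` (plus optional ``z_um``).
    axis_convention
        ``"raw"`` for tracks in the imaging frame, ``"medial_positive_x"``
        once sides have been canonicalized so medial movement is +x.
    units
        Declared spatial/temporal units; only ``"um_min"`` is produced.
    meta
        Free-form provenance, e.g. simulator ground-truth parameters.
    """

    points: pd.DataFrame
    axis_convention: str = "raw"
    units: str = "um_min"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = validate_tracks(self.points)

    @property
    def track_keys(self) -> list[tuple[str, str]]:
        """Unique ``(embryo_id, cell_id)`` pairs, in table order."""
        seen = self.points[["embryo_id", "cell_id"]].drop_duplicates()
        return list(map(tuple, seen.itertuples(index=False)))

    def iter_tracks(self):
        """Yield ``((embryo_id, cell_id), frame-sorted DataFrame)`` per track."""
        for key, grp in self.points.groupby(["embryo_id", "cell_id"], sort=False):
            yield key, grp.sort_values("frame")

    def embryos(self) -> list[str]:
        return list(self.points["embryo_id"].drop_duplicates())


@dataclass
class ReferenceTrajectory:
    """Per-frame position of the anatomical reference point of one embryo."""

    embryo_id: str
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.frames) == len(self.x) == len(self.y)):
            raise TrackValidationError("reference trajectory arrays must have equal length")
        if len(self.frames) and np.any(np.diff(self.frames) <= 0):
            raise TrackValidationError(
                f"reference trajectory for embryo {self.embryo_id!r} has non-increasing frames"
            )
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise TrackValidationError("reference trajectory coordinates must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"embryo_id": self.embryo_id, "frame": self.frames, "x_um": self.x, "y_um": self.y}
        )


def validate_tracks(df: pd.DataFrame) -> pd.DataFrame:
    """Check the track-table invariants and return a clean copy.

    Raises :class:`SchemaError` for missing columns and
    :class:`TrackValidationError` for non-monotone frames, non-finite
    coordinates, or duplicate (embryo, cell, frame) rows.  Never reorders
    rows silently: an out-of-order track is an error, not a sort.
    """
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"track table missing required columns: {missing}")
    df = df.copy()
    for col in ("frame",):
        df[col] = df[col].astype(int)
    num_cols = ["t_min", "x_um", "y_um"] + (["z_um"] if "z_um" in df.columns else [])
    for col in num_cols:
        df[col] = df[col].astype(float)
        if not np.isfinite(df[col]).all():
            raise TrackValidationError(f"non-finite values in column {col!r}")
    if df.duplicated(["embryo_id", "cell_id", "frame"]).any():
        raise TrackValidationError("duplicate (embryo_id, cell_id, frame) rows")
    for (emb, cell), grp in df.groupby(["embryo_id", "cell_id"], sort=False):
        frames = grp["frame"].to_numpy()
        if np.any(np.diff(frames) <= 0):
            raise TrackValidationError(
                f"frames not strictly increasing in track ({emb!r}, {cell!r})"
            )
        if np.any(np.diff(grp["t_min"].to_numpy()) < 0):
            raise TrackValidationError(f"time decreasing in track ({emb!r}, {cell!r})")
    return df


def read_tracks(path: str | Path, dialect: str = "native_csv",
                embryo_id: str = "embryo1", condition: str = "unknown") -> TrackSet:
    """Read a track table.

    ``dialect="native_csv"`` expects :data:`TRACK_COLUMNS`.
    ``dialect="mtrackj_points"`` ingests an mTrackJ-style points export
    with columns ``TID`` (track id), ``PID`` (point order), ``x``, ``y``,
    ``t`` and optional ``z``; TID maps to ``cell_id`` and PID (1-based)
    to 0-based frame numbers.  ``embryo_id``/``condition`` label the
    whole file in that dialect.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "native_csv":
        df = pd.read_csv(path)
        return TrackSet(points=df)
    if dialect == "mtrackj_points":
        df = pd.read_csv(path, sep=None, engine="python")
        needed = ["TID", "PID", "x", "y", "t"]
        missing = [c for c in needed if c not in df.columns]
        if missing:
            raise SchemaError(f"mTrackJ points table missing required columns: {missing}")
        out = pd.DataFrame(
            {
                "embryo_id": embryo_id,
                "condition": condition,
                "cell_id": df["TID"].map(lambda t: f"track{int(t)}"),
                "frame": df["PID"].astype(int) - 1,
                "t_min": df["t"].astype(float),
                "x_um": df["x"].astype(float),
                "y_um": df["y"].astype(float),
            }
        )
        if "z" in df.columns:
            out["z_um"] = df["z"].astype(float)
        return TrackSet(points=out)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_tracks(trackset: TrackSet, path: str | Path) -> None:
    """Write the native CSV schema (6-decimal fixed point, round-trip safe)."""
    cols = TRACK_COLUMNS + (["z_um"] if "z_um" in trackset.points.columns else [])
    trackset.points[cols].to_csv(path, index=False, float_format="%.6f")


def read_reference(path: str | Path) -> dict[str, ReferenceTrajectory]:
    """Read reference trajectories (one per embryo) from a CSV table."""
    df = pd.read_csv(path)
    missing = [c for c in REFERENCE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"reference table missing required columns: {missing}")
    return {
        str(emb): ReferenceTrajectory(str(emb), grp["frame"].to_numpy(),
                                      grp["x_um"].to_numpy(), grp["y_um"].to_numpy())
        for emb, grp in df.groupby("embryo_id", sort=False)
    }


def write_reference(references: Mapping[str, ReferenceTrajectory], path: str | Path) -> None:
    pd.concat([r.to_frame() for r in references.values()], ignore_index=True).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_protrusions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PROTRUSION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"protrusion table missing required columns: {missing}")
    df = df.copy()
    df["censored"] = df["censored"].astype(bool)
    return df


def write_protrusions(events: pd.DataFrame, path: str | Path) -> None:
    events[PROTRUSION_COLUMNS].to_csv(path, index=False, float_format="%.6f")


def correct_drift(trackset: TrackSet,
                  references: Mapping[str, ReferenceTrajectory] | ReferenceTrajectory) -> TrackSet:
    """Subtract whole-embryo drift measured at the reference landmark.

    For each embryo and frame ``f`` the offset ``reference(f) -
    reference(f0)`` (``f0`` = first reference frame) is subtracted from
    every cell position at frame ``f``, so the landmark itself maps to a
    constant point.  The reference must cover every frame present in that
    embryo's tracks.
    """
    if isinstance(references, ReferenceTrajectory):
        references = {references.embryo_id: references}
    df = trackset.points.copy()
    for emb, idx in df.groupby("embryo_id", sort=False).groups.items():
        if emb not in references:
            raise TrackValidationError(f"no reference trajectory for embryo {emb!r}")
        ref = references[emb]
        frames = df.loc[idx, "frame"].to_numpy()
        missing = np.setdiff1d(frames, ref.frames)
        if missing.size:
            raise TrackValidationError(
                f"reference for embryo {emb!r} missing frame {int(missing[0])}"
            )
        pos = {int(f): (x, y) for f, x, y in zip(ref.frames, ref.x, ref.y)}
        x0, y0 = ref.x[0], ref.y[0]
        off = np.array([pos[int(f)] for f in frames], dtype=float) - (x0, y0)
        df.loc[idx, "x_um"] = df.loc[idx, "x_um"].to_numpy() - off[:, 0]
        df.loc[idx, "y_um"] = df.loc[idx, "y_um"].to_numpy() - off[:, 1]
    return replace(trackset, points=df)


def infer_sides(trackset: TrackSet, midline_x: float) -> dict[tuple[str, str], str]:
    """Assign left/right by the sign of each track's mean x minus the midline.

    A track with points on both sides of the midline is ambiguous and
    raises; provide explicit ``side_assignments`` for such tracks.
    """
    sides: dict[tuple[str, str], str] = {}
    for key, grp in trackset.iter_tracks():
        x = grp["x_um"].to_numpy()
        if x.min() < midline_x < x.max():
            raise TrackValidationError(
                f"track {key!r} straddles the midline; explicit side assignment required"
            )
        sides[key] = "left" if x.mean() <= midline_x else "right"
    return sides


def canonicalize_sides(trackset: TrackSet, midline_x: float = 0.0,
                       side_assignments: Mapping[tuple[str, str], str] | None = None) -> TrackSet:
    """Mirror right-side tracks about the midline so medial movement is +x.

    Left-side cells (x < midline) already move medially in +x and are
    unchanged; right-side cells are reflected ``x -> 2*midline - x``.
    Applying the operation twice is the identity, and |dy| and path
    length are preserved exactly.
    """
    sides = dict(side_assignments) if side_assignments else {}
    inferred = None
    df = trackset.points.copy()
    for key, idx in df.groupby(["embryo_id", "cell_id"], sort=False).groups.items():
        side = sides.get(key)
        if side is None:
            if inferred is None:
                inferred = infer_sides(trackset, midline_x)
            side = inferred[key]
        if side not in ("left", "right"):
            raise ValueError(f"side for track {key!r} must be 'left' or 'right', got {side!r}")
        if side == "right":
            df.loc[idx, "x_um"] = 2.0 * midline_x - df.loc[idx, "x_um"].to_numpy()
    return replace(trackset, points=df, axis_convention="medial_positive_x")


def canonicalize_protrusion_sides(events: pd.DataFrame, midline_x: float = 0.0,
                                  side_assignments: Mapping[tuple[str, str], str] | None = None,
                                  ) -> pd.DataFrame:
    """Mirror right-side protrusion geometry so the medial direction is +x.

    Side is taken from ``side_assignments`` keyed by (embryo_id, cell_id)
    or, failing that, the sign of the cell's mean base x relative to the
    midline (base coordinates never straddle ambiguity the way long
    tracks can, so no straddle check is applied here).
    """
    df = events.copy()
    for key, idx in df.groupby(["embryo_id", "cell_id"], sort=False).groups.items():
        side = side_assignments.get(key) if side_assignments else None
        if side is None:
            side = "left" if df.loc[idx, "base_x"].mean() <= midline_x else "right"
        if side == "right":
            for col in ("base_x", "tip_x"):
                df.loc[idx, col] = 2.0 * midline_x - df.loc[idx, col].to_numpy()
    return df
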