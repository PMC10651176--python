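"""Synthetic imaging experiments with known ground truth.

Every downstream stage of the pipeline is exercised against simulated
data whose generative parameters are retained, so that recovery can be
tested without any raw movie.  Three generators are provided:

* **cell tracks** -- a biased persistent random walk.  Each step's
  direction is a persistence-weighted blend of the previous direction
  with a mixture of the medial unit vector (weight ``medial_bias``) and
  an isotropic unit vector; step length is ``mean_step_speed * dt``
  modulated by truncated Gaussian noise.  A shared drift velocity moves
  all cells and the anatomical reference point identically, emulating
  whole-embryo drift during acquisition.  An optional two-phase program
  rotates the bias axis anteriorly partway through the movie, emulating
  the stage dependence of medial movement.
* **protrusion events** -- onsets from a homogeneous Poisson process per
  cell, lifetimes geometric on frames (protrusion persistence is scored
  from discrete movie frames), orientations von Mises about the medial
  direction.  Events that would outlive the movie are truncated and
  flagged censored.
* **reporter images** -- a two-channel cell: uniform cytoplasmic fill in
  channel A, a Gaussian-profile membrane ring in channel B, plus
  Gaussian noise.

The default parameter values reproduce the published imaging conditions:
20-25 tracked cells per embryo sampled every ~4 min for ~3 h, protrusion
movies sampled every 1.5 min, control cells moving at ~0.23 µm/min with
strongly medial tracks and ~77% forward protrusions at ~20 events/h,
PI3K-inhibited cells slower (~0.19 µm/min), weakly oriented, with
unpolarized protrusions.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd

from .track_io import ReferenceTrajectory, TrackSet


class ConfigError(ValueError):
    """An invalid simulation configuration field, named in the message."""


def derive_seed(base_seed: int, label: str) -> int:
    """Stable per-substream seed (< 2**31) from a base seed and a label.

    Hash-derived so that adding an embryo or condition never perturbs the
    streams of the others.
    """
    digest = hashlib.sha256(f"{base_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _require(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"invalid field {fieldname!r}: {msg}")


@dataclass
class EmbryoSimConfig:
    """Parameters of one simulated embryo's track movie.

    Defaults are the control-like imaging condition; see
    :func:`pi3k_inhibited_track_config` for the inhibited preset.
    """

    n_cells: int = 22                      # 20-25 tracked cells per embryo
    duration: float = 180.0                # minutes of imaging
    sampling_interval: float = 4.0         # minutes between frames
    mean_step_speed: float = 0.2334        # µm/min
    medial_bias: float = 0.45              # weight of the heading unit vector
    persistence: float = 0.6               # step-direction autocorrelation
    drift_velocity: tuple[float, float] = (0.25, 0.15)   # µm/min, whole embryo
    initial_axis_deg: float = 0.0          # heading axis, degrees anterior of medial
    phase_switch_time: float | None = None  # minutes; None = single phase
    phase_rotation_deg: float = 60.0       # anterior rotation of the bias axis
    step_length_noise_sd: float = 0.1      # sd of the (1 + eps) length factor
    embryo_axis_sd_deg: float = 0.0        # embryo-level random rotation of the bias axis
    side: str = "both"                     # left | right | both
    embryo_id: str = "embryo1"
    condition: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_cells >= 1, "n_cells", "must be >= 1")
        _require(self.sampling_interval > 0, "sampling_interval", "must be > 0")
        _require(self.duration >= 2 * self.sampling_interval, "duration",
                 "must cover at least two sampling intervals")
        _require(0.0 <= self.medial_bias <= 1.0, "medial_bias", "must be in [0, 1]")
        _require(0.0 <= self.persistence < 1.0, "persistence", "must be in [0, 1)")
        _require(self.mean_step_speed >= 0, "mean_step_speed", "must be >= 0")
        _require(self.step_length_noise_sd >= 0, "step_length_noise_sd", "must be >= 0")
        _require(self.side in ("left", "right", "both"), "side",
                 "must be 'left', 'right' or 'both'")
        _require(self.phase_switch_time is None or self.phase_switch_time > 0,
                 "phase_switch_time", "must be > 0 or None")


@dataclass
class ProtrusionSimConfig:
    """Parameters of one simulated protrusion movie (defaults control-like)."""

    rate_per_hour: float = 20.3            # protrusion events per hour per cell
    mean_lifetime: float = 2.3             # minutes
    orientation_concentration: float = 0.9634   # von Mises kappa about medial
    thin_fraction: float = 0.5             # probability an event is thin
    frame_interval: float = 1.5            # minutes between frames
    movie_duration: float = 60.0           # minutes
    n_cells: int = 11
    n_embryos: int = 5
    embryo_prefix: str = "embryo"
    condition: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.rate_per_hour >= 0, "rate_per_hour", "must be >= 0")
        _require(self.mean_lifetime > 0, "mean_lifetime", "must be > 0")
        _require(self.orientation_concentration >= 0, "orientation_concentration",
                 "must be >= 0")
        _require(0.0 <= self.thin_fraction <= 1.0, "thin_fraction", "must be in [0, 1]")
        _require(self.frame_interval > 0, "frame_interval", "must be > 0")
        _require(self.movie_duration >= self.frame_interval, "movie_duration",
                 "must cover at least one frame")
        _require(self.n_cells >= 1, "n_cells", "must be >= 1")
        _require(self.n_embryos >= 1, "n_embryos", "must be >= 1")


def control_track_config(**overrides) -> EmbryoSimConfig:
    """Control-like preset: ~0.23 µm/min along a tight anteromedial heading
    (mean net direction ~31 degrees, high efficiency)."""
    defaults = dict(initial_axis_deg=31.0, condition="control")
    return EmbryoSimConfig(**{**defaults, **overrides})


def pi3k_inhibited_track_config(**overrides) -> EmbryoSimConfig:
    """PI3K-inhibited-like preset: slower, misdirected tracks whose heading
    axis is rotated anteriorly (mean net direction ~60 degrees)."""
    defaults = dict(mean_step_speed=0.1879, medial_bias=0.28, persistence=0.6,
                    initial_axis_deg=60.0, condition="inhibited")
    return EmbryoSimConfig(**{**defaults, **overrides})


def control_protrusion_config(**overrides) -> ProtrusionSimConfig:
    """Control-like protrusions: 20.3/h, 2.3 min, ~77% forward (kappa 0.963)."""
    return ProtrusionSimConfig(**{"condition": "control", **overrides})


def pi3k_inhibited_protrusion_config(**overrides) -> ProtrusionSimConfig:
    """Inhibited-like protrusions: 17/h, 3.23 min, unpolarized (kappa 0)."""
    defaults = dict(rate_per_hour=17.0, mean_lifetime=3.23,
                    orientation_concentration=0.0, condition="inhibited")
    return ProtrusionSimConfig(**{**defaults, **overrides})


def _rotate(v: np.ndarray, deg: float) -> np.ndarray:
    rad = math.radians(deg)
    c, s = math.cos(rad), math.sin(rad)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def simulate_embryo_tracks(config: EmbryoSimConfig) -> tuple[TrackSet, ReferenceTrajectory]:
    """Simulate one embryo's cell tracks plus its reference-point trajectory.

    Returns raw-frame tracks (drift included, sides not canonicalized)
    and the landmark trajectory carrying the identical drift, so the
    full correction pipeline can be exercised.  Ground-truth parameters
    are stored in ``TrackSet.meta``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_frames = int(math.floor(cfg.duration / cfg.sampling_interval)) + 1
    times = np.arange(n_frames) * cfg.sampling_interval
    n = cfg.n_cells

    if cfg.side == "both":
        sides = np.array(["left", "right"])[np.arange(n) % 2]
    else:
        sides = np.full(n, cfg.side)
    sign = np.where(sides == "left", 1.0, -1.0)    # medial = +x for left cells

    # start positions: lateral band on each side of the midline (x = 0)
    x0 = -sign * rng.uniform(50.0, 90.0, n)
    y0 = rng.uniform(-40.0, 40.0, n)
    pos = np.column_stack([x0, y0])

    axis_jitter = rng.normal(0.0, cfg.embryo_axis_sd_deg) if cfg.embryo_axis_sd_deg else 0.0

    def bias_axis(t: float) -> np.ndarray:
        rot = cfg.initial_axis_deg + axis_jitter
        if cfg.phase_switch_time is not None and t >= cfg.phase_switch_time:
            rot += cfg.phase_rotation_deg   # rotate toward anterior (+y)
        return _rotate(np.array([1.0, 0.0]), rot)

    drift = np.asarray(cfg.drift_velocity, dtype=float)
    dt = cfg.sampling_interval
    positions = np.empty((n_frames, n, 2))
    positions[0] = pos
    direction = None
    for f in range(1, n_frames):
        mhat_base = bias_axis(times[f - 1])
        # per-cell medial axis: mirror the x component for right-side cells
        mhat = np.column_stack([sign * mhat_base[0], np.full(n, mhat_base[1])])
        theta = rng.uniform(0.0, 2.0 * math.pi, n)
        u = np.column_stack([np.cos(theta), np.sin(theta)])
        target = cfg.medial_bias * mhat + (1.0 - cfg.medial_bias) * u
        if direction is None:
            direction = target
        else:
            direction = cfg.persistence * direction + (1.0 - cfg.persistence) * target
        norm = np.linalg.norm(direction, axis=1, keepdims=True)
        degenerate = norm[:, 0] < 1e-12
        if degenerate.any():
            direction[degenerate] = u[degenerate]
            norm = np.linalg.norm(direction, axis=1, keepdims=True)
        direction = direction / norm
        eps = rng.normal(0.0, cfg.step_length_noise_sd, n) if cfg.step_length_noise_sd else np.zeros(n)
        step = cfg.mean_step_speed * dt * (1.0 + np.clip(eps, -0.9, None))
        positions[f] = positions[f - 1] + direction * step[:, None]

    # whole-embryo drift applied to every cell and to the reference point
    drift_offsets = np.outer(times, drift)
    positions += drift_offsets[:, None, :]
    ref0 = np.array([0.0, -120.0])     # notochord tip, posterior to the heart field
    ref = ref0 + drift_offsets

    cell_ids = [f"{cfg.embryo_id}_c{i:02d}" for i in range(n)]
    frames_col = np.repeat(np.arange(n_frames), n)
    df = pd.DataFrame({
        "embryo_id": cfg.embryo_id,
        "condition": cfg.condition,
        "cell_id": np.tile(cell_ids, n_frames),
        "frame": frames_col,
        "t_min": np.repeat(times, n),
        "x_um": positions.reshape(n_frames * n, 2)[:, 0],
        "y_um": positions.reshape(n_frames * n, 2)[:, 1],
    })
    # reorder long format so each track's rows are contiguous and frame-sorted
    df = df.sort_values(["cell_id", "frame"], kind="stable").reset_index(drop=True)
    meta = {"config": asdict(cfg), "sides": dict(zip(cell_ids, sides)),
            "truth": {"mean_step_speed": cfg.mean_step_speed,
                      "medial_bias": cfg.medial_bias,
                      "persistence": cfg.persistence}}
    trackset = TrackSet(points=df, axis_convention="raw", meta=meta)
    reference = ReferenceTrajectory(cfg.embryo_id, np.arange(n_frames), ref[:, 0], ref[:, 1])
    return trackset, reference


def simulate_track_study(config: EmbryoSimConfig, n_embryos: int, seed: int,
                         ) -> tuple[TrackSet, dict[str, ReferenceTrajectory]]:
    """Simulate ``n_embryos`` embryos under one condition.

    Per-embryo seeds are hash-derived from ``seed`` and the embryo id, so
    embryo k's tracks do not depend on how many embryos are simulated.
    """
    from dataclasses import replace as dc_replace

    tracks = []
    references = {}
    for k in range(n_embryos):
        emb_id = f"{config.condition}_e{k + 1:02d}"
        cfg_k = dc_replace(config, embryo_id=emb_id,
                           seed=derive_seed(seed, f"tracks:{emb_id}"))
        ts, ref = simulate_embryo_tracks(cfg_k)
        tracks.append(ts.points)
        references[emb_id] = ref
    combined = TrackSet(points=pd.concat(tracks, ignore_index=True),
                        axis_convention="raw",
                        meta={"config": asdict(config), "n_embryos": n_embryos,
                              "seed": seed})
    return combined, references


def simulate_protrusions(config: ProtrusionSimConfig) -> pd.DataFrame:
    """Simulate protrusion event tables for ``n_cells`` cells.

    Onsets are a homogeneous Poisson process over the movie, lifetimes
    geometric on frames with the configured mean (minimum one frame),
    orientations von Mises(0, kappa) about the medial (+x) axis.  Events
    whose lifetime would extend past the last frame are truncated there
    and flagged ``censored``.  Returns the native protrusion table
    (columns of :data:`cardiotrack.track_io.PROTRUSION_COLUMNS`).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_frames = int(math.floor(cfg.movie_duration / cfg.frame_interval))
    last_frame = n_frames - 1
    mean_frames = max(cfg.mean_lifetime / cfg.frame_interval, 1.0)
    p_geom = 1.0 / mean_frames
    rows = []
    for i in range(cfg.n_cells):
        embryo = f"{cfg.embryo_prefix}{i % cfg.n_embryos + 1:02d}"
        cell = f"{embryo}_c{i:02d}"
        n_events = rng.poisson(cfg.rate_per_hour * cfg.movie_duration / 60.0)
        onsets = np.sort(rng.uniform(0.0, cfg.movie_duration, n_events))
        lifetimes = rng.geometric(p_geom, n_events)           # frames, >= 1
        angles = rng.vonmises(0.0, cfg.orientation_concentration, n_events)
        thin = rng.uniform(size=n_events) < cfg.thin_fraction
        lengths = np.clip(rng.normal(3.0, 0.8, n_events), 0.5, None)
        ratio = np.where(thin, rng.uniform(0.3, 0.9, n_events),
                         rng.uniform(1.1, 2.0, n_events))
        widths = lengths * ratio
        base_y = rng.uniform(-30.0, 30.0, n_events)
        for j in range(n_events):
            start = min(int(onsets[j] / cfg.frame_interval), last_frame)
            end = start + int(lifetimes[j]) - 1
            censored = end > last_frame
            end = min(end, last_frame)
            bx, by = -20.0, float(base_y[j])
            rows.append({
                "embryo_id": embryo, "condition": cfg.condition, "cell_id": cell,
                "event_id": f"{cell}_p{j:03d}",
                "start_frame": start, "end_frame": end,
                "base_x": bx, "base_y": by,
                "tip_x": bx + lengths[j] * math.cos(angles[j]),
                "tip_y": by + lengths[j] * math.sin(angles[j]),
                "length_um": float(lengths[j]), "width_um": float(widths[j]),
                "censored": bool(censored),
            })
    return pd.DataFrame(rows, columns=[
        "embryo_id", "condition", "cell_id", "event_id", "start_frame", "end_frame",
        "base_x", "base_y", "tip_x", "tip_y", "length_um", "width_um", "censored",
    ])


def make_reporter_image(membrane_radius: float, peak_intensity: float = 100.0,
                        background: float = 10.0, noise_sd: float = 0.0,
                        seed: int = 0, shape: tuple[int, int] = (64, 64),
                        pixel_size: float = 0.25, fill_intensity: float = 60.0,
                        ring_sigma: float = 0.5):
    """Synthetic two-channel reporter image of one round cell.

    Channel A is a uniform cytoplasmic fill inside the cell radius;
    channel B is a Gaussian-profile ring of the given peak intensity at
    the membrane (radius ``membrane_radius`` µm from the cell center),
    over a uniform background.  Gaussian noise of sd ``noise_sd`` is
    added to both channels (clipped at 0).  Returns ``(ImageGrid2C,
    truth)`` where ``truth`` records the center (pixels) and radius.
    """
    from .reporter_profiles import ImageGrid2C

    if noise_sd < 0:
        raise ConfigError("invalid field 'noise_sd': must be >= 0")
    nrows, ncols = shape
    cy, cx = (nrows - 1) / 2.0, (ncols - 1) / 2.0
    max_radius = min(cx, cy, ncols - 1 - cx, nrows - 1 - cy) * pixel_size
    if not 0 < membrane_radius < max_radius:
        raise ConfigError(
            f"invalid field 'membrane_radius': must be in (0, {max_radius:.3g}) µm "
            "to fit inside the image"
        )
    yy, xx = np.mgrid[0:nrows, 0:ncols]
    r = np.hypot(xx - cx, yy - cy) * pixel_size
    channel_a = np.where(r <= membrane_radius, fill_intensity, background).astype(float)
    channel_b = background + (peak_intensity - background) * np.exp(
        -((r - membrane_radius) ** 2) / (2.0 * ring_sigma ** 2)
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        channel_a = np.clip(channel_a + rng.normal(0, noise_sd, shape), 0, None)
        channel_b = np.clip(channel_b + rng.normal(0, noise_sd, shape), 0, None)
    image = ImageGrid2C(channel_a=channel_a, channel_b=channel_b, pixel_size=pixel_size)
    truth = {"center_px": (cx, cy), "radius_um": membrane_radius,
             "peak_intensity": peak_intensity, "background": background}
    return image, truth
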