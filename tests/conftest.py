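"""Shared fixtures: track builders and independent statistical oracles."""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest


def build_track(points, embryo_id="e1", cell_id="c1", condition="ctrl",
                t_per_frame=4.0):
    """Track DataFrame from a list of (x, y) positions, one per frame."""
    return pd.DataFrame({
        "embryo_id": embryo_id,
        "condition": condition,
        "cell_id": cell_id,
        "frame": np.arange(len(points)),
        "t_min": np.arange(len(points)) * t_per_frame,
        "x_um": [p[0] for p in points],
        "y_um": [p[1] for p in points],
    })


@pytest.fixture
def make_track():
    return build_track


def fisher_enum_oracle(table) -> Fraction:
    """Two-sided Fisher p by exact full enumeration in rational arithmetic.

    Sums the hypergeometric probability of every table with the observed
    margins whose probability does not exceed the observed table's.
    Completely independent of the log-space implementation under test.
    """
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def pmf(x):
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    obs = pmf(a)
    return sum(
        (p for x in range(max(0, c1 - r2), min(r1, c1) + 1) if (p := pmf(x)) <= obs),
        Fraction(0),
    )


@pytest.fixture
def fisher_enum():
    return fisher_enum_oracle


def simulate_net_direction_mc(medial_bias, n_steps, n_tracks, seed,
                              noise_sd=0.1):
    """Monte-Carlo oracle for the mean folded direction angle of a
    persistence-free biased random walk.

    Re-derives the step model directly (iid steps, direction =
    normalized mix of the medial axis and an isotropic unit vector) in
    vectorized form, independent of the package's track simulator.
    """
    rng = np.random.default_rng(seed)
    net = np.zeros((n_tracks, 2))
    for _ in range(n_steps):
        theta = rng.uniform(0, 2 * np.pi, n_tracks)
        d = medial_bias * np.array([1.0, 0.0]) + (1 - medial_bias) * np.c_[
            np.cos(theta), np.sin(theta)]
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        eps = np.clip(rng.normal(0, noise_sd, n_tracks), -0.9, None)
        net += d * (1 + eps)[:, None]
    dx, dy = net[:, 0], np.abs(net[:, 1])
    ang = np.where(
        dx > 0, np.degrees(np.arctan2(dy, np.abs(dx))),
        np.where(dx == 0, 90.0, 180.0 - np.degrees(np.arctan2(dy, np.abs(dx)))),
    )
    return float(ang.mean())


@pytest.fixture
def mc_direction_oracle():
    return simulate_net_direction_mc
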