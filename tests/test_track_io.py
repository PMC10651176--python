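"""Track I/O, drift correction and side canonicalisation."""

import numpy as np
import pandas as pd
import pytest

from cardiotrack import track_io
from cardiotrack.track_io import (
    ReferenceTrajectory,
    SchemaError,
    TrackSet,
    TrackValidationError,
    canonicalize_sides,
    correct_drift,
    read_tracks,
    write_tracks,
)
from cardiotrack.track_metrics import compute_cell_metrics

from conftest import build_track


def _random_trackset(n_cells=4, n_frames=25, seed=0):
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_cells):
        pts = np.cumsum(rng.normal(0, 1, (n_frames, 2)), axis=0) - (60, 0)
        frames.append(build_track(pts, cell_id=f"c{i}"))
    return TrackSet(points=pd.concat(frames, ignore_index=True))


class TestReadWrite:
    def test_round_trip_preserves_values_to_6_decimals(self, tmp_path):
        ts = _random_trackset(n_cells=4, n_frames=25)  # 100 points
        path = tmp_path / "tracks.csv"
        write_tracks(ts, path)
        back = read_tracks(path)
        for col in ("x_um", "y_um", "t_min"):
            np.testing.assert_allclose(
                back.points[col], ts.points[col], atol=5e-7)
        assert list(back.points["cell_id"]) == list(ts.points["cell_id"])

    def test_missing_column_raises_schema_error_naming_it(self, tmp_path):
        df = build_track([(0, 0), (1, 0)]).drop(columns=["t_min"])
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="t_min"):
            read_tracks(path)

    def test_empty_trackset_writes_header_only(self, tmp_path):
        empty = TrackSet(points=build_track([]).iloc[0:0])
        path = tmp_path / "empty.csv"
        write_tracks(empty, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("embryo_id,")

    def test_unicode_embryo_id_preserved(self, tmp_path):
        ts = TrackSet(points=build_track([(0, 0), (1, 1)], embryo_id="embryo_μ1"))
        path = tmp_path / "u.csv"
        write_tracks(ts, path)
        assert read_tracks(path).points["embryo_id"].iloc[0] == "embryo_μ1"

    def test_mtrackj_points_dialect_maps_columns(self, tmp_path):
        df = pd.DataFrame({
            "TID": [1, 1, 1, 2, 2],
            "PID": [1, 2, 3, 1, 2],
            "x": [0.0, 1.5, 3.0, 10.0, 11.0],
            "y": [0.0, 0.5, 1.0, -2.0, -2.5],
            "t": [0.0, 4.0, 8.0, 0.0, 4.0],
        })
        path = tmp_path / "points.csv"
        df.to_csv(path, index=False)
        ts = read_tracks(path, dialect="mtrackj_points", embryo_id="e9")
        assert set(ts.points["cell_id"]) == {"track1", "track2"}
        t1 = ts.points[ts.points["cell_id"] == "track1"]
        assert list(t1["frame"]) == [0, 1, 2]
        assert ts.points["embryo_id"].unique().tolist() == ["e9"]

    def test_mtrackj_missing_column_raises(self, tmp_path):
        path = tmp_path / "points.csv"
        pd.DataFrame({"TID": [1], "PID": [1], "x": [0.0], "y": [0.0]}).to_csv(
            path, index=False)
        with pytest.raises(SchemaError, match="t"):
            read_tracks(path, dialect="mtrackj_points")


class TestValidation:
    def test_non_monotone_frames_rejected_naming_track(self):
        df = build_track([(0, 0), (1, 0), (2, 0)])
        df.loc[2, "frame"] = 1  # duplicate -> caught as duplicate
        with pytest.raises(TrackValidationError):
            TrackSet(points=df)
        df2 = build_track([(0, 0), (1, 0), (2, 0)])
        df2["frame"] = [0, 2, 1]
        with pytest.raises(TrackValidationError, match="c1"):
            TrackSet(points=df2)

    def test_non_finite_coordinates_rejected(self):
        df = build_track([(0, 0), (np.nan, 1)])
        with pytest.raises(TrackValidationError, match="x_um"):
            TrackSet(points=df)

    def test_reader_never_reorders_silently(self, tmp_path):
        df = build_track([(0, 0), (1, 0)])
        df = df.iloc[::-1]  # frames now decreasing
        path = tmp_path / "rev.csv"
        df.to_csv(path, index=False)
        with pytest.raises(TrackValidationError):
            read_tracks(path)


class TestDriftCorrection:
    def test_constant_reference_is_identity(self):
        ts = _random_trackset()
        n = ts.points["frame"].max() + 1
        ref = ReferenceTrajectory("e1", np.arange(n), np.full(n, 7.0), np.full(n, -3.0))
        out = correct_drift(ts, ref)
        pd.testing.assert_frame_equal(out.points, ts.points)

    def test_linear_drift_added_to_all_is_removed(self):
        # drift of (5, 3) um per frame applied to cells and reference alike
        ts = _random_trackset()
        n = ts.points["frame"].max() + 1
        drifted = ts.points.copy()
        drifted["x_um"] += 5.0 * drifted["frame"]
        drifted["y_um"] += 3.0 * drifted["frame"]
        ref = ReferenceTrajectory("e1", np.arange(n),
                                  10.0 + 5.0 * np.arange(n), 3.0 * np.arange(n))
        out = correct_drift(TrackSet(points=drifted), ref)
        np.testing.assert_allclose(out.points["x_um"], ts.points["x_um"], atol=1e-9)
        np.testing.assert_allclose(out.points["y_um"], ts.points["y_um"], atol=1e-9)

    def test_hand_computed_subtraction_on_5_frames(self):
        track = build_track([(0, 0), (1, 0), (2, 1), (3, 1), (4, 2)])
        ref_x = np.array([2.0, 2.5, 1.0, 4.0, 3.0])
        ref_y = np.array([-1.0, 0.0, 0.5, -2.0, 1.0])
        out = correct_drift(TrackSet(points=track),
                            ReferenceTrajectory("e1", np.arange(5), ref_x, ref_y))
        # by hand: offset(f) = ref(f) - ref(0)
        expected_x = track["x_um"].to_numpy() - (ref_x - 2.0)
        expected_y = track["y_um"].to_numpy() - (ref_y - (-1.0))
        np.testing.assert_allclose(out.points["x_um"], expected_x)
        np.testing.assert_allclose(out.points["y_um"], expected_y)

    def test_idempotent_with_constant_reference(self):
        ts = _random_trackset()
        n = ts.points["frame"].max() + 1
        ref = ReferenceTrajectory("e1", np.arange(n),
                                  np.linspace(0, 9, n), np.linspace(0, -4, n))
        once = correct_drift(ts, ref)
        flat = ReferenceTrajectory("e1", np.arange(n), np.zeros(n), np.zeros(n))
        twice = correct_drift(once, flat)
        pd.testing.assert_frame_equal(once.points, twice.points)

    def test_missing_reference_frame_names_embryo_and_frame(self):
        ts = _random_trackset(n_frames=10)
        ref = ReferenceTrajectory("e1", np.arange(9), np.zeros(9), np.zeros(9))
        with pytest.raises(TrackValidationError, match=r"e1.*frame 9"):
            correct_drift(ts, ref)

    def test_missing_embryo_reference_raises(self):
        ts = _random_trackset()
        ref = ReferenceTrajectory("other", np.arange(30), np.zeros(30), np.zeros(30))
        with pytest.raises(TrackValidationError, match="e1"):
            correct_drift(ts, {"other": ref})


class TestCanonicalizeSides:
    def test_left_cell_unchanged(self):
        ts = TrackSet(points=build_track([(-10, 0), (-8, 1)]))
        out = canonicalize_sides(ts, midline_x=0.0)
        pd.testing.assert_frame_equal(out.points, ts.points)
        assert out.axis_convention == "medial_positive_x"

    def test_right_cell_mirrored_about_midline(self):
        ts = TrackSet(points=build_track([(10, 0), (8, 1)]))
        out = canonicalize_sides(ts, midline_x=0.0)
        assert list(out.points["x_um"]) == [-10.0, -8.0]
        assert list(out.points["y_um"]) == [0.0, 1.0]

    def test_mirror_about_nonzero_midline(self):
        ts = TrackSet(points=build_track([(60, 0), (58, 0)]))
        out = canonicalize_sides(ts, midline_x=50.0)
        assert list(out.points["x_um"]) == [40.0, 42.0]

    def test_applied_twice_with_explicit_sides_is_identity(self):
        ts = TrackSet(points=build_track([(10, 0), (8, 1), (6, -1)]))
        sides = {("e1", "c1"): "right"}
        once = canonicalize_sides(ts, 0.0, sides)
        twice = canonicalize_sides(once, 0.0, sides)
        np.testing.assert_allclose(twice.points["x_um"], ts.points["x_um"])

    def test_preserves_abs_dy_and_path_length(self):
        rng = np.random.default_rng(3)
        pts = np.cumsum(rng.normal(0, 1, (20, 2)), axis=0) + (50, 0)
        ts = TrackSet(points=build_track(pts))
        out = canonicalize_sides(ts, midline_x=0.0)
        m0 = compute_cell_metrics(ts.points)
        m1 = compute_cell_metrics(out.points)
        assert m1.dy_net_abs == pytest.approx(m0.dy_net_abs, abs=1e-12)
        assert m1.path_length == pytest.approx(m0.path_length, rel=1e-12)

    def test_mirrored_symmetric_pair_has_equal_direction(self):
        left = build_track([(-30, 0), (-25, 3), (-20, 5)], cell_id="L")
        right = build_track([(30, 0), (25, 3), (20, 5)], cell_id="R")
        ts = TrackSet(points=pd.concat([left, right], ignore_index=True))
        out = canonicalize_sides(ts, midline_x=0.0)
        mL = compute_cell_metrics(out.points[out.points["cell_id"] == "L"])
        mR = compute_cell_metrics(out.points[out.points["cell_id"] == "R"])
        assert mL.direction == pytest.approx(mR.direction, abs=1e-12)

    def test_straddling_track_requires_explicit_side(self):
        ts = TrackSet(points=build_track([(-5, 0), (5, 0)]))
        with pytest.raises(TrackValidationError, match="straddles"):
            canonicalize_sides(ts, midline_x=0.0)
        out = canonicalize_sides(ts, 0.0, {("e1", "c1"): "left"})
        assert list(out.points["x_um"]) == [-5.0, 5.0]

    def test_protrusion_geometry_mirrored_for_right_cells(self):
        ev = pd.DataFrame({
            "embryo_id": ["e1"], "condition": ["ctrl"], "cell_id": ["c1"],
            "event_id": ["p0"], "start_frame": [0], "end_frame": [1],
            "base_x": [20.0], "base_y": [1.0], "tip_x": [23.0], "tip_y": [1.0],
            "length_um": [3.0], "width_um": [1.0], "censored": [False],
        })
        out = track_io.canonicalize_protrusion_sides(ev, midline_x=0.0)
        assert out["base_x"].iloc[0] == -20.0 and out["tip_x"].iloc[0] == -23.0
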