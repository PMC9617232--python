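"""Facial kinematics: EAR/blink detection and mouth/peri-oral variances."""

import dataclasses

import numpy as np
import pytest

import pdscreen as p
from pdscreen import face as F
from pdscreen.errors import DegenerateGeometryError
from pdscreen.simulate import SYNTHETIC_SCHEMA
from pdscreen.types import LandmarkTrack

from conftest import (
    loop_angle_variance,
    loop_pair_distance_variance,
    loop_perioral_variance,
    make_track,
)


def transformed(track, scale=1.0, offset=(0.0, 0.0), angle=0.0, schema=None):
    c = track.coords.copy()
    if angle:
        rot = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        c = c @ rot.T
    c = c * scale + np.asarray(offset)
    return LandmarkTrack.from_array(c, track.ids, track.fps, schema or track.schema)


class TestEarSeries:
    def test_static_face_constant_ear(self, static_track):
        ear = F.ear_series(static_track)
        assert np.allclose(ear.raw, ear.raw[0])
        assert np.allclose(ear.smoothed, ear.raw)

    def test_scaling_leaves_ear_unchanged(self, moving_track):
        a = F.ear_series(moving_track)
        b = F.ear_series(transformed(moving_track, scale=2.0))
        assert np.allclose(a.raw, b.raw)

    def test_planted_dip_produces_smoothed_valley(self):
        track = make_track(n_frames=120)
        c = track.coords.copy()
        ids = list(track.ids)
        for tid, bid in ((12, 13), (22, 23)):  # squeeze lids to 20% of baseline
            ti, bi = ids.index(tid), ids.index(bid)
            mid = 0.38
            c[40:46, ti, 1] = mid - 0.2 * 0.015
            c[40:46, bi, 1] = mid + 0.2 * 0.015
        dipped = LandmarkTrack.from_array(c, track.ids, track.fps, track.schema)
        ear = F.ear_series(dipped)
        assert ear.smoothed[40:75].min() < 0.9 * ear.smoothed[:40].min()
        assert np.argmin(ear.smoothed) in range(40, 76)

    def test_zero_eye_width_raises(self, static_track):
        c = static_track.coords.copy()
        ids = list(static_track.ids)
        c[5, ids.index(10)] = c[5, ids.index(11)]  # collapse right eye width
        bad = LandmarkTrack.from_array(c, static_track.ids, 30.0, static_track.schema)
        with pytest.raises(DegenerateGeometryError, match="frame 5"):
            F.ear_series(bad)


class TestBlinkFraction:
    def test_constant_ear_no_blinks(self, static_track):
        ear = F.ear_series(static_track)
        assert all(F.blink_fraction(ear, t) == 0.0 for t in (30, 50, 70, 90))

    def test_deep_blink_detected_at_90(self):
        track, truth = p.simulate_face(
            p.FaceParams(
                duration_s=10, blink_rate_hz=0.0, jitter_sd=0.0,
                mouth_amp=0.0, perioral_amp=0.0,
            ),
            seed=0,
        )
        c = track.coords.copy()
        ids = list(track.ids)
        for tid, bid in ((12, 13), (22, 23)):
            ti, bi = ids.index(tid), ids.index(bid)
            c[100:120, ti, 1] = 0.38 - 0.05 * 0.015
            c[100:120, bi, 1] = 0.38 + 0.05 * 0.015
        blinked = LandmarkTrack.from_array(c, track.ids, track.fps, track.schema)
        ear = F.ear_series(blinked)
        assert F.blink_fraction(ear, 90) > 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_thresholds_nested(self, seed):
        track, _ = p.simulate_face(
            p.FaceParams(duration_s=20, blink_rate_hz=0.5, blink_duration_frames=18),
            seed=seed,
        )
        ear = F.ear_series(track)
        fr = [F.blink_fraction(ear, t) for t in (30, 50, 70, 90)]
        assert fr[0] <= fr[1] <= fr[2] <= fr[3]


class TestVarianceFeatures:
    def test_static_face_all_zero(self, static_track):
        feats = p.extract_facial_features(static_track)
        assert all(v == 0.0 for v in feats.to_dict().values())

    def test_horizontal_stretch_separates_axes(self):
        track = make_track(n_frames=40)
        c = track.coords.copy()
        ids = list(track.ids)
        stretch = 0.01 * np.sin(np.linspace(0, 4 * np.pi, 40))
        c[:, ids.index(30), 0] -= stretch
        c[:, ids.index(31), 0] += stretch
        t2 = LandmarkTrack.from_array(c, track.ids, 30.0, track.schema)
        assert F.mouth_width_variance(t2) > 0.0
        assert F.mouth_height_variance(t2) == 0.0

    @pytest.mark.parametrize("seed", range(4))
    def test_variances_match_loop_oracles(self, seed):
        track = make_track(n_frames=50, motion_sd=2e-3, seed=seed)
        s = track.schema
        assert F.mouth_eye_distance_variance(track, "right") == pytest.approx(
            loop_pair_distance_variance(track, s.right_eye_outer, s.mouth_corner_right),
            abs=1e-12,
        )
        assert F.mouth_height_variance(track) == pytest.approx(
            loop_pair_distance_variance(track, s.upper_lip, s.lower_lip), abs=1e-12
        )
        assert F.mouth_width_variance(track) == pytest.approx(
            loop_pair_distance_variance(track, s.mouth_corner_right, s.mouth_corner_left),
            abs=1e-12,
        )
        assert F.mouth_angle_variance(track) == pytest.approx(
            loop_angle_variance(track), abs=1e-9
        )
        for side in ("right", "left"):
            assert F.perioral_variance(track, side) == pytest.approx(
                loop_perioral_variance(track, side), abs=1e-12
            )

    def test_translation_and_scale_invariance(self, moving_track):
        base = p.extract_facial_features(moving_track).to_dict()
        moved = p.extract_facial_features(
            transformed(moving_track, scale=1.7, offset=(0.4, -0.2))
        ).to_dict()
        for k in base:
            assert moved[k] == pytest.approx(base[k], rel=1e-9, abs=1e-12), k

    def test_rigid_rotation_preserves_angle_variance(self, moving_track):
        a = F.mouth_angle_variance(moving_track)
        b = F.mouth_angle_variance(transformed(moving_track, angle=0.7))
        assert b == pytest.approx(a, abs=1e-8)

    def test_whole_face_translation_gives_zero_perioral(self, static_track):
        c = static_track.coords + np.linspace(0, 0.05, static_track.n_frames)[:, None, None]
        t2 = LandmarkTrack.from_array(c, static_track.ids, 30.0, static_track.schema)
        assert F.perioral_variance(t2, "right") == pytest.approx(0.0, abs=1e-12)

    def test_zero_face_width_raises(self, static_track):
        c = static_track.coords.copy()
        ids = list(static_track.ids)
        c[3, ids.index(100)] = c[3, ids.index(101)]
        bad = LandmarkTrack.from_array(c, static_track.ids, 30.0, static_track.schema)
        with pytest.raises(DegenerateGeometryError):
            F.mouth_height_variance(bad)


class TestExtractFacialFeatures:
    def test_mirror_flip_swaps_sides_exactly(self):
        track, _ = p.simulate_face(p.FaceParams(duration_s=10), seed=4)
        mirror_schema = dataclasses.replace(
            SYNTHETIC_SCHEMA,
            right_eye_outer=SYNTHETIC_SCHEMA.left_eye_outer,
            right_eye_inner=SYNTHETIC_SCHEMA.left_eye_inner,
            right_eye_top=SYNTHETIC_SCHEMA.left_eye_top,
            right_eye_bottom=SYNTHETIC_SCHEMA.left_eye_bottom,
            left_eye_outer=SYNTHETIC_SCHEMA.right_eye_outer,
            left_eye_inner=SYNTHETIC_SCHEMA.right_eye_inner,
            left_eye_top=SYNTHETIC_SCHEMA.right_eye_top,
            left_eye_bottom=SYNTHETIC_SCHEMA.right_eye_bottom,
            mouth_corner_right=SYNTHETIC_SCHEMA.mouth_corner_left,
            mouth_corner_left=SYNTHETIC_SCHEMA.mouth_corner_right,
            perioral_right=SYNTHETIC_SCHEMA.perioral_left,
            perioral_left=SYNTHETIC_SCHEMA.perioral_right,
        )
        c = track.coords.copy()
        c[:, :, 0] = 1.0 - c[:, :, 0]
        mirrored = LandmarkTrack.from_array(c, track.ids, track.fps, mirror_schema)
        a = p.extract_facial_features(track).to_dict()
        b = p.extract_facial_features(mirrored).to_dict()
        swap = {
            "mouth_eye_var_right": "mouth_eye_var_left",
            "mouth_eye_var_left": "mouth_eye_var_right",
            "perioral_var_right": "perioral_var_left",
            "perioral_var_left": "perioral_var_right",
        }
        for k in a:
            assert b[swap.get(k, k)] == pytest.approx(a[k], abs=1e-12), k
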