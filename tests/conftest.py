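"""Shared fixtures: tone signals, landmark tracks, tiny cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from pdscreen import AudioSignal, LandmarkTrack
from pdscreen.simulate import _BASE_LAYOUT, SYNTHETIC_SCHEMA


def make_tone(f0: float, duration: float = 2.0, amplitude: float = 3000.0,
              sample_rate: int = 44100, phase: float = 0.0) -> AudioSignal:
    t = np.arange(int(duration * sample_rate)) / sample_rate
    return AudioSignal(amplitude * np.sin(2 * np.pi * f0 * t + phase), sample_rate)


def make_track(n_frames: int = 60, fps: float = 30.0, motion_sd: float = 0.0,
               seed: int = 0, schema=SYNTHETIC_SCHEMA) -> LandmarkTrack:
    """Neutral face, optionally with smooth random landmark motion."""
    rng = np.random.default_rng(seed)
    ids = sorted(_BASE_LAYOUT)
    coords = np.tile(np.array([_BASE_LAYOUT[i] for i in ids]), (n_frames, 1, 1))
    if motion_sd > 0:
        # smooth random walk so frame-to-frame changes stay facial-motion sized
        steps = rng.normal(0.0, motion_sd, size=coords.shape)
        coords = coords + np.cumsum(steps, axis=0) / np.sqrt(np.arange(1, n_frames + 1))[:, None, None]
    return LandmarkTrack.from_array(coords, ids, fps=fps, schema=schema)


@pytest.fixture
def static_track() -> LandmarkTrack:
    return make_track(n_frames=90)


@pytest.fixture
def moving_track() -> LandmarkTrack:
    return make_track(n_frames=90, motion_sd=2e-3, seed=3)


# ------------------------------------------------------------------ oracles


def brute_force_crossings(samples: np.ndarray, samples_per_frame: int) -> list[int]:
    """Independent per-frame zero-crossing count: explicit pairwise scan with
    zero samples adopting the previous nonzero sign; a consecutive-sample pair
    belongs to the frame holding its right-hand sample."""
    n_frames = len(samples) // samples_per_frame
    framed = samples[: n_frames * samples_per_frame]
    sign, signs = 0.0, []
    for x in framed:
        if x > 0:
            sign = 1.0
        elif x < 0:
            sign = -1.0
        signs.append(sign)
    counts = [0] * n_frames
    for i in range(1, len(framed)):
        if signs[i - 1] * signs[i] < 0:
            counts[i // samples_per_frame] += 1
    return counts


def brute_force_pause_count(volumes: np.ndarray) -> int:
    threshold = 30.0 if volumes.mean() > 100.0 else 20.0
    return int(sum(1 for v in volumes if v < threshold))


def brute_force_auroc(y: np.ndarray, scores: np.ndarray) -> float:
    """All-pairs concordance with ties counted 1/2."""
    pos = scores[np.asarray(y) == 1]
    neg = scores[np.asarray(y) == 0]
    total = len(pos) * len(neg)
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / total


def loop_pair_distance_variance(track: LandmarkTrack, id_a: int, id_b: int) -> float:
    """Naive frame loop: sum |d_t - d_{t-1}| / face_width_t / n_frames."""
    wa, wb = track.schema.face_width_pair
    total = 0.0
    for t in range(1, track.n_frames):
        d_t = float(np.hypot(*(track.xy(id_a)[t] - track.xy(id_b)[t])))
        d_p = float(np.hypot(*(track.xy(id_a)[t - 1] - track.xy(id_b)[t - 1])))
        fw = float(np.hypot(*(track.xy(wa)[t] - track.xy(wb)[t])))
        total += abs(d_t - d_p) / fw
    return total / track.n_frames


def loop_perioral_variance(track: LandmarkTrack, side: str) -> float:
    nose = track.schema.nose_center
    wa, wb = track.schema.face_width_pair
    ring = getattr(track.schema, f"perioral_{side}")
    total = 0.0
    for t in range(1, track.n_frames):
        fw = float(np.hypot(*(track.xy(wa)[t] - track.xy(wb)[t])))
        for p in ring:
            d_t = float(np.hypot(*(track.xy(nose)[t] - track.xy(p)[t])))
            d_p = float(np.hypot(*(track.xy(nose)[t - 1] - track.xy(p)[t - 1])))
            total += abs(d_t - d_p) / fw
    return total / track.n_frames


def loop_angle_variance(track: LandmarkTrack) -> float:
    s = track.schema
    angles = []
    for t in range(track.n_frames):
        v1 = track.xy(s.mouth_corner_left)[t] - track.xy(s.mouth_corner_right)[t]
        v2 = track.xy(s.lower_lip)[t] - track.xy(s.upper_lip)[t]
        c = abs(float(np.dot(v1, v2))) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        angles.append(np.degrees(np.arccos(min(max(c, -1.0), 1.0))))
    return sum(abs(angles[t] - angles[t - 1]) for t in range(1, len(angles))) / track.n_frames
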