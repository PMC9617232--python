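"""Blink and oro-facial kinematics features from a facial landmark track.

Blinking is detected through the eye aspect ratio (EAR = eye height / eye
width, averaged over both eyes), smoothed with a trailing 30-frame rolling
mean.  A frame is "in blink" at threshold p% when the smoothed EAR drops
below p% of its overall mean; the feature is the in-blink fraction of frames,
reported at the four thresholds 30/50/70/90%.  Hypomimia shows up as lower
blink fractions.

Every mouth/peri-oral feature is a mean per-frame absolute change of a
landmark distance, divided frame-wise by the face width (distance between two
face-outline anchors) so that camera zoom and distance cancel; the mouth
angle feature uses the crossing angle between the mouth-corner line and the
upper-to-lower-lip line (degrees, acute) and needs no width normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, InputError
from .types import LandmarkTrack

__all__ = [
    "EarSeries",
    "FaceConfig",
    "FacialFeatures",
    "ear_series",
    "blink_fraction",
    "mouth_eye_distance_variance",
    "mouth_height_variance",
    "mouth_width_variance",
    "mouth_angle_variance",
    "perioral_variance",
    "extract_facial_features",
]

BLINK_THRESHOLDS = (30, 50, 70, 90)


@dataclass
class FaceConfig:
    """Tunable conventions for the facial extractor."""

    ear_window: int = 30  # trailing rolling-mean window, frames (~1 s at 30 fps)
    average_eyes: bool = True  # EAR averaged over both eyes


@dataclass
class EarSeries:
    """Per-frame eye aspect ratio, raw and smoothed."""

    raw: np.ndarray
    smoothed: np.ndarray
    window: int


@dataclass
class FacialFeatures:
    """Per-subject facial feature vector (11 values)."""

    blink_30: float
    blink_50: float
    blink_70: float
    blink_90: float
    mouth_eye_var_right: float
    mouth_eye_var_left: float
    mouth_height_var: float
    mouth_width_var: float
    mouth_angle_var: float
    perioral_var_right: float
    perioral_var_left: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _dist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.linalg.norm(a - b, axis=-1)


def _face_width(track: LandmarkTrack) -> np.ndarray:
    i, j = track.schema.face_width_pair
    fw = _dist(track.xy(i), track.xy(j))
    if np.any(fw <= 0):
        t = int(np.flatnonzero(fw <= 0)[0])
        raise DegenerateGeometryError(f"zero face width at frame {t}")
    return fw


def ear_series(track: LandmarkTrack, window: int = 30) -> EarSeries:
    """Eye aspect ratio per frame, averaged over both eyes, with trailing
    rolling mean (edge frames use the available shorter window)."""
    ears = []
    for side in ("right", "left"):
        top = track.role_xy(f"{side}_eye_top")
        bottom = track.role_xy(f"{side}_eye_bottom")
        outer = track.role_xy(f"{side}_eye_outer")
        inner = track.role_xy(f"{side}_eye_inner")
        width = _dist(outer, inner)
        if np.any(width <= 0):
            t = int(np.flatnonzero(width <= 0)[0])
            raise DegenerateGeometryError(f"zero {side} eye width at frame {t}")
        ears.append(_dist(top, bottom) / width)
    raw = np.mean(ears, axis=0)
    smoothed = pd.Series(raw).rolling(window, min_periods=1).mean().to_numpy()
    return EarSeries(raw=raw, smoothed=smoothed, window=window)


def blink_fraction(ear: EarSeries, threshold_pct: int) -> float:
    """Fraction of frames whose smoothed EAR lies below threshold_pct % of the
    mean smoothed EAR."""
    if ear.smoothed.size == 0:
        raise InputError("empty EAR series")
    cut = (threshold_pct / 100.0) * float(ear.smoothed.mean())
    return float((ear.smoothed < cut).mean())


def _change_variance(track: LandmarkTrack, dists: np.ndarray) -> float:
    """Sum_t |d_t - d_{t-1}| / face_width_t / n_frames (face width at the
    current frame, so zoom drift cancels)."""
    if track.n_frames < 2:
        raise InputError("variance features need at least 2 frames")
    fw = _face_width(track)
    steps = np.abs(np.diff(dists, axis=0))
    if steps.ndim > 1:  # multiple point distances: sum over points per frame
        steps = steps.sum(axis=1)
    return float((steps / fw[1:]).sum()) / track.n_frames


def mouth_eye_distance_variance(track: LandmarkTrack, side: str) -> float:
    """Mean per-frame change of the outer-eye-corner-to-mouth-corner distance
    on one side, face-width normalised."""
    eye = track.role_xy(f"{side}_eye_outer")
    mouth = track.role_xy(f"mouth_corner_{side}")
    return _change_variance(track, _dist(eye, mouth))


def mouth_height_variance(track: LandmarkTrack) -> float:
    """Mean per-frame change of the upper-to-lower-lip distance."""
    return _change_variance(
        track, _dist(track.role_xy("upper_lip"), track.role_xy("lower_lip"))
    )


def mouth_width_variance(track: LandmarkTrack) -> float:
    """Mean per-frame change of the mouth-corner-to-corner distance."""
    return _change_variance(
        track,
        _dist(track.role_xy("mouth_corner_right"), track.role_xy("mouth_corner_left")),
    )


def mouth_angle_variance(track: LandmarkTrack) -> float:
    """Mean per-frame change (degrees) of the acute crossing angle between the
    mouth-width line and the lip-to-lip line; no width normalisation."""
    if track.n_frames < 2:
        raise InputError("variance features need at least 2 frames")
    v1 = track.role_xy("mouth_corner_left") - track.role_xy("mouth_corner_right")
    v2 = track.role_xy("lower_lip") - track.role_xy("upper_lip")
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    if np.any(n1 <= 0) or np.any(n2 <= 0):
        t = int(np.flatnonzero((n1 <= 0) | (n2 <= 0))[0])
        raise DegenerateGeometryError(f"degenerate mouth line at frame {t}")
    cosang = np.abs((v1 * v2).sum(axis=1)) / (n1 * n2)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))  # acute, [0, 90]
    return float(np.abs(np.diff(ang)).sum()) / track.n_frames


def perioral_variance(track: LandmarkTrack, side: str) -> float:
    """Mean per-frame total change of the six nose-to-peri-oral-point
    distances on one side, face-width normalised."""
    nose = track.role_xy("nose_center")
    ring = getattr(track.schema, f"perioral_{side}")
    dists = np.stack([_dist(nose, track.xy(p)) for p in ring], axis=1)
    return _change_variance(track, dists)


def extract_facial_features(
    track: LandmarkTrack, config: FaceConfig | None = None
) -> FacialFeatures:
    """Compute the full 11-value facial feature vector for one subject."""
    cfg = config or FaceConfig()
    ear = ear_series(track, window=cfg.ear_window)
    blink = {p: blink_fraction(ear, p) for p in BLINK_THRESHOLDS}
    return FacialFeatures(
        blink_30=blink[30],
        blink_50=blink[50],
        blink_70=blink[70],
        blink_90=blink[90],
        mouth_eye_var_right=mouth_eye_distance_variance(track, "right"),
        mouth_eye_var_left=mouth_eye_distance_variance(track, "left"),
        mouth_height_var=mouth_height_variance(track),
        mouth_width_var=mouth_width_variance(track),
        mouth_angle_var=mouth_angle_variance(track),
        perioral_var_right=perioral_variance(track, "right"),
        perioral_var_left=perioral_variance(track, "left"),
    )
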