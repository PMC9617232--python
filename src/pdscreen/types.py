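"""Domain containers: audio signals, landmark tracks/schemas, subject metadata.

Conventions
-----------
* Audio amplitudes live on the 16-bit signed-integer scale (|x| <= 32767)
  regardless of the source file's bit depth, so the absolute pause thresholds
  used by the voice features are meaningful.
* Landmark coordinates are image-normalised (x, y roughly in [0, 1]).  All
  facial distances are divided by a per-frame face width downstream, so the
  absolute units never matter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from typing import Mapping, Sequence

import numpy as np

from .errors import InputError, SchemaError

__all__ = [
    "AudioSignal",
    "LandmarkSchema",
    "LandmarkTrack",
    "SubjectRecord",
]


@dataclass
class AudioSignal:
    """A mono sampled waveform on the 16-bit signed-integer amplitude scale."""

    samples: np.ndarray
    sample_rate: int = 44100
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise InputError("AudioSignal requires a non-empty 1-D sample array")
        if self.sample_rate <= 0:
            raise InputError(f"sample_rate must be positive, got {self.sample_rate}")
        peak = float(np.max(np.abs(self.samples)))
        if peak > 32767.0 + 1e-6:
            raise InputError(
                f"samples exceed the 16-bit scale (max |x| = {peak:.1f} > 32767)"
            )

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return self.samples.size / self.sample_rate


# roles that name a single landmark id
_SINGLE_ROLES = (
    "right_eye_outer",
    "right_eye_inner",
    "right_eye_top",
    "right_eye_bottom",
    "left_eye_outer",
    "left_eye_inner",
    "left_eye_top",
    "left_eye_bottom",
    "mouth_corner_right",
    "mouth_corner_left",
    "upper_lip",
    "lower_lip",
    "nose_center",
)


@dataclass(frozen=True)
class LandmarkSchema:
    """Maps semantic facial roles to landmark ids.

    Peri-oral rings hold exactly six points per side (mouth/jaw area), and
    ``face_width_pair`` names the two face-outline anchors whose distance is
    the per-frame scale normaliser.
    """

    right_eye_outer: int
    right_eye_inner: int
    right_eye_top: int
    right_eye_bottom: int
    left_eye_outer: int
    left_eye_inner: int
    left_eye_top: int
    left_eye_bottom: int
    mouth_corner_right: int
    mouth_corner_left: int
    upper_lip: int
    lower_lip: int
    nose_center: int
    perioral_right: tuple[int, ...] = field(default_factory=tuple)
    perioral_left: tuple[int, ...] = field(default_factory=tuple)
    face_width_pair: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "perioral_right", tuple(self.perioral_right))
        object.__setattr__(self, "perioral_left", tuple(self.perioral_left))
        object.__setattr__(self, "face_width_pair", tuple(self.face_width_pair))
        for side in ("perioral_right", "perioral_left"):
            ring = getattr(self, side)
            if len(ring) != 6:
                raise SchemaError(f"{side} must name exactly 6 landmark ids, got {len(ring)}")
            if len(set(ring)) != 6:
                raise SchemaError(f"{side} ids must be distinct")
        if len(self.face_width_pair) != 2 or self.face_width_pair[0] == self.face_width_pair[1]:
            raise SchemaError("face_width_pair must be two distinct landmark ids")

    def required_ids(self) -> tuple[int, ...]:
        """All landmark ids any frame must contain, in a fixed order."""
        ids: list[int] = [getattr(self, r) for r in _SINGLE_ROLES]
        ids.extend(self.perioral_right)
        ids.extend(self.perioral_left)
        ids.extend(self.face_width_pair)
        # preserve first-seen order, drop duplicates across roles
        seen: dict[int, None] = {}
        for i in ids:
            seen.setdefault(i, None)
        return tuple(seen)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "LandmarkSchema":
        return cls(**{k: v for k, v in d.items()})

    @classmethod
    def from_json(cls, path) -> "LandmarkSchema":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


class LandmarkTrack:
    """Time-indexed 2-D facial landmark coordinates.

    Internally a dense (n_frames, n_landmarks, 2) float array plus an id->column
    map; construction validates that every frame carries every id the schema
    requires.
    """

    def __init__(
        self,
        frames: Sequence[Mapping[int, tuple[float, float]]],
        fps: float,
        schema: LandmarkSchema,
        subject_id: str = "",
    ) -> None:
        if fps <= 0:
            raise InputError(f"fps must be positive, got {fps}")
        if len(frames) == 0:
            raise InputError("LandmarkTrack requires at least one frame")
        required = schema.required_ids()
        for t, fr in enumerate(frames):
            missing = [i for i in required if i not in fr]
            if missing:
                raise SchemaError(
                    f"frame {t} is missing required landmark id(s) {missing}"
                )
        self.ids: tuple[int, ...] = required
        self._col = {i: k for k, i in enumerate(required)}
        coords = np.empty((len(frames), len(required), 2), dtype=np.float64)
        for t, fr in enumerate(frames):
            for i, k in self._col.items():
                coords[t, k, :] = fr[i]
        self.coords = coords
        self.fps = float(fps)
        self.schema = schema
        self.subject_id = subject_id

    @classmethod
    def from_array(
        cls,
        coords: np.ndarray,
        ids: Sequence[int],
        fps: float,
        schema: LandmarkSchema,
        subject_id: str = "",
    ) -> "LandmarkTrack":
        """Build directly from a (n_frames, n_landmarks, 2) array."""
        coords = np.asarray(coords, dtype=np.float64)
        if coords.ndim != 3 or coords.shape[2] != 2:
            raise InputError("coords must have shape (n_frames, n_landmarks, 2)")
        obj = cls.__new__(cls)
        col = {int(i): k for k, i in enumerate(ids)}
        missing = [i for i in schema.required_ids() if i not in col]
        if missing:
            raise SchemaError(f"coords array is missing required landmark id(s) {missing}")
        if fps <= 0:
            raise InputError(f"fps must be positive, got {fps}")
        obj.ids = tuple(int(i) for i in ids)
        obj._col = col
        obj.coords = coords
        obj.fps = float(fps)
        obj.schema = schema
        obj.subject_id = subject_id
        return obj

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def xy(self, landmark_id: int) -> np.ndarray:
        """(n_frames, 2) trajectory of one landmark."""
        return self.coords[:, self._col[landmark_id], :]

    def role_xy(self, role: str) -> np.ndarray:
        """Trajectory of the single landmark filling a schema role."""
        return self.xy(getattr(self.schema, role))


@dataclass
class SubjectRecord:
    """Demographics and label for one subject."""

    subject_id: str
    age: float
    sex: str  # "male" | "female"
    label: str  # "PD" | "control"
    stage: float | None = None  # Hoehn-Yahr; stage < 3 is early disease
    phase: str | None = None  # "on" | "off" | "drug_naive"

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise InputError(f"age must be positive, got {self.age}")
        if self.sex not in ("male", "female"):
            raise InputError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.label not in ("PD", "control"):
            raise InputError(f"label must be 'PD' or 'control', got {self.label!r}")
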