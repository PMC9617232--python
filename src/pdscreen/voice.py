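"""Short-time acoustic features of a reading-task recording.

The feature set targets parkinsonian dysarthria and is deliberately simple:

* ``reading_time`` — seconds between the first and last non-pause frame.
* ``pause_percentage`` — percent of 25-ms frames whose volume falls below an
  absolute threshold (30 if the recording's mean volume exceeds 100 on the
  16-bit scale, else 20).
* ``volume_variance`` — relative drift of loudness, 100 x (mean volume of the
  first half - mean volume of the second half) / overall mean volume.
  Negative means the speaker got louder over time.
* ``average_pitch`` — fundamental-frequency estimate from zero-crossing counts
  in 10-ms frames; a near-periodic signal of frequency f crosses zero 2f times
  per second, so Hz = mean count / (2 x frame duration).
* ``pitch_variance`` — mean absolute frame-to-frame change of the crossing
  count over voiced frames, on the same Hz scale; a monotone voice scores low.

Volume is the mean absolute amplitude per frame (configurable to RMS) on the
16-bit integer scale, which is what makes the absolute pause thresholds
meaningful.  Pitch statistics are computed over voiced (non-pause) frames by
default because silent frames produce spurious noise crossings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import FeatureUndefinedError, InputError
from .types import AudioSignal

__all__ = [
    "FrameSeries",
    "VoiceConfig",
    "VoiceFeatures",
    "frame_volume",
    "pause_threshold",
    "pause_mask",
    "pause_percentage",
    "volume_variance",
    "zero_crossings",
    "average_pitch",
    "pitch_variance",
    "reading_time",
    "voiced_mask_from_pauses",
    "extract_voice_features",
]


@dataclass
class FrameSeries:
    """Per-frame scalar series (volume or zero-crossing counts)."""

    values: np.ndarray
    frame_duration: float  # seconds
    kind: str  # "volume" | "crossings"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.frame_duration <= 0:
            raise InputError("frame_duration must be positive")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class VoiceConfig:
    """Tunable conventions for the voice extractor."""

    volume_frame_s: float = 0.025  # frame blocking for volume/pause analysis
    pitch_frame_s: float = 0.010  # frame blocking for zero-crossing counts
    volume_stat: str = "mean_abs"  # or "rms"
    pitch_in_hz: bool = True  # False: raw crossing counts per frame
    volume_variance_x100: bool = False  # handled by extract (reported x100)
    voiced_frames_only: bool = True  # pitch stats over non-pause frames
    highpass_hz: float | None = None  # optional pre-filter, off by default


@dataclass
class VoiceFeatures:
    """Per-subject voice feature vector."""

    reading_time: float  # seconds
    pause_percentage: float  # % of frames
    volume_variance: float  # dimensionless x100
    average_pitch: float  # Hz
    pitch_variance: float  # Hz-scale mean |frame-to-frame change|
    phonetic_score: float | None = None  # optional passthrough

    def to_dict(self) -> dict:
        d = {
            "reading_time": self.reading_time,
            "pause_percentage": self.pause_percentage,
            "volume_variance": self.volume_variance,
            "average_pitch": self.average_pitch,
            "pitch_variance": self.pitch_variance,
        }
        if self.phonetic_score is not None:
            d["phonetic_score"] = self.phonetic_score
        return d


def _frame_view(signal: AudioSignal, frame_duration: float) -> np.ndarray:
    spf = int(round(frame_duration * signal.sample_rate))
    if spf <= 0:
        raise InputError("frame_duration too small for this sample rate")
    n = signal.samples.size // spf
    if n == 0:
        raise InputError(
            f"signal of {signal.duration:.4f}s is shorter than one "
            f"{frame_duration * 1e3:.0f}-ms frame"
        )
    return signal.samples[: n * spf].reshape(n, spf)


def frame_volume(
    signal: AudioSignal, frame_duration: float = 0.025, stat: str = "mean_abs"
) -> FrameSeries:
    """Per-frame volume; the trailing partial frame is dropped."""
    frames = _frame_view(signal, frame_duration)
    if stat == "mean_abs":
        vals = np.abs(frames).mean(axis=1)
    elif stat == "rms":
        vals = np.sqrt((frames**2).mean(axis=1))
    else:
        raise InputError(f"unknown volume stat {stat!r}")
    return FrameSeries(vals, frame_duration, "volume")


def pause_threshold(volumes: FrameSeries) -> float:
    """Absolute pause threshold: 30 when mean volume exceeds 100, else 20."""
    if len(volumes) == 0:
        raise InputError("empty volume series")
    return 30.0 if float(volumes.values.mean()) > 100.0 else 20.0


def pause_mask(volumes: FrameSeries) -> np.ndarray:
    """Boolean mask of pause frames (volume strictly below the threshold)."""
    return volumes.values < pause_threshold(volumes)


def pause_percentage(volumes: FrameSeries) -> float:
    """Percent of frames counted as pause."""
    return 100.0 * float(pause_mask(volumes).mean())


def volume_variance(volumes: FrameSeries, x100: bool = True) -> float:
    """Relative loudness drift between the two halves of the recording.

    With an odd frame count the middle frame joins the first half.  Positive
    means the voice faded; negative means it got louder.
    """
    v = volumes.values
    if v.size < 2:
        raise InputError("volume variance needs at least 2 frames")
    total = float(v.mean())
    if total <= 0:
        raise FeatureUndefinedError("volume variance undefined for silent signal")
    cut = (v.size + 1) // 2  # middle frame goes to the first half
    value = (float(v[:cut].mean()) - float(v[cut:].mean())) / total
    return 100.0 * value if x100 else value


def zero_crossings(signal: AudioSignal, frame_duration: float = 0.010) -> FrameSeries:
    """Zero-crossing count per frame.

    A crossing is a sign change between consecutive samples within the frame;
    zero samples adopt the sign of the last nonzero sample, so a single touch
    of zero counts once, not twice.
    """
    spf = int(round(frame_duration * signal.sample_rate))
    frames = _frame_view(signal, frame_duration)
    n = frames.shape[0]
    x = signal.samples[: n * spf]
    s = np.sign(x)
    # forward-fill zero signs with the previous nonzero sign
    idx = np.where(s != 0, np.arange(s.size), -1)
    np.maximum.accumulate(idx, out=idx)
    filled = np.where(idx >= 0, s[np.maximum(idx, 0)], 0.0)
    cross = (filled[1:] * filled[:-1]) < 0  # cross[j]: pair (j, j+1)
    csum = np.concatenate(([0], np.cumsum(cross)))
    starts = np.arange(n) * spf
    # a pair belongs to the frame holding its right-hand sample, so crossings
    # landing exactly on a frame boundary are never dropped
    counts = csum[starts + spf - 1] - csum[np.maximum(starts - 1, 0)]
    return FrameSeries(counts, frame_duration, "crossings")


def _voiced_values(crossings: FrameSeries, voiced_mask) -> np.ndarray:
    if voiced_mask is None:
        return crossings.values
    voiced_mask = np.asarray(voiced_mask, dtype=bool)
    if voiced_mask.size != len(crossings):
        raise InputError("voiced_mask length must match the crossing series")
    return crossings.values[voiced_mask]


def average_pitch(
    crossings: FrameSeries, voiced_mask=None, in_hz: bool = True
) -> float:
    """Mean crossing count over voiced frames, optionally converted to Hz."""
    v = _voiced_values(crossings, voiced_mask)
    if v.size == 0:
        raise FeatureUndefinedError("average pitch undefined: no voiced frames")
    mean_count = float(v.mean())
    return mean_count / (2.0 * crossings.frame_duration) if in_hz else mean_count


def pitch_variance(
    crossings: FrameSeries, voiced_mask=None, in_hz: bool = True
) -> float:
    """Mean |change| of crossing counts between consecutive voiced frames."""
    v = _voiced_values(crossings, voiced_mask)
    if v.size < 2:
        raise FeatureUndefinedError("pitch variance undefined: < 2 voiced frames")
    mad = float(np.abs(np.diff(v)).mean())
    return mad / (2.0 * crossings.frame_duration) if in_hz else mad


def reading_time(volumes: FrameSeries) -> float:
    """Seconds spanned by the first through last non-pause frame."""
    speech = ~pause_mask(volumes)
    if not speech.any():
        raise FeatureUndefinedError("reading time undefined: all frames are pause")
    idx = np.flatnonzero(speech)
    return (idx[-1] - idx[0] + 1) * volumes.frame_duration


def voiced_mask_from_pauses(
    volumes: FrameSeries, n_pitch_frames: int, pitch_frame_s: float
) -> np.ndarray:
    """Resample the non-pause mask from the volume grid to the pitch grid.

    A pitch frame is voiced when at least half of its duration overlaps
    non-pause volume frames; time past the framed volume coverage counts as
    pause.
    """
    nonpause = ~pause_mask(volumes)
    vfd = volumes.frame_duration
    a = np.arange(n_pitch_frames) * pitch_frame_s
    b = a + pitch_frame_s
    overlap = np.zeros(n_pitch_frames)
    span = int(math.ceil(pitch_frame_s / vfd)) + 1
    i0 = np.floor(a / vfd + 1e-9).astype(int)
    for j in range(span + 1):
        i = i0 + j
        valid = i < len(volumes)
        lo = np.maximum(a, i * vfd)
        hi = np.minimum(b, (i + 1) * vfd)
        piece = np.clip(hi - lo, 0.0, None)
        overlap += np.where(valid & nonpause[np.minimum(i, len(volumes) - 1)], piece, 0.0)
    return overlap >= 0.5 * pitch_frame_s


def extract_voice_features(
    signal: AudioSignal,
    config: VoiceConfig | None = None,
    phonetic_score: float | None = None,
) -> VoiceFeatures:
    """Compute the full voice feature vector for one subject."""
    cfg = config or VoiceConfig()
    vols = frame_volume(signal, cfg.volume_frame_s, cfg.volume_stat)
    cz = zero_crossings(signal, cfg.pitch_frame_s)
    mask = (
        voiced_mask_from_pauses(vols, len(cz), cfg.pitch_frame_s)
        if cfg.voiced_frames_only
        else None
    )
    return VoiceFeatures(
        reading_time=reading_time(vols),
        pause_percentage=pause_percentage(vols),
        volume_variance=volume_variance(vols, x100=True),
        average_pitch=average_pitch(cz, mask, in_hz=cfg.pitch_in_hz),
        pitch_variance=pitch_variance(cz, mask, in_hz=cfg.pitch_in_hz),
        phonetic_score=phonetic_score,
    )
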