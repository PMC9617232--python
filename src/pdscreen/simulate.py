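"""Synthetic cohort generator with analytic ground truth.

Real reading-task recordings of Parkinson's patients are not redistributable,
so every stage of the package is exercised on simulated subjects instead.
The generator emulates the statistical structure of the clinical cohorts:

* voice — alternating voiced/pause segments; voiced segments are sinusoids at
  a per-subject fundamental frequency with per-10-ms jitter (sinusoids rather
  than synthesised speech because the downstream features — zero crossings,
  frame volumes, pauses — are insensitive to phonetic content and a sinusoid
  gives analytic ground truth); amplitude follows a linear drift that plants
  the sign of the volume-variance feature.
* face — a canonical neutral landmark layout; blinks are raised-cosine EAR
  valleys arriving at a Poisson rate with configurable depth and duration;
  mouth and peri-oral landmarks oscillate with configurable amplitude; an
  optional global zoom/translation drift checks that extraction is scale-free.

Group effects are planted only in the features the clinical data found
discriminative (reading time, pause percentage, volume drift, pitch jitter,
blink rate/depth); mouth-motion parameters are drawn identically for both
groups so feature selection has true negatives to reject.  ``effect_scale``
multiplies every group-mean separation: 0 makes the groups exchangeable, 1 is
the default clinically-motivated separation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .face import FaceConfig, extract_facial_features
from .types import AudioSignal, LandmarkSchema, LandmarkTrack, SubjectRecord
from .voice import VoiceConfig, extract_voice_features

__all__ = [
    "SYNTHETIC_SCHEMA",
    "VoiceParams",
    "FaceParams",
    "CohortConfig",
    "Cohort",
    "SimulatedCohort",
    "simulate_voice",
    "simulate_face",
    "simulate_cohort",
    "extract_features",
    "cohort_table",
]

#: mirror-symmetric landmark layout: flipping x -> 1 - x maps each right-side
#: id onto its left-side partner's position and vice versa
SYNTHETIC_SCHEMA = LandmarkSchema(
    right_eye_outer=10,
    right_eye_inner=11,
    right_eye_top=12,
    right_eye_bottom=13,
    left_eye_outer=20,
    left_eye_inner=21,
    left_eye_top=22,
    left_eye_bottom=23,
    mouth_corner_right=30,
    mouth_corner_left=31,
    upper_lip=32,
    lower_lip=33,
    nose_center=1,
    perioral_right=(40, 41, 42, 43, 44, 45),
    perioral_left=(50, 51, 52, 53, 54, 55),
    face_width_pair=(100, 101),
)

# neutral layout, image-normalised coordinates; left side mirrors right
_BASE_LAYOUT: dict[int, tuple[float, float]] = {
    1: (0.50, 0.50),  # nose center
    10: (0.35, 0.38),  # right eye outer
    11: (0.45, 0.38),  # right eye inner
    12: (0.40, 0.365),  # right eye top
    13: (0.40, 0.395),  # right eye bottom
    20: (0.65, 0.38),
    21: (0.55, 0.38),
    22: (0.60, 0.365),
    23: (0.60, 0.395),
    30: (0.42, 0.62),  # mouth corner right
    31: (0.58, 0.62),  # mouth corner left
    32: (0.50, 0.60),  # upper lip
    33: (0.50, 0.64),  # lower lip
    40: (0.41, 0.57),
    41: (0.39, 0.61),
    42: (0.40, 0.65),
    43: (0.43, 0.68),
    44: (0.46, 0.70),
    45: (0.44, 0.56),
    50: (0.59, 0.57),
    51: (0.61, 0.61),
    52: (0.60, 0.65),
    53: (0.57, 0.68),
    54: (0.54, 0.70),
    55: (0.56, 0.56),
    100: (0.30, 0.50),  # face-width anchors
    101: (0.70, 0.50),
}

_BASE_EAR = 0.03 / 0.10  # eye height / width of the neutral layout


# ---------------------------------------------------------------- voice


@dataclass
class VoiceParams:
    """Per-subject voice generation parameters."""

    duration_s: float = 52.0  # reading time
    f0_mean: float = 157.0  # Hz
    f0_jitter_sd: float = 16.0  # Hz, iid per 10-ms block
    pause_fraction: float = 0.134
    voiced_segment_s: float = 1.5  # mean voiced-segment length
    amplitude: float = 3000.0  # 16-bit scale
    volume_drift: float = 0.0  # relative fade; + = fading, - = getting louder
    pause_noise_sd: float = 0.8  # well below either pause threshold
    voiced_noise_sd: float = 10.0
    dc_offset: float = 4.0  # room-tone bias >> pause noise: silence must not chatter around zero
    sample_rate: int = 44100


def simulate_voice(params: VoiceParams, seed) -> tuple[AudioSignal, dict]:
    """Generate one subject's WAV-ready waveform and its ground truth.

    Segment boundaries are quantised to a 50-ms grid (the least common
    multiple of the 25-ms volume and 10-ms pitch analysis frames) so that no
    analysis frame straddles a voiced/pause boundary and the planted pause
    fraction is recovered exactly up to thresholding.  Additive noise is
    band-limited (smoothed white noise): broadband noise inside a voiced
    frame would create spurious sign flickers near the sinusoid's zero
    crossings, whereas slowly varying noise only shifts the crossing times.
    """
    rng = np.random.default_rng(seed)
    sr = params.sample_rate
    grid = int(round(0.050 * sr))  # lcm of both analysis frames
    n = max(int(round(params.duration_s * sr / grid)), 2) * grid
    # alternating voiced/pause segments; first and last are voiced so the
    # computed reading time spans the whole recording
    pf = min(max(params.pause_fraction, 0.0), 0.9)
    pause_mean = params.voiced_segment_s * pf / max(1.0 - pf, 1e-6)
    voiced = np.zeros(n, dtype=bool)
    pos, is_voiced = 0, True
    while pos < n:
        if not is_voiced and pause_mean <= 0:
            is_voiced = True
            continue
        mean = params.voiced_segment_s if is_voiced else pause_mean
        seg = int(round(rng.gamma(4.0, max(mean, 0.05) / 4.0) * sr / grid)) * grid
        seg = max(seg, grid)
        voiced[pos : pos + seg] = is_voiced
        pos += seg
        is_voiced = not is_voiced
    voiced[-4 * grid :] = True  # end voiced (0.2 s, grid-aligned)

    # phase-continuous sinusoid with per-10-ms F0 jitter
    block = max(int(round(0.010 * sr)), 1)
    n_blocks = -(-n // block)
    f0_blocks = params.f0_mean + rng.normal(0.0, params.f0_jitter_sd, n_blocks)
    f0_blocks = np.clip(f0_blocks, 60.0, 400.0)
    f0 = np.repeat(f0_blocks, block)[:n]
    # random start phase keeps crossings off the exact frame-boundary grid
    phase = rng.uniform(0.0, 2.0 * np.pi) + 2.0 * np.pi * np.cumsum(f0) / sr
    t_rel = np.arange(n) / n  # 0..1
    env = params.amplitude * np.clip(1.0 - params.volume_drift * (t_rel - 0.5), 0.05, None)
    x = np.where(voiced, env * np.sin(phase), 0.0)
    smooth = 882  # ~20 ms correlation: low-rumble noise, ~0 crossings per 10-ms frame
    noise = uniform_filter1d(rng.standard_normal(n), size=smooth) * np.sqrt(smooth)
    x += np.where(voiced, params.voiced_noise_sd, params.pause_noise_sd) * noise
    x += params.dc_offset
    x = np.clip(x, -32767.0, 32767.0)
    truth = {
        "pause_fraction": float(1.0 - voiced.mean()),
        "f0_mean": params.f0_mean,
        "f0_realized": float(f0[voiced].mean()),
        "f0_jitter_sd": params.f0_jitter_sd,
        "volume_drift": params.volume_drift,
        "duration_s": n / sr,
    }
    return AudioSignal(x, sample_rate=sr), truth


# ---------------------------------------------------------------- face


@dataclass
class FaceParams:
    """Per-subject facial-track generation parameters."""

    duration_s: float = 30.0
    fps: float = 30.0
    blink_rate_hz: float = 0.30  # blinks per second
    blink_depth: float = 0.92  # fraction of baseline EAR removed at the valley bottom
    blink_duration_frames: int = 12
    mouth_amp: float = 0.010  # lip-opening oscillation amplitude, image units
    mouth_freq_hz: float = 2.0
    perioral_amp: float = 0.004
    jitter_sd: float = 3e-4  # landmark detector noise
    scale_drift: float = 0.0  # relative zoom amplitude
    translation_drift: float = 0.0  # image units
    ear_window: int = 30


def _blink_profile(n_frames: int, onsets, duration: int, depth: float) -> np.ndarray:
    """Multiplicative EAR factor per frame: 1 when open, dips during blinks."""
    e = np.ones(n_frames)
    k = np.arange(duration)
    w = 0.5 * (1.0 - np.cos(2.0 * np.pi * (k + 0.5) / duration))  # raised cosine
    for o in onsets:
        hi = min(o + duration, n_frames)
        e[o:hi] *= 1.0 - depth * w[: hi - o]
    return e


def truth_blink_fractions(ear_factor: np.ndarray, window: int) -> dict[int, float]:
    """Blink fractions implied by the noiseless planted EAR profile, under the
    same trailing-mean smoothing and mean-relative thresholds the extractor
    uses."""
    sm = pd.Series(_BASE_EAR * ear_factor).rolling(window, min_periods=1).mean().to_numpy()
    mean = sm.mean()
    return {p: float((sm < (p / 100.0) * mean).mean()) for p in (30, 50, 70, 90)}


def simulate_face(params: FaceParams, seed) -> tuple[LandmarkTrack, dict]:
    """Generate one subject's landmark track and its ground truth."""
    rng = np.random.default_rng(seed)
    n = int(round(params.duration_s * params.fps))
    t = np.arange(n) / params.fps
    ids = sorted(_BASE_LAYOUT)
    col = {i: k for k, i in enumerate(ids)}
    local = np.tile(
        np.array([_BASE_LAYOUT[i] for i in ids], dtype=float), (n, 1, 1)
    )  # (n, L, 2)

    # --- blinks: squeeze eye tops/bottoms toward the eye centreline
    n_blinks = rng.poisson(params.blink_rate_hz * params.duration_s)
    margin = params.blink_duration_frames
    onsets = (
        np.sort(rng.integers(0, max(n - margin, 1), size=n_blinks)) if n_blinks else []
    )
    e = _blink_profile(n, onsets, params.blink_duration_frames, params.blink_depth)
    half_h = 0.015  # half eye height of the neutral layout
    for side_top, side_bot in ((12, 13), (22, 23)):
        cy = 0.38
        local[:, col[side_top], 1] = cy - half_h * e
        local[:, col[side_bot], 1] = cy + half_h * e

    # --- mouth oscillation (identical distribution in both groups)
    ph = rng.uniform(0.0, 2.0 * np.pi, size=4)
    osc = np.sin(2.0 * np.pi * params.mouth_freq_hz * t + ph[0])
    local[:, col[33], 1] += params.mouth_amp * (0.5 + 0.5 * osc)  # lower lip opens
    local[:, col[32], 1] -= 0.3 * params.mouth_amp * (0.5 + 0.5 * osc)
    stretch = 0.5 * params.mouth_amp * np.sin(2.0 * np.pi * 0.7 * params.mouth_freq_hz * t + ph[1])
    local[:, col[30], 0] -= stretch  # corners move apart and back
    local[:, col[31], 0] += stretch
    # slight one-sided corner lift so the mouth crossing angle moves
    local[:, col[30], 1] += 0.2 * params.mouth_amp * np.sin(
        2.0 * np.pi * 0.9 * params.mouth_freq_hz * t + ph[2]
    )

    # --- peri-oral radial oscillation around the nose
    nose = np.array(_BASE_LAYOUT[1])
    for ring in (SYNTHETIC_SCHEMA.perioral_right, SYNTHETIC_SCHEMA.perioral_left):
        for p in ring:
            u = np.array(_BASE_LAYOUT[p]) - nose
            u /= np.linalg.norm(u)
            r = params.perioral_amp * np.sin(
                2.0 * np.pi * params.mouth_freq_hz * t + rng.uniform(0, 2 * np.pi)
            )
            local[:, col[p], :] += r[:, None] * u[None, :]

    # --- global zoom/translation drift (extraction must cancel it)
    centre = np.array([0.5, 0.5])
    s = 1.0 + params.scale_drift * np.sin(2.0 * np.pi * 0.05 * t + ph[3])
    trans = params.translation_drift * np.stack(
        [np.sin(2.0 * np.pi * 0.08 * t), np.cos(2.0 * np.pi * 0.11 * t)], axis=1
    )
    coords = centre + s[:, None, None] * (local - centre) + trans[:, None, :]
    if params.jitter_sd > 0:
        coords = coords + rng.normal(0.0, params.jitter_sd, coords.shape)

    track = LandmarkTrack.from_array(coords, ids, fps=params.fps, schema=SYNTHETIC_SCHEMA)
    truth = {
        "n_blinks": int(n_blinks),
        "blink_rate_hz": params.blink_rate_hz,
        "blink_depth": params.blink_depth,
        "mouth_amp": params.mouth_amp,
        "n_frames": n,
    }
    truth.update(
        {f"blink_{p}": v for p, v in truth_blink_fractions(e, params.ear_window).items()}
    )
    return track, truth


# ---------------------------------------------------------------- cohort

# (control_mean, control_sd, pd_mean, pd_sd, low_clip, high_clip) per planted
# parameter; PD means follow the direction and approximate magnitude of the
# clinical group differences
_PARAM_DISTS: dict[str, tuple[float, float, float, float, float, float]] = {
    "duration_s": (52.3, 12.8, 62.0, 20.0, 25.0, 110.0),
    "pause_fraction": (0.134, 0.073, 0.21, 0.10, 0.02, 0.60),
    "volume_drift": (-0.016, 0.21, -0.052, 0.21, -0.8, 0.8),
    "f0_mean": (157.3, 32.0, 152.0, 33.0, 85.0, 290.0),
    "f0_jitter_sd": (16.2, 4.5, 12.9, 4.3, 1.5, 35.0),
    "blink_rate_hz": (0.30, 0.12, 0.16, 0.09, 0.02, 0.9),
    "blink_depth": (0.92, 0.04, 0.84, 0.07, 0.55, 0.98),
    "blink_duration_frames": (12.0, 2.0, 10.0, 2.0, 5.0, 20.0),
    # identical in both groups: true negatives for feature selection
    "mouth_amp": (0.010, 0.003, 0.010, 0.003, 0.002, 0.03),
    "perioral_amp": (0.004, 0.0015, 0.004, 0.0015, 0.001, 0.012),
    "age": (68.5, 9.0, 66.5, 9.4, 40.0, 92.0),
}

_MALE_PROB = {"control": 0.453, "PD": 0.52}


@dataclass
class CohortConfig:
    """Study-design knobs for the simulated cohorts."""

    n_per_group: int = 100
    n_validation_per_group: int | None = None  # default: same as n_per_group
    seed: int = 0
    fps: float = 30.0
    video_seconds: float = 30.0
    audio_seconds: float | None = None  # override the per-subject reading time
    effect_scale: float = 1.0  # 0 = exchangeable groups, 1 = planted effects
    param_dists: Mapping = field(default_factory=lambda: dict(_PARAM_DISTS))
    scale_drift: float = 0.02
    translation_drift: float = 0.01
    sample_rate: int = 44100

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for name, d in self.param_dists.items():
            if d[1] < 0 or d[3] < 0:
                raise ValueError(f"negative sd for parameter {name}")


@dataclass
class Cohort:
    """One simulated cohort: raw signals, tracks, metadata and ground truth."""

    audio: dict[str, AudioSignal]
    tracks: dict[str, LandmarkTrack]
    records: list[SubjectRecord]
    truth: pd.DataFrame


@dataclass
class SimulatedCohort:
    train: Cohort
    validation: Cohort
    config: CohortConfig


def _draw_param(rng, cfg: CohortConfig, name: str, group: str) -> float:
    cm, cs, pm, ps, lo, hi = cfg.param_dists[name]
    if group == "PD":
        mean = cm + cfg.effect_scale * (pm - cm)
        sd = ps
    else:
        mean, sd = cm, cs
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def _simulate_subject(cfg: CohortConfig, group: str, subject_id: str, phase: str | None, seed_seq):
    seeds = seed_seq.generate_state(4)
    rng = np.random.default_rng(seeds[0])
    p = {name: _draw_param(rng, cfg, name, group) for name in cfg.param_dists}
    vp = VoiceParams(
        duration_s=cfg.audio_seconds or p["duration_s"],
        f0_mean=p["f0_mean"],
        f0_jitter_sd=p["f0_jitter_sd"],
        pause_fraction=p["pause_fraction"],
        volume_drift=p["volume_drift"],
        sample_rate=cfg.sample_rate,
    )
    fp = FaceParams(
        duration_s=cfg.video_seconds,
        fps=cfg.fps,
        blink_rate_hz=p["blink_rate_hz"],
        blink_depth=p["blink_depth"],
        blink_duration_frames=int(round(p["blink_duration_frames"])),
        mouth_amp=p["mouth_amp"],
        perioral_amp=p["perioral_amp"],
        scale_drift=cfg.scale_drift,
        translation_drift=cfg.translation_drift,
    )
    signal, vtruth = simulate_voice(vp, seeds[1])
    signal.subject_id = subject_id
    track, ftruth = simulate_face(fp, seeds[2])
    track.subject_id = subject_id
    demo_rng = np.random.default_rng(seeds[3])
    male_p = _MALE_PROB["control"] + cfg.effect_scale * (
        _MALE_PROB[group] - _MALE_PROB["control"]
    )
    sex = "male" if demo_rng.random() < male_p else "female"
    stage = None
    if group == "PD":
        stage = float(demo_rng.choice([1, 2, 3], p=[0.25, 0.45, 0.30]))
    rec = SubjectRecord(
        subject_id=subject_id,
        age=p["age"],
        sex=sex,
        label=group,
        stage=stage,
        phase=phase if group == "PD" else None,
    )
    truth = {"subject_id": subject_id, "label": group, **vtruth, **ftruth}
    return signal, track, rec, truth


def _iter_subjects(cfg: CohortConfig, prefix: str, n_per_group: int, phase: str, seed_seq):
    """Yield (signal, track, record, truth) per subject with stable sub-seeds."""
    children = seed_seq.spawn(2 * n_per_group)
    k = 0
    for group, tag in (("control", "ct"), ("PD", "pd")):
        for i in range(n_per_group):
            sid = f"{prefix}_{tag}_{i:03d}"
            yield _simulate_subject(cfg, group, sid, phase, children[k])
            k += 1


def _simulate_one_cohort(cfg: CohortConfig, prefix: str, n_per_group: int, phase: str, seed_seq) -> Cohort:
    audio, tracks, records, rows = {}, {}, [], []
    for signal, track, rec, truth in _iter_subjects(cfg, prefix, n_per_group, phase, seed_seq):
        audio[rec.subject_id] = signal
        tracks[rec.subject_id] = track
        records.append(rec)
        rows.append(truth)
    truth_df = pd.DataFrame(rows).set_index("subject_id")
    return Cohort(audio=audio, tracks=tracks, records=records, truth=truth_df)


def simulate_cohort(config: CohortConfig | None = None, **overrides) -> SimulatedCohort:
    """Simulate subject-disjoint training and validation cohorts.

    The training cohort's PD subjects are tagged as medicated ("on" phase) and
    the validation cohort's as unmedicated ("off"), mirroring a
    train-on-medicated / validate-on-unmedicated design; both cohorts are drawn
    from the same group distributions with distinct sub-seeds.
    """
    cfg = replace(config, **overrides) if config is not None else CohortConfig(**overrides)
    root = np.random.SeedSequence(cfg.seed)
    train_ss, val_ss = root.spawn(2)
    n_val = cfg.n_validation_per_group or cfg.n_per_group
    train = _simulate_one_cohort(cfg, "tr", cfg.n_per_group, "on", train_ss)
    val = _simulate_one_cohort(cfg, "va", n_val, "off", val_ss)
    return SimulatedCohort(train=train, validation=val, config=cfg)


# ---------------------------------------------------------------- helpers


def simulate_feature_tables(
    config: CohortConfig | None = None,
    feature_set: str = "combined_plus_demographics",
    voice_config: VoiceConfig | None = None,
    face_config: FaceConfig | None = None,
    **overrides,
):
    """Streaming simulate -> extract: per-subject raw signals are discarded
    immediately, so large cohorts fit in memory.

    Returns ``(train_table, validation_table, train_truth, validation_truth)``
    with the same per-subject seeds as :func:`simulate_cohort`, so the two
    paths produce identical features for identical configs.
    """
    from .pipeline import build_table

    cfg = replace(config, **overrides) if config is not None else CohortConfig(**overrides)
    root = np.random.SeedSequence(cfg.seed)
    train_ss, val_ss = root.spawn(2)
    n_val = cfg.n_validation_per_group or cfg.n_per_group
    out = []
    for prefix, n, phase, ss in (("tr", cfg.n_per_group, "on", train_ss), ("va", n_val, "off", val_ss)):
        voice, face, records, rows = {}, {}, [], []
        for signal, track, rec, truth in _iter_subjects(cfg, prefix, n, phase, ss):
            voice[rec.subject_id] = extract_voice_features(signal, voice_config)
            face[rec.subject_id] = extract_facial_features(track, face_config)
            records.append(rec)
            rows.append(truth)
            del signal, track
        out.append(build_table(voice, face, records, feature_set))
        out.append(pd.DataFrame(rows).set_index("subject_id"))
    return out[0], out[2], out[1], out[3]


def extract_features(
    cohort: Cohort,
    voice_config: VoiceConfig | None = None,
    face_config: FaceConfig | None = None,
):
    """Run both extractors on every subject of a cohort."""
    voice = {sid: extract_voice_features(sig, voice_config) for sid, sig in cohort.audio.items()}
    face = {sid: extract_facial_features(tr, face_config) for sid, tr in cohort.tracks.items()}
    return voice, face


def cohort_table(cohort: Cohort, feature_set: str = "combined_plus_demographics") -> pd.DataFrame:
    """Extract features and assemble the modelling table for one cohort."""
    from .pipeline import build_table

    voice, face = extract_features(cohort)
    return build_table(voice, face, cohort.records, feature_set)
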