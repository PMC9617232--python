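"""Readers and writers for WAV audio, landmark tracks, feature tables, reports.

The feature-table CSV has a fixed column order (facial block, voice block,
optional phonetic score, demographics, label) and round-trips losslessly to
12 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .errors import FormatError, IntegrityError
from .types import AudioSignal, LandmarkSchema, LandmarkTrack

__all__ = [
    "FACIAL_COLUMNS",
    "VOICE_COLUMNS",
    "DEMOGRAPHIC_COLUMNS",
    "read_wav",
    "write_wav",
    "read_landmark_track",
    "write_landmark_track",
    "read_feature_table",
    "write_feature_table",
    "read_report",
    "write_report",
]

#: facial feature block, in fixed table order
FACIAL_COLUMNS = [
    "blink_30",
    "blink_50",
    "blink_70",
    "blink_90",
    "mouth_eye_var_right",
    "mouth_eye_var_left",
    "mouth_height_var",
    "mouth_width_var",
    "mouth_angle_var",
    "perioral_var_right",
    "perioral_var_left",
]

#: voice feature block, in fixed table order
VOICE_COLUMNS = [
    "reading_time",
    "pause_percentage",
    "volume_variance",
    "average_pitch",
    "pitch_variance",
]

DEMOGRAPHIC_COLUMNS = ["age", "sex"]

#: full canonical ordering; phonetic_score is an optional passthrough column
ALL_COLUMNS = FACIAL_COLUMNS + VOICE_COLUMNS + ["phonetic_score"] + DEMOGRAPHIC_COLUMNS + ["label"]


def read_wav(path, subject_id: str | None = None) -> AudioSignal:
    """Read a PCM WAV file as a mono :class:`AudioSignal` on the 16-bit scale.

    Stereo channels are averaged; 8-, 24- and 32-bit integer and float sources
    are rescaled so that full scale maps to +/-32767.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except (ValueError, FileNotFoundError, EOFError) as exc:
        raise FormatError(f"cannot read PCM WAV file {path}: {exc}") from exc
    x = np.asarray(data, dtype=np.float64)
    if x.ndim == 2:  # average channels to mono
        x = x.mean(axis=1)
    dt = np.asarray(data).dtype
    if dt == np.int16:
        pass
    elif dt == np.int32:  # 24-bit PCM also arrives as int32, MSB-aligned
        x = x / 65536.0
    elif dt == np.uint8:
        x = (x - 128.0) * 256.0
    elif dt.kind == "f":  # IEEE float WAV, full scale +/-1
        x = x * 32767.0
    else:
        raise FormatError(f"unsupported WAV sample format {dt} in {path}")
    x = np.clip(x, -32767.0, 32767.0)
    return AudioSignal(x, sample_rate=int(rate), subject_id=subject_id or path.stem)


def write_wav(signal: AudioSignal, path) -> None:
    """Write a signal as 16-bit PCM WAV."""
    data = np.clip(np.round(signal.samples), -32767, 32767).astype(np.int16)
    wavfile.write(str(path), int(signal.sample_rate), data)


def _track_dataframe(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            payload = json.load(fh)
        rows = payload["rows"] if isinstance(payload, dict) else payload
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path)
    required = {"frame", "landmark_id", "x", "y"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"landmark file {path} must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    return df


def read_landmark_track(path, schema: LandmarkSchema, fps: float, subject_id: str | None = None) -> LandmarkTrack:
    """Read a long-format landmark file (CSV or JSON rows: frame, landmark_id, x, y).

    The video frame rate is a required input; the recording hardware does not
    embed it in the landmark export.
    """
    df = _track_dataframe(path)
    frames = []
    for _, sub in df.sort_values("frame").groupby("frame", sort=True):
        frames.append(
            {int(r.landmark_id): (float(r.x), float(r.y)) for r in sub.itertuples()}
        )
    stem = Path(path).stem.removesuffix("_landmarks")
    return LandmarkTrack(frames, fps=fps, schema=schema, subject_id=subject_id or stem)


def write_landmark_track(track: LandmarkTrack, path) -> None:
    """Write a track in long CSV (or JSON) format; round-trips losslessly."""
    path = Path(path)
    n, m = track.coords.shape[:2]
    rec = pd.DataFrame(
        {
            "frame": np.repeat(np.arange(n), m),
            "landmark_id": np.tile(np.asarray(track.ids), n),
            "x": track.coords[:, :, 0].ravel(),
            "y": track.coords[:, :, 1].ravel(),
        }
    )
    if path.suffix.lower() == ".json":
        rec.to_json(path, orient="records", double_precision=15)
    else:
        rec.to_csv(path, index=False)  # default shortest-repr floats: lossless


def _validate_feature_table(table: pd.DataFrame) -> None:
    if table.index.name != "subject_id":
        raise IntegrityError("feature table index must be named 'subject_id'")
    if table.index.has_duplicates:
        dups = table.index[table.index.duplicated()].unique().tolist()
        raise IntegrityError(f"duplicate subject_id(s): {dups}")
    if len(table) and "label" not in table.columns:
        raise IntegrityError("feature table is missing the 'label' column")
    if len(table) and table["label"].isna().any():
        bad = table.index[table["label"].isna()].tolist()
        raise IntegrityError(f"missing label for subject(s): {bad}")
    model_cols = [c for c in table.columns if c != "phonetic_score"]
    if len(table) and table[model_cols].isna().any().any():
        bad = [c for c in model_cols if table[c].isna().any()]
        raise IntegrityError(f"missing values in modelling column(s): {bad}")


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a subjects-by-features table as CSV in the canonical column order."""
    _validate_feature_table(table)
    ordered = [c for c in ALL_COLUMNS if c in table.columns]
    ordered += [c for c in table.columns if c not in ordered]
    table[ordered].to_csv(path, float_format="%.12g")


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="subject_id")
    df.index = df.index.astype(str)
    _validate_feature_table(df)
    return df


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=False)


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
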