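"""Readers and writers for every on-disk format the pipeline touches.

Formats
-------
* R-R interval series: plain text, one interval in milliseconds per line,
  with the literal token ``NaN`` (any case) marking signal dropouts.
* EEG recordings: EDF (via :mod:`mne`, optional dependency) or CSV with a
  leading time/index column and one column per electrode.
* Session manifests: JSON mapping block indices to ``[start_s, end_s)``
  windows on the session clock (seconds from session start).
* Per-epoch feature tables: CSV with the fixed key columns
  ``participant, task, block, epoch, channel`` followed by feature columns.
* Configuration: a single flat YAML mapping; :func:`default_config` holds
  every tunable the pipeline reads.

All timing is in seconds from session start, sample indices are 0-based and
block windows are half-open ``[start_s, end_s)``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ChannelMismatchError,
    EmptyInputError,
    FormatError,
    SchemaError,
)

log = logging.getLogger("stresspipe")

#: Electrode montage of the 4-channel forehead headband (reference FpZ).
EXPECTED_CHANNELS = ("Fp1", "Fp2", "T9", "T10")


class Task(str, Enum):
    CVT = "CVT"
    MMIT = "MMIT"


class RROrigin(str, Enum):
    RAW = "raw"
    INTERPOLATED = "interpolated"
    NN = "nn"


@dataclass
class RRSeries:
    """Ordered R-R intervals in ms; ``nan`` marks a missing interval.

    ``origin`` tracks the preprocessing state: ``raw`` straight from disk,
    ``interpolated`` after gap filling, ``nn`` after ectopic-beat removal
    (normal-to-normal intervals, possibly holding fresh ``nan`` markers for
    the removed beats).
    """

    intervals_ms: np.ndarray
    origin: RROrigin = RROrigin.RAW
    source_id: str = ""

    def __post_init__(self) -> None:
        self.intervals_ms = np.asarray(self.intervals_ms, dtype=float)
        if self.intervals_ms.size == 0:
            raise EmptyInputError("R-R series must contain at least one interval")
        present = self.intervals_ms[~np.isnan(self.intervals_ms)]
        if np.any(present <= 0):
            raise ValueError("R-R intervals must be positive")

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.intervals_ms).sum())

    def cumulative_times_s(self) -> np.ndarray:
        """Time of each interval's terminating beat, in seconds.

        Missing intervals contribute the mean present interval so that the
        clock keeps advancing through dropouts.
        """
        iv = self.intervals_ms.copy()
        present = iv[~np.isnan(iv)]
        if present.size == 0:
            raise EmptyInputError("R-R series has no present intervals")
        iv[np.isnan(iv)] = present.mean()
        return np.cumsum(iv) / 1000.0


@dataclass
class EEGRecording:
    """Multi-channel EEG trace in microvolts, channel-major."""

    channels: tuple[str, ...]
    samples: np.ndarray  # shape (n_channels, n_samples)
    fs: float
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.channels = tuple(self.channels)
        if self.samples.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.samples.shape[0]} sample rows for "
                f"{len(self.channels)} channel labels"
            )
        if not self.fs > 80:
            # 40 Hz analysis ceiling must sit below Nyquist
            raise ValueError(f"sampling rate {self.fs} Hz too low (need > 80 Hz)")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        norm = {_norm_channel(c): i for i, c in enumerate(self.channels)}
        key = _norm_channel(label)
        if key not in norm:
            raise ChannelMismatchError(
                f"channel {label!r} not found; have {list(self.channels)}"
            )
        return self.samples[norm[key]]


@dataclass(frozen=True)
class BlockWindow:
    block_index: int
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError(f"block {self.block_index}: end_s must exceed start_s")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class SessionManifest:
    """Block timing for one participant-task session."""

    participant_id: str
    task: Task
    blocks: tuple[BlockWindow, ...]
    task_order: str = "CVT_first"

    def __post_init__(self) -> None:
        self.task = Task(self.task)
        self.blocks = tuple(self.blocks)
        for a, b in zip(self.blocks, self.blocks[1:]):
            if b.block_index <= a.block_index:
                raise ValueError("block indices must be strictly increasing")
            if b.start_s < a.end_s:
                raise ValueError(
                    f"blocks {a.block_index} and {b.block_index} overlap"
                )

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


@dataclass
class EpochFeatureRow:
    """One feature vector for one (block, epoch, channel) cell."""

    participant: str
    task: str
    block: int
    epoch: int
    channel: str
    features: dict[str, float] = field(default_factory=dict)


def _norm_channel(label: str) -> str:
    """Normalize electrode labels: case-fold, strip, map TP9/TP10 -> T9/T10."""
    s = label.strip().upper()
    for prefix in ("EEG ", "EEG"):
        if s.startswith(prefix) and len(s) > len(prefix):
            s = s[len(prefix):].strip()
    if s in ("TP9", "TP10"):
        s = "T" + s[2:]
    return s


# ---------------------------------------------------------------------------
# R-R text format

def read_rr_file(path: str | Path, source_id: str | None = None) -> RRSeries:
    """Parse a one-interval-per-line R-R text file (``NaN`` = dropout)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    tokens = [ln.strip() for ln in lines]
    tokens = [t for i, t in enumerate(tokens) if t or i < len(tokens) - 1]
    # trailing blank line tolerated; interior blanks are format errors
    values: list[float] = []
    for lineno, tok in enumerate(tokens, start=1):
        if tok.lower() == "nan":
            values.append(math.nan)
            continue
        try:
            values.append(float(tok))
        except ValueError:
            raise FormatError(
                f"{path.name}: unparsable R-R token {tok!r} at line {lineno}"
            ) from None
    if not values:
        raise EmptyInputError(f"{path.name}: no R-R intervals")
    return RRSeries(
        np.array(values), origin=RROrigin.RAW,
        source_id=source_id or path.stem,
    )


def write_rr_file(rr: RRSeries, path: str | Path) -> None:
    lines = [
        "NaN" if math.isnan(v) else format(v, ".6f").rstrip("0").rstrip(".")
        for v in rr.intervals_ms
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# EEG readers/writers

def read_eeg(
    path: str | Path,
    format: str | None = None,
    fs: float | None = None,
    participant_id: str = "",
) -> EEGRecording:
    """Load an EEG recording from EDF or CSV.

    CSV dialect: mandatory header, first column either time in seconds or a
    sample index, remaining columns one per electrode. ``fs`` overrides any
    rate inferred from the time column (and is required when the first
    column is a bare index).
    """
    path = Path(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "edf":
        return _read_eeg_edf(path, participant_id)
    if fmt == "csv":
        return _read_eeg_csv(path, fs, participant_id)
    raise ValueError(f"unknown EEG format {fmt!r}")


def _require_channels(found: Sequence[str]) -> dict[str, str]:
    norm_found = {_norm_channel(c): c for c in found}
    missing = [c for c in EXPECTED_CHANNELS if _norm_channel(c) not in norm_found]
    if missing:
        raise ChannelMismatchError(
            f"missing channels {missing}; found {list(found)} "
            f"(expected {list(EXPECTED_CHANNELS)})"
        )
    return {c: norm_found[_norm_channel(c)] for c in EXPECTED_CHANNELS}


def _read_eeg_csv(path: Path, fs: float | None, participant_id: str) -> EEGRecording:
    df = pd.read_csv(path)
    if df.shape[1] < 5:
        raise FormatError(
            f"{path.name}: need a time/index column plus 4 channel columns"
        )
    mapping = _require_channels(df.columns[1:])
    first = df.iloc[:, 0].to_numpy(dtype=float)
    if fs is None:
        dt = np.diff(first)
        if first.size < 2 or not np.all(dt > 0):
            raise FormatError(f"{path.name}: cannot infer fs from first column")
        step = float(np.median(dt))
        if math.isclose(step, 1.0, abs_tol=1e-9):
            raise FormatError(
                f"{path.name}: first column looks like a sample index; pass fs"
            )
        fs = 1.0 / step
    data = np.vstack([df[mapping[c]].to_numpy(dtype=float) for c in EXPECTED_CHANNELS])
    return EEGRecording(EXPECTED_CHANNELS, data, fs, participant_id)


def _read_eeg_edf(path: Path, participant_id: str) -> EEGRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the optional dependency mne") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    mapping = _require_channels(raw.ch_names)
    picks = [raw.ch_names.index(mapping[c]) for c in EXPECTED_CHANNELS]
    data_uv = raw.get_data(picks=picks) * 1e6  # mne loads volts
    return EEGRecording(EXPECTED_CHANNELS, data_uv, float(raw.info["sfreq"]),
                        participant_id)


def write_eeg_csv(rec: EEGRecording, path: str | Path) -> None:
    t = np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame({"time_s": t})
    for i, c in enumerate(rec.channels):
        df[c] = rec.samples[i]
    df.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Session manifest (JSON)

def read_manifest(path: str | Path) -> SessionManifest:
    obj = json.loads(Path(path).read_text())
    blocks = tuple(
        BlockWindow(int(b["block_index"]), float(b["start_s"]), float(b["end_s"]))
        for b in obj["blocks"]
    )
    return SessionManifest(
        participant_id=obj["participant_id"],
        task=Task(obj["task"]),
        blocks=blocks,
        task_order=obj.get("task_order", "CVT_first"),
    )


def write_manifest(manifest: SessionManifest, path: str | Path) -> None:
    obj = {
        "participant_id": manifest.participant_id,
        "task": manifest.task.value,
        "task_order": manifest.task_order,
        "blocks": [
            {"block_index": b.block_index,
             "start_s": round(b.start_s, 6),
             "end_s": round(b.end_s, 6)}
            for b in manifest.blocks
        ],
    }
    Path(path).write_text(json.dumps(obj, indent=1) + "\n")


# ---------------------------------------------------------------------------
# Feature tables

KEY_COLUMNS = ("participant", "task", "block", "epoch", "channel")


def rows_to_frame(rows: Sequence[EpochFeatureRow]) -> pd.DataFrame:
    """Convert feature rows to a wide DataFrame with the fixed key columns."""
    if not rows:
        return pd.DataFrame(columns=list(KEY_COLUMNS))
    names = tuple(rows[0].features.keys())
    for r in rows:
        if set(r.features.keys()) != set(names):
            raise SchemaError(
                f"heterogeneous feature names: {sorted(r.features)} vs "
                f"{sorted(names)}"
            )
    recs = [
        {"participant": r.participant, "task": r.task, "block": r.block,
         "epoch": r.epoch, "channel": r.channel, **r.features}
        for r in rows
    ]
    return pd.DataFrame.from_records(recs, columns=list(KEY_COLUMNS) + list(names))


def frame_to_rows(df: pd.DataFrame) -> list[EpochFeatureRow]:
    feature_cols = [c for c in df.columns if c not in KEY_COLUMNS]
    return [
        EpochFeatureRow(
            participant=str(rec["participant"]), task=str(rec["task"]),
            block=int(rec["block"]), epoch=int(rec["epoch"]),
            channel=str(rec["channel"]),
            features={c: float(rec[c]) for c in feature_cols},
        )
        for rec in df.to_dict("records")
    ]


def write_features(rows: Sequence[EpochFeatureRow] | pd.DataFrame,
                   path: str | Path) -> None:
    df = rows if isinstance(rows, pd.DataFrame) else rows_to_frame(rows)
    df.to_csv(path, index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in KEY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"feature table missing key columns {missing}")
    return df


# ---------------------------------------------------------------------------
# Configuration

def default_config() -> dict:
    """Every tunable the pipeline reads, with its default."""
    return {
        # R-R preprocessing
        "rr_low_ms": 300.0,
        "rr_high_ms": 2000.0,
        "malik_tolerance": 0.2,
        "min_block_intervals": 10,
        # EEG preprocessing
        "bandpass_lo_hz": 0.5,
        "bandpass_hi_hz": 40.0,
        "filter_order": 8,
        "epoch_window_s": 2.0,
        "epoch_step_s": None,        # None -> non-overlapping
        "flatline_window_s": 2.0,
        "flatline_sd_floor_uv": 0.1,
        "flatline_exclusion_fraction": 0.2,
        # EEG features
        "sampen_m": 2,
        "sampen_r": 0.2,             # multiples of the window SD
        "higuchi_kmax": 10,
        # Model
        "svr_C": 1.0,
        "svr_epsilon": 0.1,
        "svr_kernel": "rbf",
        "epoch_stress_threshold": 0.5,
        "hrv_feature_subset": ["sdnn", "rmssd", "pnni_50", "mean_hr"],
        "eeg_feature_set": "all",    # "all" | "absolute" | "relative"
        # Synthetic data
        "synthetic_fs": 125.0,
    }


def load_config(path: str | Path | None = None) -> dict:
    cfg = default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(user, dict):
            raise FormatError("config YAML must be a flat mapping")
        unknown = set(user) - set(cfg)
        if unknown:
            log.warning("config: ignoring unknown keys %s", sorted(unknown))
        cfg.update({k: v for k, v in user.items() if k in cfg})
    return cfg
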