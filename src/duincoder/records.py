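"""Driving-record IO, validation, splitting, normalization and windowing.

A *driving record* is one continuous journey of six-channel telemetry sampled
at a fixed frame rate (canonically 10 Hz):

======  ===================  =========
index   channel              units
======  ===================  =========
0       speed                km/h
1       steering             [-1, 1]
2       throttle             [0, 1]
3       brake                [0, 1]
4       lane_deviation       m
5       yaw_rate             rad/s
======  ===================  =========

Records are stored as single CSV files: leading ``# key=value`` comment lines
carry the metadata (record_id, participant_id, route, status, frame_rate),
followed by a header row naming the six channels and one row per frame.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

CHANNELS = ("speed", "steering", "throttle", "brake", "lane_deviation", "yaw_rate")
N_CHANNELS = len(CHANNELS)
ROUTES = ("accident", "urban", "highway")
STATUSES = ("normal", "drunk")

#: z-score constants printed in the original experimental setup; shipped as the
#: default normalization when no data-derived statistics are supplied.
DEFAULT_MEAN = (55.372, -0.004, 0.178, 0.070, -0.090, 0.003)
DEFAULT_STD = (19.734, 0.069, 0.145, 0.240, 0.470, 0.066)


class RecordFormatError(ValueError):
    """A record file is malformed (missing channel, bad metadata)."""


class RecordParseError(ValueError):
    """A record file has unparseable cell content."""


class RecordValidationError(ValueError):
    """A record violates the telemetry invariants."""


@dataclass
class DrivingRecord:
    """One journey's six-channel time series plus metadata.

    ``frames`` is a T x 6 float array in the canonical channel order.
    ``normalized`` marks z-scored data, on which the raw range invariants
    (steering in [-1,1] etc.) are suspended.
    """

    record_id: str
    participant_id: str
    route: str
    status: str
    frames: np.ndarray
    frame_rate: float = 10.0
    normalized: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.validate()

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def validate(self) -> None:
        if self.route not in ROUTES:
            raise RecordValidationError(
                f"record {self.record_id!r}: route {self.route!r} not in {ROUTES}")
        if self.status not in STATUSES:
            raise RecordValidationError(
                f"record {self.record_id!r}: status {self.status!r} not in {STATUSES}")
        if self.frame_rate <= 0:
            raise RecordValidationError(
                f"record {self.record_id!r}: frame_rate must be positive")
        f = self.frames
        if f.ndim != 2 or f.shape[1] != N_CHANNELS:
            raise RecordValidationError(
                f"record {self.record_id!r}: frames must be T x {N_CHANNELS}, "
                f"got shape {f.shape}")
        if f.shape[0] < 1:
            raise RecordValidationError(
                f"record {self.record_id!r}: needs at least one frame")
        if not np.isfinite(f).all():
            raise RecordValidationError(
                f"record {self.record_id!r}: non-finite or missing values")
        if not self.normalized:
            checks = (("steering", 1, -1.0, 1.0), ("throttle", 2, 0.0, 1.0),
                      ("brake", 3, 0.0, 1.0))
            for name, j, lo, hi in checks:
                col = f[:, j]
                if col.min() < lo or col.max() > hi:
                    raise RecordValidationError(
                        f"record {self.record_id!r}: channel {name!r} outside "
                        f"[{lo}, {hi}]")


@dataclass
class NormalizationStats:
    """Per-channel z-score mean/std in raw channel units."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(N_CHANNELS)
        self.std = np.asarray(self.std, dtype=float).reshape(N_CHANNELS)
        if not (self.std > 0).all():
            raise RecordValidationError("normalization std must be strictly positive")

    @classmethod
    def shipped_default(cls) -> "NormalizationStats":
        return cls(mean=np.array(DEFAULT_MEAN), std=np.array(DEFAULT_STD))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(
            {"mean": [float(v) for v in self.mean],
             "std": [float(v) for v in self.std]}))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NormalizationStats":
        d = yaml.safe_load(Path(path).read_text())
        return cls(mean=np.array(d["mean"], dtype=float),
                   std=np.array(d["std"], dtype=float))


@dataclass
class WindowBatch:
    """Flattened, centered sliding windows ready for the driver model.

    ``data`` is B x (N*L), each row the N x L window block flattened
    feature-major (all L frames of channel 0, then channel 1, ...).
    ``labels`` carries the source record status for evaluation only; the
    driver model never consumes it.
    """

    data: np.ndarray
    center_frames: np.ndarray
    record_ids: np.ndarray
    window_frames: int
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.window_frames % 2 == 0 or self.window_frames < 1:
            raise ValueError("window_frames must be a positive odd integer")
        if self.data.shape[1] % self.window_frames != 0:
            raise ValueError("data width is not a multiple of window_frames")

    @property
    def n_windows(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1] // self.window_frames

    def unflatten(self) -> np.ndarray:
        """Reshape rows back to (B, N, L)."""
        return self.data.reshape(self.n_windows, self.n_channels, self.window_frames)


# ---------------------------------------------------------------------------
# IO

_META_KEYS = ("record_id", "participant_id", "route", "status", "frame_rate")


def write_record(record: DrivingRecord, path: str | Path) -> None:
    """Write one record in the single-file CSV dialect."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# record_id={record.record_id}\n")
        fh.write(f"# participant_id={record.participant_id}\n")
        fh.write(f"# route={record.route}\n")
        fh.write(f"# status={record.status}\n")
        fh.write(f"# frame_rate={record.frame_rate!r}\n")
        df = pd.DataFrame(record.frames, columns=list(CHANNELS))
        df.to_csv(fh, index=False, float_format="%.9g")


def read_record(path: str | Path) -> DrivingRecord:
    """Read one record CSV, validating metadata and channels."""
    path = Path(path)
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line.lstrip("#").strip()
                if "=" in stripped:
                    k, v = stripped.split("=", 1)
                    meta[k.strip()] = v.strip()
            else:
                body_lines.append(line)
    for key in ("record_id", "route", "status"):
        if key not in meta:
            raise RecordFormatError(f"{path}: missing metadata key {key!r}")
    df = pd.read_csv(io.StringIO("".join(body_lines)))
    missing = [c for c in CHANNELS if c not in df.columns]
    if missing:
        raise RecordFormatError(f"{path}: missing channel column(s) {missing}")
    df = df[list(CHANNELS)]  # coerce canonical order
    for col in CHANNELS:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.index[values.isna() & df[col].notna()]
        if len(bad):
            raise RecordParseError(
                f"{path}: non-numeric value in channel {col!r} at data row "
                f"{int(bad[0])}")
        if values.isna().any():
            row = int(values.index[values.isna()][0])
            raise RecordParseError(f"{path}: missing value in {col!r} at row {row}")
        df[col] = values
    return DrivingRecord(
        record_id=meta["record_id"],
        participant_id=meta.get("participant_id", "unknown"),
        route=meta["route"],
        status=meta["status"],
        frame_rate=float(meta.get("frame_rate", 10.0)),
        frames=df.to_numpy(dtype=float),
    )


def read_records(path: str | Path) -> list[DrivingRecord]:
    """Read a record CSV, or every ``*.csv`` record in a directory.

    Directory reads skip a ``manifest.csv`` if present and preserve sorted
    file order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_file():
        return [read_record(path)]
    files = sorted(p for p in path.glob("*.csv") if p.name != "manifest.csv")
    if not files:
        raise RecordFormatError(f"{path}: no record CSV files found")
    return [read_record(p) for p in files]


# ---------------------------------------------------------------------------
# Splitting

def split_records(
    records: Sequence[DrivingRecord],
    ratio: tuple[float, float, float] = (7.0, 2.0, 1.0),
    seed: int = 0,
    stratify: bool = False,
) -> tuple[list[DrivingRecord], list[DrivingRecord], list[DrivingRecord]]:
    """Partition records into train/validation/test at record granularity.

    Counts follow largest-remainder rounding of the ratio proportions; records
    are ordered by id and shuffled by ``seed`` before assignment, so the split
    is a pure function of (record ids, ratio, seed). With ``stratify`` the
    rounding is applied within each (route, status) stratum.
    """
    if not records:
        raise ValueError("split_records: empty record list")
    ratio_arr = np.asarray(ratio, dtype=float)
    if ratio_arr.min() < 0 or ratio_arr.sum() <= 0:
        raise ValueError("ratio must be nonnegative with positive sum")

    def _assign(group: list[DrivingRecord], rng: np.random.Generator):
        order = rng.permutation(len(group))
        shuffled = [group[i] for i in order]
        counts = _largest_remainder(len(group), ratio_arr)
        out, start = [], 0
        for c in counts:
            out.append(shuffled[start:start + c])
            start += c
        return out

    rng = np.random.default_rng(seed)
    ordered = sorted(records, key=lambda r: r.record_id)
    if not stratify:
        parts = _assign(ordered, rng)
    else:
        parts = [[], [], []]
        keys = sorted({(r.route, r.status) for r in ordered})
        for key in keys:
            group = [r for r in ordered if (r.route, r.status) == key]
            for bucket, chunk in zip(parts, _assign(group, rng)):
                bucket.extend(chunk)
    return tuple(parts)  # type: ignore[return-value]


def _largest_remainder(n: int, ratio: np.ndarray) -> list[int]:
    props = ratio / ratio.sum()
    raw = props * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    # ties on fractional part break toward the earlier ratio entry
    frac_order = np.argsort(-(raw - counts), kind="stable")
    for i in range(remainder):
        counts[frac_order[i]] += 1
    return counts.tolist()


# ---------------------------------------------------------------------------
# Normalization

def compute_stats(
    records: Sequence[DrivingRecord],
    std_floor: float | None = None,
) -> NormalizationStats:
    """Pooled per-channel mean/std over all frames of all records.

    A zero-variance channel is an error unless ``std_floor`` is given, in
    which case its std is floored (silent inflation can hide simulator bugs,
    so the floor is opt-in).
    """
    if not records:
        raise ValueError("compute_stats: empty record list")
    pooled = np.concatenate([r.frames for r in records], axis=0)
    mean = pooled.mean(axis=0)
    std = pooled.std(axis=0)
    zero = std <= 0
    if zero.any():
        if std_floor is None:
            names = [CHANNELS[i] for i in np.flatnonzero(zero)]
            raise RecordValidationError(
                f"zero-variance channel(s) {names}; pass std_floor "
                f"(e.g. 1e-6) to floor them")
        std = np.maximum(std, std_floor)
    return NormalizationStats(mean=mean, std=std)


def normalize(record: DrivingRecord, stats: NormalizationStats) -> DrivingRecord:
    """z-score each channel: (value - mean) / std. Metadata unchanged."""
    frames = (record.frames - stats.mean) / stats.std
    return replace(record, frames=frames, normalized=True)


def denormalize(record: DrivingRecord, stats: NormalizationStats) -> DrivingRecord:
    frames = record.frames * stats.std + stats.mean
    return replace(record, frames=frames, normalized=False)


# ---------------------------------------------------------------------------
# Windowing

def window_frames_for(duration_s: float, frame_rate: float = 10.0) -> int:
    """Window length in frames for a duration: round(duration * rate) + 1.

    Inclusive endpoints: a 10 s window at 10 Hz spans 101 frames.
    """
    return int(round(duration_s * frame_rate)) + 1


def extract_windows(record: DrivingRecord, window_frames: int) -> WindowBatch:
    """One window centered on every frame, edge-padded at the boundaries.

    Row t is the N x L block around frame t, flattened feature-major; indices
    outside [0, T) replicate the first/last frame.
    """
    if window_frames < 1 or window_frames % 2 == 0:
        raise ValueError("window_frames must be a positive odd integer")
    T = record.n_frames
    half = window_frames // 2
    idx = np.arange(T)[:, None] + np.arange(-half, half + 1)[None, :]
    idx = np.clip(idx, 0, T - 1)
    windows = record.frames[idx]                      # (T, L, N)
    data = windows.transpose(0, 2, 1).reshape(T, -1)  # feature-major flatten
    return WindowBatch(
        data=data,
        center_frames=np.arange(T),
        record_ids=np.full(T, record.record_id, dtype=object),
        window_frames=window_frames,
        labels=np.full(T, record.status, dtype=object),
    )


def concat_batches(batches: Iterable[WindowBatch]) -> WindowBatch:
    batches = list(batches)
    if not batches:
        raise ValueError("no batches to concatenate")
    L = batches[0].window_frames
    if any(b.window_frames != L for b in batches):
        raise ValueError("mismatched window_frames")
    return WindowBatch(
        data=np.concatenate([b.data for b in batches], axis=0),
        center_frames=np.concatenate([b.center_frames for b in batches]),
        record_ids=np.concatenate([b.record_ids for b in batches]),
        window_frames=L,
        labels=np.concatenate([b.labels for b in batches]),
    )


def windows_from_records(
    records: Sequence[DrivingRecord],
    window_frames: int,
    stats: NormalizationStats | None = None,
) -> WindowBatch:
    """Normalize (optionally) and window a set of records into one batch."""
    batches = []
    for rec in records:
        if stats is not None and not rec.normalized:
            rec = normalize(rec, stats)
        batches.append(extract_windows(rec, window_frames))
    return concat_batches(batches)
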