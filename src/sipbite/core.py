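"""Shared domain types and CSV readers/writers.

The package works on uniformly sampled six-channel wrist inertial streams
(tri-axial accelerometer in m/s^2, tri-axial gyroscope in deg/s) plus labeled
activity intervals over the three-class vocabulary ``{eat, drink, other}``.
All intervals are half-open ``[start, end)`` in seconds since midnight, and
sample ``i`` of a stream covers ``[t0 + i/fs, t0 + (i+1)/fs)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Standard gravity used by gravity-referenced features (m/s^2).
GRAVITY = 9.80665

#: The activity vocabulary.  Rasterization precedence is drink > eat > other.
CLASSES = ("eat", "drink", "other")

STREAM_COLUMNS = ["timestamp", "ax", "ay", "az", "gx", "gy", "gz"]
LABEL_COLUMNS = ["start_s", "end_s", "label"]


class FormatError(ValueError):
    """A file does not conform to one of the documented CSV dialects."""


@dataclass
class SensorStream:
    """Uniformly sampled accelerometer + gyroscope recording.

    Attributes
    ----------
    t0 : float
        Absolute start time of day, seconds since midnight.
    fs : float
        Sample rate in Hz.
    acc : ndarray of shape (n, 3)
        Accelerometer channels (m/s^2).
    gyro : ndarray of shape (n, 3)
        Gyroscope channels (deg/s).
    """

    t0: float
    fs: float
    acc: np.ndarray
    gyro: np.ndarray

    def __post_init__(self) -> None:
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise ValueError("acc must have shape (n, 3)")
        if self.gyro.shape != self.acc.shape:
            raise ValueError("gyro must match acc shape")
        if not self.fs > 0:
            raise ValueError("fs must be > 0")
        if not (np.isfinite(self.acc).all() and np.isfinite(self.gyro).all()):
            raise ValueError("stream contains non-finite values")

    @property
    def n(self) -> int:
        return self.acc.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    def times(self) -> np.ndarray:
        """Per-sample start times (seconds since midnight)."""
        return self.t0 + np.arange(self.n) / self.fs

    def slice(self, start_idx: int, end_idx: int) -> "SensorStream":
        """Sub-stream over sample span [start_idx, end_idx)."""
        return SensorStream(
            t0=self.t0 + start_idx / self.fs,
            fs=self.fs,
            acc=self.acc[start_idx:end_idx],
            gyro=self.gyro[start_idx:end_idx],
        )


@dataclass(frozen=True)
class LabeledInterval:
    """Half-open labeled interval in seconds since midnight."""

    start_s: float
    end_s: float
    label: str

    def __post_init__(self) -> None:
        if not 0 <= self.start_s < self.end_s:
            raise ValueError(
                f"invalid interval [{self.start_s}, {self.end_s})"
            )
        if self.label not in CLASSES:
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class LabelTrack:
    """Ordered collection of labeled intervals over one stream.

    Intervals are kept sorted by start time.  Overlap is permitted only
    between a drink and an eat interval (a sip during a meal); on a shared
    instant the precedence drink > eat > other decides the class.
    """

    intervals: list[LabeledInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(
            self.intervals, key=lambda iv: (iv.start_s, iv.end_s)
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def of_label(self, label: str) -> list[LabeledInterval]:
        return [iv for iv in self.intervals if iv.label == label]


@dataclass
class Window:
    """Contiguous half-open sample span produced by a segmentation method."""

    start_idx: int
    end_idx: int
    method: str  # one of {"FW", "DW", "DFW"}
    label: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start_idx < self.end_idx:
            raise ValueError(
                f"invalid window [{self.start_idx}, {self.end_idx})"
            )
        if self.method not in ("FW", "DW", "DFW"):
            raise ValueError(f"unknown segmentation method {self.method!r}")

    def __len__(self) -> int:
        return self.end_idx - self.start_idx

    def mid_idx(self) -> float:
        return 0.5 * (self.start_idx + self.end_idx)


@dataclass
class RunConfig:
    """Flat bag of every tunable the pipeline consumes.

    Durations are seconds unless suffixed otherwise; times of day in hours.
    """

    fs_target: float = 50.0
    downsample_factor: int = 2
    lowpass_cutoff_hz: float = 5.0
    lowpass_order: int = 4
    smooth_sigma_s: float = 0.5
    fw_length_s: float = 10.0
    fw_overlap: float = 0.25
    dw_N: int = 100
    dw_scale: float = 2.0
    dw_floor: float = 0.1
    dfw_t_s: float = 10.0
    smoothing_N: int = 3
    meal_centers_h: tuple[float, ...] = (8.0, 12.5, 20.0)
    meal_sigma_h: float = 1.5
    meal_threshold: float = 0.5
    min_meal_min: int = 5
    drink_match_tol_s: float = 10.0
    drink_peak_thresh: float = 60.0
    drink_peak_sep_s: float = 0.25
    energy_win_s: float = 5.0
    energy_lookback_s: float = 120.0
    energy_k: float = 3.0
    apply_e3: bool = False
    n_trees: int = 100
    smote_k: int = 5
    enn_k: int = 3
    gravity: float = GRAVITY
    seed: int = 0

    def __post_init__(self) -> None:
        self.meal_centers_h = tuple(float(c) for c in self.meal_centers_h)
        positive = (
            "fs_target fw_length_s dfw_t_s meal_sigma_h min_meal_min "
            "drink_match_tol_s energy_win_s energy_lookback_s"
        ).split()
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.fw_overlap < 1:
            raise ValueError("fw_overlap must be in [0, 1)")

    def replace(self, **kw) -> "RunConfig":
        return replace(self, **kw)

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kw = {}
        types = {f.name: f for f in fields(cls)}
        for ln, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"config line {ln}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in types:
                raise FormatError(f"config line {ln}: unknown key {key!r}")
            if key == "meal_centers_h":
                kw[key] = tuple(float(x) for x in val.split(","))
            elif key == "apply_e3":
                kw[key] = val.lower() in ("1", "true", "yes", "on")
            elif key in ("downsample_factor", "lowpass_order", "dw_N",
                         "smoothing_N", "min_meal_min", "n_trees",
                         "smote_k", "enn_k", "seed"):
                kw[key] = int(val)
            else:
                kw[key] = float(val)
        return cls(**kw)


# ---------------------------------------------------------------------------
# CSV I/O


def read_stream_csv(path: str | Path, fs: float, t0: float = 0.0) -> SensorStream:
    """Read a sensor CSV (``timestamp,ax,ay,az,gx,gy,gz``) into a stream.

    Timestamps must be strictly increasing; any missing column or
    non-numeric cell raises :class:`FormatError` naming the offending row
    (1-based, counting data rows).
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file, expected header "
                          + ",".join(STREAM_COLUMNS))
    missing = [c for c in STREAM_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    df = df[STREAM_COLUMNS]
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.nonzero(~np.isfinite(values))[0]
    if bad.size:
        row = int(bad[0]) + 1
        raise FormatError(f"{path}: non-numeric or non-finite value at data row {row}")
    ts = values[:, 0]
    if ts.size > 1 and not np.all(np.diff(ts) > 0):
        row = int(np.nonzero(np.diff(ts) <= 0)[0][0]) + 2
        raise FormatError(f"{path}: non-monotone timestamp at data row {row}")
    return SensorStream(t0=t0, fs=fs, acc=values[:, 1:4], gyro=values[:, 4:7])


def write_stream_csv(stream: SensorStream, path: str | Path) -> None:
    """Write a stream as the sensor CSV dialect; round-trips with the reader."""
    ts = np.arange(stream.n) / stream.fs
    df = pd.DataFrame(
        np.column_stack([ts, stream.acc, stream.gyro]) if stream.n else
        np.empty((0, 7)),
        columns=STREAM_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_labels_csv(path: str | Path) -> LabelTrack:
    """Read a labels CSV (``start_s,end_s,label``) into a sorted LabelTrack."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return LabelTrack([])
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    intervals = []
    for i, row in enumerate(df.itertuples(index=False), 1):
        try:
            intervals.append(
                LabeledInterval(float(row.start_s), float(row.end_s),
                                str(row.label).strip())
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: data row {i}: {exc}") from exc
    return LabelTrack(intervals)


def write_labels_csv(track: LabelTrack, path: str | Path) -> None:
    df = pd.DataFrame(
        [(iv.start_s, iv.end_s, iv.label) for iv in track],
        columns=LABEL_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_predictions_csv(path: str | Path) -> pd.DataFrame:
    """Read a predictions CSV (``start_s,end_s,label,probability``)."""
    df = pd.read_csv(path)
    need = ["start_s", "end_s", "label", "probability"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return df[need]


def write_predictions_csv(rows, path: str | Path) -> None:
    """Write (start_s, end_s, label, probability) rows."""
    df = pd.DataFrame(
        list(rows), columns=["start_s", "end_s", "label", "probability"]
    )
    df.to_csv(path, index=False, float_format="%.17g")


def rasterize_labels(
    track: LabelTrack, t0: float, unit_s: float, n_units: int
) -> list[str]:
    """Label a uniform grid of ``n_units`` units of ``unit_s`` seconds.

    Each unit takes the label of the interval covering its midpoint; on
    overlap the precedence drink > eat > other applies, and uncovered units
    are ``other``.
    """
    if not unit_s > 0:
        raise ValueError("unit_s must be > 0")
    mids = t0 + (np.arange(n_units) + 0.5) * unit_s
    out = np.full(n_units, "other", dtype=object)
    # precedence: apply eat first so drink overwrites on overlap
    for label in ("eat", "drink"):
        for iv in track.of_label(label):
            sel = (mids >= iv.start_s) & (mids < iv.end_s)
            out[sel] = label
    return list(out)
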