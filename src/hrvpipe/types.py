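"""Core data containers shared across the pipeline.

Units: time in milliseconds everywhere, sampling rates in Hz, heart rate in
BPM, spectral power in ms². Sample indices are 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Iterator, Sequence

import numpy as np

EPOCH_LABELS = ("stimulation", "washout", "baseline")
CHANNEL_ROLES = ("ear_left", "ear_right", "chest_I")

#: Table-style display names for the 16 summary metrics, in report order.
METRIC_NAMES = {
    "mean_rr": "Mean RR",
    "mean_hr": "Mean HR",
    "sdnn": "SDNN",
    "rmssd": "RMSSD",
    "pnnx": "PNN5",
    "lf": "LF",
    "hf": "HF",
    "total_power": "Total Power",
    "lf_hf": "LF/HF",
    "sd1": "SD1",
    "sd2": "SD2",
    "sd1_sd2": "SD1/SD2",
    "sampen": "Sample Entropy",
    "dfa_a1": "DFA α1",
    "dfa_a2": "DFA α2",
    "dfa_ratio": "DFA α Ratio",
}
METRIC_FIELDS = tuple(METRIC_NAMES)


class FormatError(ValueError):
    """Malformed on-disk artifact (readers reject rather than coerce)."""


@dataclass
class ECGRecord:
    """Multi-channel, uniformly sampled voltage series.

    ``data`` is ``(n_channels, n_samples)``; ``channel_labels`` gives the role
    of each row (``ear_left``, ``ear_right``, ``chest_I``).
    """

    sample_rate_hz: float
    channel_labels: tuple[str, ...]
    data: np.ndarray
    t0_ms: float = 0.0
    normalized: bool = False

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)
        self.data = np.asarray(self.data, dtype=float)
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_channels, n_samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel row required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples * 1000.0 / self.sample_rate_hz

    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.n_samples) * 1000.0 / self.sample_rate_hz

    def channel(self, label: str) -> np.ndarray:
        try:
            i = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not in record (have {self.channel_labels})"
            ) from None
        return self.data[i]


@dataclass(frozen=True)
class Epoch:
    label: str
    start_ms: float
    end_ms: float
    trial: int

    def __post_init__(self) -> None:
        if self.label not in EPOCH_LABELS:
            raise FormatError(
                f"unknown epoch label {self.label!r}; allowed: {EPOCH_LABELS}"
            )
        if not self.start_ms < self.end_ms:
            raise FormatError(
                f"epoch start must precede end ({self.start_ms} >= {self.end_ms})"
            )
        if self.trial < 1:
            raise FormatError("trial index must be >= 1")

    def contains(self, t_ms: float) -> bool:
        # half-open [start, end) so boundary beats are never double-counted
        return self.start_ms <= t_ms < self.end_ms


@dataclass
class EpochSchedule:
    """Ordered, non-overlapping stimulation/washout/baseline intervals."""

    epochs: list[Epoch]

    def __post_init__(self) -> None:
        self.epochs = sorted(self.epochs, key=lambda e: e.start_ms)
        for a, b in zip(self.epochs, self.epochs[1:]):
            if b.start_ms < a.end_ms:
                raise FormatError(f"overlapping epochs: {a} and {b}")

    def __iter__(self) -> Iterator[Epoch]:
        return iter(self.epochs)

    def __len__(self) -> int:
        return len(self.epochs)

    @property
    def end_ms(self) -> float:
        return max((e.end_ms for e in self.epochs), default=0.0)

    def label_at(self, t_ms: float, default: str = "baseline") -> str:
        for e in self.epochs:
            if e.contains(t_ms):
                return e.label
        return default


@dataclass
class BeatAnnotation:
    """Per-channel R-peak locations (indices and times)."""

    channel: str
    peak_indices: np.ndarray
    peak_times_ms: np.ndarray

    def __post_init__(self) -> None:
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        self.peak_times_ms = np.asarray(self.peak_times_ms, dtype=float)
        if self.peak_indices.shape != self.peak_times_ms.shape:
            raise ValueError("indices and times must align")
        if len(self.peak_times_ms) > 1 and not np.all(
            np.diff(self.peak_times_ms) > 0
        ):
            raise ValueError("peak times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.peak_times_ms)


@dataclass
class RRSeries:
    """Beat times with NN intervals and per-interval validity flags.

    Invalid intervals are retained (flagged, never deleted) so the time axis
    stays intact for spectral analysis.
    """

    beat_times_ms: np.ndarray
    rr_ms: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times_ms = np.asarray(self.beat_times_ms, dtype=float)
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if len(self.beat_times_ms) != len(self.rr_ms) + 1 and len(self.rr_ms) > 0:
            raise ValueError("need n+1 beat times for n intervals")
        if self.rr_ms.shape != self.valid.shape:
            raise ValueError("one validity flag per interval required")
        if np.any(self.rr_ms <= 0):
            raise ValueError("RR intervals must be positive")

    @classmethod
    def from_times(cls, beat_times_ms: Sequence[float]) -> "RRSeries":
        t = np.asarray(beat_times_ms, dtype=float)
        rr = np.diff(t)
        return cls(t, rr, np.ones(len(rr), dtype=bool))

    def __len__(self) -> int:
        return len(self.rr_ms)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    @property
    def usable(self) -> bool:
        return self.n_valid >= 1

    def valid_nn(self) -> np.ndarray:
        return self.rr_ms[self.valid]

    def valid_pair_diffs(self) -> np.ndarray:
        """Successive differences over pairs of adjacent *valid* intervals."""
        if len(self.rr_ms) < 2:
            return np.empty(0)
        ok = self.valid[:-1] & self.valid[1:]
        return (self.rr_ms[1:] - self.rr_ms[:-1])[ok]


@dataclass(frozen=True)
class ChannelQuality:
    """Windowed beat-coverage gate for one channel."""

    channel: str
    start_ms: float
    end_ms: float
    coverage: float
    usable: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must lie in [0, 1]")


@dataclass
class HRVSummary:
    """The full metric battery for one epoch and one modality.

    Undefined metrics are carried as NaN, never imputed to 0.
    """

    mean_rr: float = math.nan
    mean_hr: float = math.nan
    sdnn: float = math.nan
    rmssd: float = math.nan
    pnnx: float = math.nan
    lf: float = math.nan
    hf: float = math.nan
    total_power: float = math.nan
    lf_hf: float = math.nan
    sd1: float = math.nan
    sd2: float = math.nan
    sd1_sd2: float = math.nan
    sampen: float = math.nan
    dfa_a1: float = math.nan
    dfa_a2: float = math.nan
    dfa_ratio: float = math.nan
    n_beats: int = 0
    epoch_label: str = ""
    modality: str = ""
    trial: int = 0

    def metric(self, name: str) -> float:
        if name not in METRIC_NAMES:
            raise KeyError(f"unknown metric {name!r}")
        return getattr(self, name)

    def metrics(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in METRIC_FIELDS}


def power_label(d: float) -> str:
    """Effect-size label: large for |d| > 0.8, medium for 0.5 < |d| <= 0.8."""
    if math.isnan(d):
        return "undefined"
    if abs(d) > 0.8:
        return "large"
    if abs(d) > 0.5:
        return "medium"
    return "small"


@dataclass
class ComparisonResult:
    """One statistical-comparison row (sequential S−W or modality agreement)."""

    metric: str
    kind: str  # "sequential" | "modality_agreement"
    mean_delta: float
    cohens_d: float
    p_value: float
    n_pairs: int
    power_label: str = field(default="")
    modality: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("sequential", "modality_agreement"):
            raise ValueError(f"unknown comparison kind {self.kind!r}")
        if not math.isnan(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if not self.power_label:
            self.power_label = power_label(self.cohens_d)

    @property
    def significant(self) -> bool:
        return (not math.isnan(self.p_value)) and self.p_value < 0.05
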