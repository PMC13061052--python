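"""Readers and writers for the on-disk artifacts.

Everything is plain CSV: comma-separated, ``.`` decimal, UTF-8, header
mandatory. Times are milliseconds on disk; sample indices 0-based. Readers
validate and reject malformed input rather than coercing it silently.
Floats are written with 10 significant digits so write→read round trips are
exact to well past the 6 significant digits guaranteed.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .types import (
    EPOCH_LABELS,
    BeatAnnotation,
    ComparisonResult,
    ECGRecord,
    Epoch,
    EpochSchedule,
    FormatError,
    HRVSummary,
    RRSeries,
)
from .simulate import GroundTruth

_FLOAT_FMT = "%.10g"


# -- multi-channel records ---------------------------------------------------

def write_record(record: ECGRecord, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"time_ms": record.times_ms()})
    for label in record.channel_labels:
        df[label] = record.channel(label)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_record(path: str | Path, expected_rate_hz: float | None = None) -> ECGRecord:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or unparseable CSV ({exc})") from exc
    if df.columns.empty or df.columns[0] != "time_ms":
        raise FormatError(f"{path}: first header column must be 'time_ms'")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: no channel columns present")
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax()) + 2  # 1-based + header line
        raise FormatError(f"{path}: missing value at line {row}")
    t = df["time_ms"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        line = int(np.argmax(dt <= 0)) + 3
        raise FormatError(f"{path}: time not strictly increasing at line {line}")
    period = float(np.median(dt))
    dev = np.abs(dt - period)
    # deviations are judged against half the smallest plausible sample period
    if np.max(dev) >= 0.5 * float(np.min(dt)):
        line = int(np.argmax(dev)) + 3
        raise FormatError(f"{path}: non-uniform sampling at line {line}")
    rate = expected_rate_hz if expected_rate_hz is not None else 1000.0 / period
    if expected_rate_hz is not None and abs(1000.0 / period - expected_rate_hz) > 0.01 * expected_rate_hz:
        raise FormatError(
            f"{path}: sampling rate {1000.0 / period:g} Hz contradicts "
            f"expected {expected_rate_hz:g} Hz"
        )
    labels = tuple(df.columns[1:])
    data = df[list(labels)].to_numpy(dtype=float).T
    return ECGRecord(rate, labels, data, t0_ms=float(t[0]))


# -- epoch schedules ---------------------------------------------------------

def write_schedule(schedule: EpochSchedule, path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {"label": e.label, "start_ms": e.start_ms, "end_ms": e.end_ms, "trial": e.trial}
        for e in schedule
    ]
    pd.DataFrame(rows, columns=["label", "start_ms", "end_ms", "trial"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )
    return path


def read_schedule(path: str | Path) -> EpochSchedule:
    path = Path(path)
    df = pd.read_csv(path)
    required = ["label", "start_ms", "end_ms", "trial"]
    if list(df.columns) != required:
        raise FormatError(f"{path}: header must be {','.join(required)}")
    epochs = []
    for i, row in df.iterrows():
        label = str(row["label"])
        if label not in EPOCH_LABELS:
            raise FormatError(
                f"{path}: unknown label {label!r} at line {i + 2}; "
                f"allowed: {', '.join(EPOCH_LABELS)}"
            )
        try:
            epochs.append(
                Epoch(label, float(row["start_ms"]), float(row["end_ms"]), int(row["trial"]))
            )
        except (FormatError, ValueError) as exc:
            raise FormatError(f"{path}: bad epoch at line {i + 2}: {exc}") from exc
    return EpochSchedule(epochs)  # overlap check happens in the constructor


# -- beat annotations --------------------------------------------------------

def write_annotations(
    ann: BeatAnnotation | Iterable[BeatAnnotation], path: str | Path
) -> Path:
    path = Path(path)
    anns = [ann] if isinstance(ann, BeatAnnotation) else list(ann)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["channel", "sample_index", "time_ms"])
        for a in anns:
            for idx, t in zip(a.peak_indices, a.peak_times_ms):
                w.writerow([a.channel, int(idx), _FLOAT_FMT % t])
    return path


def read_annotations(path: str | Path) -> dict[str, BeatAnnotation]:
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != ["channel", "sample_index", "time_ms"]:
        raise FormatError(f"{path}: header must be channel,sample_index,time_ms")
    out: dict[str, BeatAnnotation] = {}
    for ch, sub in df.groupby("channel", sort=False):
        out[str(ch)] = BeatAnnotation(
            str(ch),
            sub["sample_index"].to_numpy(dtype=int),
            sub["time_ms"].to_numpy(dtype=float),
        )
    return out


# -- RR series ---------------------------------------------------------------

def write_rr(rr: RRSeries, path: str | Path) -> Path:
    """One row per beat; the interval and flag attach to the interval that
    *starts* at the row's beat (last beat has empty interval columns)."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["beat_time_ms", "rr_ms", "valid"])
        for i, t in enumerate(rr.beat_times_ms):
            if i < len(rr.rr_ms):
                w.writerow([_FLOAT_FMT % t, _FLOAT_FMT % rr.rr_ms[i], int(rr.valid[i])])
            else:
                w.writerow([_FLOAT_FMT % t, "", ""])
    return path


def read_rr(path: str | Path) -> RRSeries:
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != ["beat_time_ms", "rr_ms", "valid"]:
        raise FormatError(f"{path}: header must be beat_time_ms,rr_ms,valid")
    t = df["beat_time_ms"].to_numpy(dtype=float)
    rr = df["rr_ms"].to_numpy(dtype=float)[:-1] if len(df) > 1 else np.empty(0)
    valid = df["valid"].to_numpy(dtype=float)[:-1] if len(df) > 1 else np.empty(0)
    if np.any(np.isnan(rr)) or np.any(np.isnan(valid)):
        raise FormatError(f"{path}: interior rows must carry rr_ms and valid")
    return RRSeries(t, rr, valid.astype(bool))


# -- ground truth ------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["beat_time_ms", "rr_ms", "epoch_label"])
        for i, t in enumerate(truth.beat_times_ms):
            rr = _FLOAT_FMT % truth.rr_ms[i] if i < len(truth.rr_ms) else ""
            w.writerow([_FLOAT_FMT % t, rr, truth.epoch_labels[i]])
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != ["beat_time_ms", "rr_ms", "epoch_label"]:
        raise FormatError(f"{path}: header must be beat_time_ms,rr_ms,epoch_label")
    t = df["beat_time_ms"].to_numpy(dtype=float)
    rr = df["rr_ms"].to_numpy(dtype=float)
    return GroundTruth(t, rr[:-1] if len(rr) > 1 else np.empty(0),
                       df["epoch_label"].astype(str).to_numpy(dtype=object))


# -- summaries and comparisons ----------------------------------------------

def write_summaries(summaries: Iterable[HRVSummary], path: str | Path) -> Path:
    """Long-format CSV keyed by (modality, epoch_label, trial, metric)."""
    path = Path(path)
    rows = []
    for s in summaries:
        for name, value in s.metrics().items():
            rows.append(
                {
                    "modality": s.modality,
                    "epoch_label": s.epoch_label,
                    "trial": s.trial,
                    "metric": name,
                    "value": value,
                    "n_beats": s.n_beats,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_summaries(path: str | Path) -> list[HRVSummary]:
    df = pd.read_csv(path)
    out = []
    keys = ["modality", "epoch_label", "trial"]
    for (modality, epoch_label, trial), sub in df.groupby(keys, sort=False):
        s = HRVSummary(
            epoch_label=str(epoch_label),
            modality=str(modality),
            trial=int(trial),
            n_beats=int(sub["n_beats"].iloc[0]),
        )
        for _, row in sub.iterrows():
            setattr(s, str(row["metric"]), float(row["value"]))
        out.append(s)
    return out


def write_comparisons(results: Iterable[ComparisonResult], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "metric": r.metric,
            "kind": r.kind,
            "modality": r.modality,
            "mean_delta": r.mean_delta,
            "cohens_d": r.cohens_d,
            "p_value": r.p_value,
            "n_pairs": r.n_pairs,
            "power_label": r.power_label,
            "significant": r.significant,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


# -- config ------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return cfg
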