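"""End-to-end study orchestration: simulate → detect → fuse → hrv → report.

The "ear" modality is the fusion of the two in-ear channels (with windowed
single-channel fallback when one sensor degrades); the "chest" modality is
the single lead-I channel, screened directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from . import detect, fuse, io, simulate, stats_report
from .types import (
    BeatAnnotation,
    ChannelQuality,
    ComparisonResult,
    ECGRecord,
    EpochSchedule,
    HRVSummary,
    RRSeries,
)

__all__ = ["StudyResult", "analyze_record", "run_study"]

EAR_CHANNELS = ("ear_left", "ear_right")
CHEST_CHANNEL = "chest_I"


@dataclass
class StudyResult:
    record: ECGRecord
    schedule: EpochSchedule
    annotations: dict[str, BeatAnnotation]
    quality: dict[str, list[ChannelQuality]]
    rr_by_modality: dict[str, RRSeries]
    summaries: list[HRVSummary]
    sequential: dict[str, list[ComparisonResult]] = field(default_factory=dict)
    agreement: list[ComparisonResult] = field(default_factory=list)
    truth: "simulate.GroundTruth | None" = None


def analyze_record(
    record: ECGRecord,
    schedule: EpochSchedule,
    band: tuple[float, float] = detect.DEFAULT_BAND,
    hr_range: tuple[float, float] = detect.DEFAULT_HR_RANGE,
    tol_ms: float = fuse.DEFAULT_TOL_MS,
    window_ms: float = fuse.DEFAULT_WINDOW_MS,
    modalities: tuple[str, ...] = ("chest", "ear"),
) -> StudyResult:
    """Run detection, fusion, per-epoch summaries and both statistics."""
    pre = detect.preprocess(record, band)
    duration = record.duration_ms

    annotations: dict[str, BeatAnnotation] = {}
    quality: dict[str, list[ChannelQuality]] = {}
    for ch in record.channel_labels:
        ann = detect.detect_r_peaks(pre, ch, hr_range)
        annotations[ch] = ann
        quality[ch] = fuse.channel_quality(ann, duration, hr_range, window_ms)

    rr_by_modality: dict[str, RRSeries] = {}
    if "ear" in modalities:
        ears = {ch: annotations[ch] for ch in EAR_CHANNELS if ch in annotations}
        rr_by_modality["ear"] = fuse.aggregate_beats(
            ears, {ch: quality[ch] for ch in ears}, tol_ms
        )
    if "chest" in modalities and CHEST_CHANNEL in annotations:
        rr = detect.extract_rr(annotations[CHEST_CHANNEL])
        rr_by_modality["chest"] = detect.reject_artifacts(rr)

    summaries: list[HRVSummary] = []
    for mod, rr in rr_by_modality.items():
        summaries.extend(stats_report.summarize_epochs(rr, schedule, mod))

    sequential = {
        mod: stats_report.sequential_analysis(
            [s for s in summaries if s.modality == mod]
        )
        for mod in rr_by_modality
    }
    agreement: list[ComparisonResult] = []
    if {"chest", "ear"} <= set(rr_by_modality):
        agreement = stats_report.modality_agreement(
            [s for s in summaries if s.modality == "chest"],
            [s for s in summaries if s.modality == "ear"],
        )
    return StudyResult(
        record, schedule, annotations, quality, rr_by_modality, summaries,
        sequential, agreement,
    )


def run_study(
    config: simulate.SimulationConfig,
    out_dir: str | Path | None = None,
    **analysis_kwargs,
) -> StudyResult:
    """Simulate a study, analyze it, and (optionally) write all artifacts."""
    record, schedule, truth = simulate.generate_study(config)
    result = analyze_record(record, schedule, **analysis_kwargs)
    result.truth = truth
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        io.write_record(record, out_dir / "record.csv")
        io.write_schedule(schedule, out_dir / "schedule.csv")
        io.write_ground_truth(truth, out_dir / "ground_truth.csv")
        io.write_annotations(result.annotations.values(), out_dir / "peaks.csv")
        for mod, rr in result.rr_by_modality.items():
            io.write_rr(rr, out_dir / f"rr_{mod}.csv")
        io.write_summaries(result.summaries, out_dir / "summaries.csv")
        comparisons = result.agreement + [
            r for res in result.sequential.values() for r in res
        ]
        io.write_comparisons(comparisons, out_dir / "comparisons.csv")
        stats_report.build_report(
            out_dir / "report", result.record, result.schedule,
            result.rr_by_modality, result.summaries, result.agreement,
            result.sequential,
        )
    return result
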