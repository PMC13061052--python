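"""Epoch segmentation, the two study statistics, and report generation.

Two comparisons are run per metric:

* sequential — paired t-test and Cohen's d (the paired d_z form,
  mean(diff)/SD(diff)) on stimulation-minus-subsequent-washout differences,
  paired within trial; the sign convention is S − W, so a positive injected
  RR shift during stimulation yields a positive Mean RR delta.
* modality agreement — Welch (unequal-variance) independent t-test of chest
  vs ear per-epoch values pooled across all trials.

Tests are two-sided; no multiple-testing correction is applied by default
(each metric is reported on its own), but a Bonferroni flag is exposed.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sci_stats

from . import hrv
from .types import (
    METRIC_FIELDS,
    METRIC_NAMES,
    ComparisonResult,
    ECGRecord,
    Epoch,
    EpochSchedule,
    HRVSummary,
    RRSeries,
)

logger = logging.getLogger(__name__)

__all__ = [
    "segment_epochs",
    "summarize_epochs",
    "paired_comparison",
    "sequential_analysis",
    "modality_agreement",
    "build_report",
]


def segment_epochs(
    rr: RRSeries, schedule: EpochSchedule
) -> list[tuple[Epoch, RRSeries]]:
    """Split an RR series by epoch.

    An interval belongs to an epoch iff *both* of its bounding beats lie in
    the half-open [start, end); boundary-spanning intervals belong to no
    epoch. Epochs with fewer than 2 beats yield empty series (logged).
    """
    out = []
    t = rr.beat_times_ms
    for epoch in schedule:
        mask = (t >= epoch.start_ms) & (t < epoch.end_ms)
        idx = np.flatnonzero(mask)
        if idx.size < 2:
            logger.warning("epoch %s trial %d has <2 beats", epoch.label, epoch.trial)
            out.append((epoch, RRSeries(t[idx], np.empty(0), np.empty(0, dtype=bool))))
            continue
        # beats in a window form a contiguous run, so intervals map directly
        lo, hi = idx[0], idx[-1]
        sub = RRSeries(t[lo : hi + 1], rr.rr_ms[lo:hi], rr.valid[lo:hi])
        out.append((epoch, sub))
    return out


def summarize_epochs(
    rr: RRSeries, schedule: EpochSchedule, modality: str, **hrv_kwargs
) -> list[HRVSummary]:
    """Per-epoch metric summaries for one modality (unusable epochs skipped)."""
    out = []
    for epoch, sub in segment_epochs(rr, schedule):
        if not sub.usable:
            continue
        out.append(
            hrv.compute_summary(
                sub, epoch_label=epoch.label, modality=modality,
                trial=epoch.trial, **hrv_kwargs,
            )
        )
    return out


def paired_comparison(
    stim_values: Sequence[float],
    washout_values: Sequence[float],
    metric: str = "",
    modality: str = "",
) -> ComparisonResult:
    """Paired S−W comparison: mean delta, Cohen's d_z, two-sided paired t."""
    s = np.asarray(stim_values, dtype=float)
    w = np.asarray(washout_values, dtype=float)
    if s.shape != w.shape:
        raise ValueError("stimulation and washout values must pair one-to-one")
    ok = np.isfinite(s) & np.isfinite(w)
    d = s[ok] - w[ok]
    n = d.size
    if n < 2:
        return ComparisonResult(metric, "sequential", math.nan, math.nan, math.nan, n,
                                modality=modality)
    mean_delta = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        # zero spread: effect size and t undefined, reported as such
        return ComparisonResult(metric, "sequential", mean_delta, math.nan, math.nan,
                                n, modality=modality)
    cohens_d = abs(mean_delta) / sd
    t_res = sci_stats.ttest_1samp(d, 0.0)
    return ComparisonResult(
        metric, "sequential", mean_delta, cohens_d, float(t_res.pvalue), n,
        modality=modality,
    )


def _pair_by_trial(
    summaries: Iterable[HRVSummary],
) -> list[tuple[HRVSummary, HRVSummary]]:
    stim = {s.trial: s for s in summaries if s.epoch_label == "stimulation"}
    wash = {s.trial: s for s in summaries if s.epoch_label == "washout"}
    return [(stim[t], wash[t]) for t in sorted(stim) if t in wash]


def sequential_analysis(
    summaries: Iterable[HRVSummary],
    metrics: Sequence[str] = METRIC_FIELDS,
) -> list[ComparisonResult]:
    """S−W comparison per metric over one modality's epoch summaries.

    Each stimulation epoch is paired with the subsequent washout of the same
    trial; at least two complete pairs are required per metric.
    """
    summaries = list(summaries)
    modalities = {s.modality for s in summaries}
    if len(modalities) > 1:
        raise ValueError("sequential_analysis expects a single modality")
    modality = modalities.pop() if modalities else ""
    pairs = _pair_by_trial(summaries)
    out = []
    for metric in metrics:
        s_vals = [p[0].metric(metric) for p in pairs]
        w_vals = [p[1].metric(metric) for p in pairs]
        out.append(paired_comparison(s_vals, w_vals, metric=metric, modality=modality))
    return out


def modality_agreement(
    summaries_chest: Iterable[HRVSummary],
    summaries_ear: Iterable[HRVSummary],
    metrics: Sequence[str] = METRIC_FIELDS,
) -> list[ComparisonResult]:
    """Welch independent t-test of chest vs ear per-epoch metric values.

    Symmetric in its arguments up to the sign of the mean delta; metrics with
    fewer than two defined values in either modality are skipped (logged).
    """
    chest = list(summaries_chest)
    ear = list(summaries_ear)
    out = []
    for metric in metrics:
        a = np.array([s.metric(metric) for s in chest], dtype=float)
        b = np.array([s.metric(metric) for s in ear], dtype=float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if len(a) < 2 or len(b) < 2:
            logger.warning("metric %s: <2 defined values in a modality; skipped", metric)
            continue
        mean_delta = float(a.mean() - b.mean())
        pooled = math.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
        cohens_d = abs(mean_delta) / pooled if pooled > 0 else math.nan
        if np.array_equal(np.sort(a), np.sort(b)):
            p = 1.0  # identical samples: no evidence of any difference
        else:
            p = float(sci_stats.ttest_ind(a, b, equal_var=False).pvalue)
        out.append(
            ComparisonResult(metric, "modality_agreement", mean_delta, cohens_d, p,
                             min(len(a), len(b)))
        )
    return out


# -- report ------------------------------------------------------------------

def _metric_table(summaries: list[HRVSummary]) -> pd.DataFrame:
    """Table-1-style layout: metric rows × modality columns (mean over epochs)."""
    rows = []
    for s in summaries:
        for name, value in s.metrics().items():
            rows.append({"metric": name, "modality": s.modality, "value": value})
    df = pd.DataFrame(rows)
    wide = df.pivot_table(index="metric", columns="modality", values="value",
                          aggfunc="mean")
    wide = wide.reindex(list(METRIC_FIELDS))
    wide.index = [METRIC_NAMES[m] for m in wide.index]
    wide.index.name = "Metric"
    return wide


def _comparison_table(
    agreement: list[ComparisonResult],
    sequential: dict[str, list[ComparisonResult]],
) -> pd.DataFrame:
    """Table-2-style layout with significance (*) and power (**) markers."""
    agree = {r.metric: r for r in agreement}
    seq = {mod: {r.metric: r for r in results} for mod, results in sequential.items()}
    rows = []
    for metric in METRIC_FIELDS:
        row: dict[str, object] = {"Metric": METRIC_NAMES[metric]}
        ra = agree.get(metric)
        row["Modality Agreement p"] = ra.p_value if ra else math.nan
        for mod, res in seq.items():
            r = res.get(metric)
            if r is None:
                continue
            row[f"Sequential Effect ({mod}, S-W)"] = r.mean_delta
            row[f"Cohen's d ({mod})"] = r.cohens_d
            row[f"Sequential p ({mod})"] = r.p_value
            row[f"significant ({mod})"] = "*" if r.significant else ""
            row[f"powerful ({mod})"] = (
                "**" if (not math.isnan(r.cohens_d) and abs(r.cohens_d) > 0.5) else ""
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _save_fig(fig, out_dir: Path, stem: str) -> list[Path]:
    paths = []
    for ext in ("png", "svg"):
        p = out_dir / f"{stem}.{ext}"
        fig.savefig(p, dpi=100)
        paths.append(p)
    return paths


def build_report(
    out_dir: str | Path,
    record: ECGRecord,
    schedule: EpochSchedule,
    rr_by_modality: dict[str, RRSeries],
    summaries: list[HRVSummary],
    agreement: list[ComparisonResult],
    sequential: dict[str, list[ComparisonResult]],
) -> dict[str, Path]:
    """Emit the metric table, comparison table, and the five figures
    (ECG snippet, tachogram, Poincaré, PSD, normalized-HR violins).

    Missing metrics render as blank cells, never zeros. Returns the paths of
    everything written.
    """
    from matplotlib.figure import Figure

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    table1 = _metric_table(summaries)
    paths["metric_table"] = out_dir / "metric_table.csv"
    table1.to_csv(paths["metric_table"], float_format="%.10g")

    table2 = _comparison_table(agreement, sequential)
    paths["comparison_table"] = out_dir / "comparison_table.csv"
    table2.to_csv(paths["comparison_table"], index=False, float_format="%.10g")

    # 5-second dual-trace snippet of the (normalized) record
    fig = Figure(figsize=(10, 4))
    ax = fig.subplots()
    n5 = min(record.n_samples, int(5 * record.sample_rate_hz))
    t = record.times_ms()[:n5] / 1000.0
    for label in record.channel_labels:
        ax.plot(t, record.channel(label)[:n5], lw=0.6, label=label)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("amplitude (a.u.)")
    ax.legend(loc="upper right", fontsize=8)
    ax.set_title("ECG snippet (first 5 s)")
    paths["snippet"] = _save_fig(fig, out_dir, "ecg_snippet")[0]

    # full-session tachogram with epoch shading
    fig = Figure(figsize=(10, 4))
    ax = fig.subplots()
    shade = {"stimulation": "#fdd", "washout": "#ddf"}
    for e in schedule:
        ax.axvspan(e.start_ms / 1000.0, e.end_ms / 1000.0,
                   color=shade.get(e.label, "#eee"), alpha=0.5, lw=0)
    for mod, rr in rr_by_modality.items():
        ax.plot(rr.beat_times_ms[1:] / 1000.0, rr.rr_ms, lw=0.7, label=mod)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("RR (ms)")
    ax.legend(loc="upper right", fontsize=8)
    ax.set_title("Tachogram with stimulation/washout epochs")
    paths["tachogram"] = _save_fig(fig, out_dir, "tachogram")[0]

    # per-condition Poincaré scatter with SD1/SD2 ellipse
    fig = Figure(figsize=(9, 4.2))
    axes = fig.subplots(1, 2)
    mods = list(rr_by_modality)
    for ax, condition in zip(axes, ("stimulation", "washout")):
        for mod in mods:
            segs = segment_epochs(rr_by_modality[mod], schedule)
            nn = np.concatenate(
                [s.valid_nn() for e, s in segs if e.label == condition and s.usable]
                or [np.empty(0)]
            )
            if nn.size < 3:
                continue
            ax.scatter(nn[:-1], nn[1:], s=4, alpha=0.4, label=mod)
            pooled = RRSeries.from_times(np.concatenate([[0.0], np.cumsum(nn)]))
            sd1, sd2, _ = hrv.poincare(pooled)
            c = float(nn.mean())
            theta = np.linspace(0, 2 * math.pi, 100)
            ex = c + sd2 * np.cos(theta) * math.cos(math.pi / 4) - sd1 * np.sin(theta) * math.sin(math.pi / 4)
            ey = c + sd2 * np.cos(theta) * math.sin(math.pi / 4) + sd1 * np.sin(theta) * math.cos(math.pi / 4)
            ax.plot(ex, ey, lw=1.2)
        ax.set_title(condition)
        ax.set_xlabel("RR$_i$ (ms)")
        ax.set_ylabel("RR$_{i+1}$ (ms)")
        ax.legend(fontsize=7)
    paths["poincare"] = _save_fig(fig, out_dir, "poincare")[0]

    # per-condition PSD with band shading
    fig = Figure(figsize=(9, 4.2))
    axes = fig.subplots(1, 2)
    from scipy import interpolate as sci_interp, signal as sps

    for ax, condition in zip(axes, ("stimulation", "washout")):
        ax.axvspan(*hrv.DEFAULT_LF_BAND, color="#fee", lw=0)
        ax.axvspan(*hrv.DEFAULT_HF_BAND, color="#eef", lw=0)
        for mod in mods:
            segs = segment_epochs(rr_by_modality[mod], schedule)
            for e, s in segs:
                if e.label != condition or s.n_valid < 8:
                    continue
                t_k = s.beat_times_ms[1:][s.valid]
                if t_k[-1] - t_k[0] < 25000.0:  # matches hrv.spectral's minimum
                    continue
                grid = np.arange(t_k[0], t_k[-1], 1000.0 / hrv.DEFAULT_RESAMPLE_HZ)
                x = sci_interp.CubicSpline(t_k, s.rr_ms[s.valid])(grid)
                x = sps.detrend(x)
                nper = int(2 * len(x) / 5)
                f, p = sps.welch(x, fs=hrv.DEFAULT_RESAMPLE_HZ, nperseg=nper,
                                 noverlap=nper // 2, detrend=False)
                ax.semilogy(f, np.maximum(p, 1e-12), lw=0.8,
                            label=f"{mod} trial {e.trial}")
                break  # one representative epoch per modality
        ax.set_xlim(0, hrv.DEFAULT_HF_BAND[1] + 0.5)
        ax.set_xlabel("frequency (Hz)")
        ax.set_ylabel("PSD (ms²/Hz)")
        ax.set_title(condition)
        if ax.get_lines():
            ax.legend(fontsize=7)
    paths["psd"] = _save_fig(fig, out_dir, "psd")[0]

    # normalized-HR violins per modality and condition; normalization is
    # division by the session mean HR of that modality
    fig = Figure(figsize=(8, 4.2))
    ax = fig.subplots()
    data, labels = [], []
    for mod in mods:
        rr = rr_by_modality[mod]
        hr = 60000.0 / rr.valid_nn()
        base = hr.mean()
        segs = segment_epochs(rr, schedule)
        for condition in ("stimulation", "washout"):
            vals = np.concatenate(
                [60000.0 / s.valid_nn() / base
                 for e, s in segs if e.label == condition and s.usable]
                or [np.empty(0)]
            )
            if vals.size:
                data.append(vals)
                labels.append(f"{mod}\n{condition}")
    if data:
        ax.violinplot(data, showmedians=True)
        ax.set_xticks(range(1, len(labels) + 1), labels, fontsize=8)
    ax.set_ylabel("normalized HR")
    ax.set_title("Normalized heart rate by modality and condition")
    paths["violin"] = _save_fig(fig, out_dir, "normalized_hr_violin")[0]

    return paths
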