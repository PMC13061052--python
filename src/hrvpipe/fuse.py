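"""Multi-lead beat fusion.

R-peaks are detected independently on each in-ear channel; matched beats are
averaged into a single aggregate beat train. When one sensor degrades (e.g.
falls out of the ear canal mid-session), windowed quality gating drops that
channel locally and the other channel's beats pass through unchanged — the
fallback applies per 30 s window, not to the whole recording.

"Averaged" here means averaging the matched peak *times*, not the two RR
series: the fused output then remains a genuine point process from which RR
intervals are re-derived.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .detect import DEFAULT_HR_RANGE, DEFAULT_PHYSIO_RANGE_MS, extract_rr, reject_artifacts
from .types import BeatAnnotation, ChannelQuality, RRSeries

logger = logging.getLogger(__name__)

__all__ = ["channel_quality", "match_times", "match_beats", "aggregate_beats"]

DEFAULT_TOL_MS = 30.0       # < half the minimum rodent RR interval
DEFAULT_WINDOW_MS = 30000.0
DEFAULT_COVERAGE_THRESHOLD = 0.5


def channel_quality(
    ann: BeatAnnotation,
    record_duration_ms: float,
    hr_range: tuple[float, float] = DEFAULT_HR_RANGE,
    window_ms: float = DEFAULT_WINDOW_MS,
    threshold: float = DEFAULT_COVERAGE_THRESHOLD,
) -> list[ChannelQuality]:
    """Windowed beat coverage: detected beats over the minimum plausible count
    (window length × hr_min / 60000), capped at 1. A window is usable when
    coverage reaches ``threshold``."""
    if record_duration_ms <= 0:
        raise ValueError("record duration must be positive")
    window_ms = min(window_ms, record_duration_ms)
    hr_min = hr_range[0]
    edges = np.arange(0.0, record_duration_ms, window_ms)
    out = []
    for start in edges:
        end = min(start + window_ms, record_duration_ms)
        n = int(np.count_nonzero((ann.peak_times_ms >= start) & (ann.peak_times_ms < end)))
        expected = (end - start) * hr_min / 60000.0
        coverage = min(1.0, n / expected) if expected > 0 else 0.0
        out.append(ChannelQuality(ann.channel, start, end, coverage, coverage >= threshold))
    return out


def _match_canonical(a: np.ndarray, b: np.ndarray, tol: float):
    """Greedy chronological one-to-one nearest matching within ``tol``."""
    pairs: list[tuple[int, int]] = []
    i = j = 0
    na, nb = len(a), len(b)
    while i < na and j < nb:
        d = b[j] - a[i]
        if d < -tol:
            j += 1
        elif d > tol:
            i += 1
        else:
            cur = abs(d)
            nxt_a = abs(b[j] - a[i + 1]) if i + 1 < na else math.inf
            nxt_b = abs(b[j + 1] - a[i]) if j + 1 < nb else math.inf
            if nxt_a < cur and nxt_a <= nxt_b:
                i += 1  # a[i] has no better partner; leave unmatched
            elif nxt_b < cur:
                j += 1  # b[j] has no better partner
            else:
                pairs.append((i, j))
                i += 1
                j += 1
    return pairs


def match_times(
    a: np.ndarray, b: np.ndarray, tol_ms: float = DEFAULT_TOL_MS
) -> tuple[list[tuple[int, int]], np.ndarray, np.ndarray]:
    """Match two strictly increasing time arrays one-to-one within ``tol_ms``.

    Returns ``(pairs, unmatched_a, unmatched_b)`` where pairs are index
    tuples ``(i_a, i_b)``. The matching is symmetric: swapping the arguments
    swaps the pair order but changes nothing else.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    # canonical argument order so the operation is exactly symmetric
    key_a = (a[0] if len(a) else math.inf, len(a))
    key_b = (b[0] if len(b) else math.inf, len(b))
    if key_b < key_a:
        pairs = [(ia, ib) for ib, ia in _match_canonical(b, a, tol_ms)]
    else:
        pairs = _match_canonical(a, b, tol_ms)
    ua = np.setdiff1d(np.arange(len(a)), [p[0] for p in pairs])
    ub = np.setdiff1d(np.arange(len(b)), [p[1] for p in pairs])
    return pairs, ua, ub


def match_beats(
    ann_a: BeatAnnotation, ann_b: BeatAnnotation, tol_ms: float = DEFAULT_TOL_MS
) -> tuple[list[tuple[int, int]], np.ndarray, np.ndarray]:
    """`match_times` on the peak times of two annotations."""
    return match_times(ann_a.peak_times_ms, ann_b.peak_times_ms, tol_ms)


def aggregate_beats(
    anns: dict[str, BeatAnnotation],
    quality: dict[str, list[ChannelQuality]],
    tol_ms: float = DEFAULT_TOL_MS,
    physio_range_ms: tuple[float, float] = DEFAULT_PHYSIO_RANGE_MS,
    jump_frac: float = 0.3,
) -> RRSeries:
    """Fuse one or two beat trains into a single artifact-screened RR series.

    Within windows where both channels are usable, the fused beat time is the
    arithmetic mean of each matched pair; beats seen by only one (usable)
    channel there are dropped as likely artifacts. Within windows where a
    single channel is usable, that channel's beats pass through unchanged.
    Windows with no usable channel are excluded and logged.
    """
    labels = sorted(anns)
    if not 1 <= len(labels) <= 2:
        raise ValueError("aggregate_beats fuses one or two channels")
    for lab in labels:
        if lab not in quality:
            raise ValueError(f"missing quality windows for channel {lab!r}")

    if len(labels) == 1:
        t = np.asarray(anns[labels[0]].peak_times_ms, dtype=float)
        times = []
        for w in quality[labels[0]]:
            if w.usable:
                times.append(t[(t >= w.start_ms) & (t < w.end_ms)])
            else:
                logger.warning(
                    "window [%g, %g) ms: no usable channel, excluded",
                    w.start_ms, w.end_ms,
                )
        fused = np.concatenate(times) if times else np.empty(0)
    else:
        qa, qb = quality[labels[0]], quality[labels[1]]
        if len(qa) != len(qb) or any(
            (x.start_ms, x.end_ms) != (y.start_ms, y.end_ms) for x, y in zip(qa, qb)
        ):
            raise ValueError("quality windows must align across channels")
        a = anns[labels[0]].peak_times_ms
        b = anns[labels[1]].peak_times_ms
        pairs, _, _ = match_times(a, b, tol_ms)
        pair_means = np.array([(a[i] + b[j]) / 2.0 for i, j in pairs])
        times: list[np.ndarray] = []
        for wa, wb in zip(qa, qb):
            s, e = wa.start_ms, wa.end_ms
            if wa.usable and wb.usable:
                times.append(pair_means[(pair_means >= s) & (pair_means < e)])
            elif wa.usable:
                times.append(a[(a >= s) & (a < e)])
            elif wb.usable:
                times.append(b[(b >= s) & (b < e)])
            else:
                logger.warning("window [%g, %g) ms: no usable channel, excluded", s, e)
        fused = np.concatenate(times) if times else np.empty(0)

    fused = np.sort(fused)
    if len(fused) > 1:
        # guard against boundary duplicates (a pair mean and a fallback beat
        # describing the same physical beat across a window edge)
        keep = np.concatenate([[True], np.diff(fused) > tol_ms])
        fused = fused[keep]
    if len(fused) < 2:
        logger.warning("fused train has <2 beats; series unusable")
        return RRSeries(fused, np.empty(0), np.empty(0, dtype=bool))
    rr = extract_rr(BeatAnnotation("fused", np.zeros(len(fused), int), fused))
    return reject_artifacts(rr, physio_range_ms=physio_range_ms, jump_frac=jump_frac)
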