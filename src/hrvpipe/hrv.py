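"""The HRV metric battery: time-domain, frequency-domain and non-linear.

Conventions, fixed here once and asserted by the test suite:

* ``mean_hr`` is the mean of the instantaneous per-beat rate 60000/NN_i
  (not 60000 / mean NN — the two differ by Jensen's inequality whenever the
  series has variance).
* ``pnnx`` counts successive-difference magnitudes *strictly greater* than
  the threshold (default 5 ms, the rodent analogue of human pNN50).
* ``sd1`` is defined through the uncentered second moment of successive
  differences, sd1 = rmssd/√2, and ``sd2`` through
  sd2² = 2·var(NN) − sd1² (floored at 0), so that with population (ddof=0)
  variance the identity sd1² + sd2² = 2·sdnn² holds to machine precision.
* ``total_power`` is LF + HF by definition.
* successive-difference statistics skip pairs that span an invalid interval.

Undefined metrics are returned as NaN, never as 0.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import interpolate, signal as sps

from .types import HRVSummary, RRSeries

__all__ = [
    "time_domain",
    "poincare",
    "spectral",
    "sample_entropy",
    "dfa",
    "dfa_fluctuations",
    "compute_summary",
]

#: Rodent spectral band conventions (Hz). The LF band tracks baroreflex
#: activity, the HF band respiratory/parasympathetic modulation; rat
#: respiration under anesthesia sits near 1 Hz, far above the human bands.
DEFAULT_LF_BAND = (0.2, 0.75)
DEFAULT_HF_BAND = (0.75, 3.0)
DEFAULT_RESAMPLE_HZ = 20.0

DEFAULT_A1_SCALES = (4, 16)
DEFAULT_A2_SCALES = (16, 64)

#: Minimum segment length: two cycles of the lowest LF frequency, so the
#: averaged periodogram can resolve the bottom of the LF band.
_MIN_SEGMENT_CYCLES = 2.0


def time_domain(
    rr: RRSeries, pnn_threshold_ms: float = 5.0, ddof: int = 1
) -> dict[str, float]:
    """Mean RR/HR, SDNN, RMSSD and PNNx over the valid intervals."""
    nn = rr.valid_nn()
    diffs = rr.valid_pair_diffs()
    out = {
        "mean_rr": math.nan,
        "mean_hr": math.nan,
        "sdnn": math.nan,
        "rmssd": math.nan,
        "pnnx": math.nan,
    }
    if nn.size >= 1:
        out["mean_rr"] = float(nn.mean())
        out["mean_hr"] = float(np.mean(60000.0 / nn))
    if nn.size >= 2:
        out["sdnn"] = float(nn.std(ddof=ddof))
    if diffs.size >= 2:
        out["rmssd"] = float(np.sqrt(np.mean(diffs**2)))
        out["pnnx"] = float(100.0 * np.mean(np.abs(diffs) > pnn_threshold_ms))
    return out


def poincare(rr: RRSeries, ddof: int = 0) -> tuple[float, float, float]:
    """Poincaré short-axis SD1, long-axis SD2 and their ratio.

    sd1 = sqrt(mean(diff²)/2) (= rmssd/√2); sd2 = sqrt(2·var(NN) − sd1²),
    floored at 0. The ratio is NaN when sd2 = 0 (e.g. perfect alternation).
    """
    nn = rr.valid_nn()
    diffs = rr.valid_pair_diffs()
    if nn.size < 3 or diffs.size < 2:
        return math.nan, math.nan, math.nan
    sd1_sq = float(np.mean(diffs**2)) / 2.0
    sd1 = math.sqrt(sd1_sq)
    sd2_sq = 2.0 * float(nn.var(ddof=ddof)) - sd1_sq
    sd2 = math.sqrt(max(sd2_sq, 0.0))
    ratio = sd1 / sd2 if sd2 > 0 else math.nan
    return sd1, sd2, ratio


def spectral(
    rr: RRSeries,
    lf_band: tuple[float, float] = DEFAULT_LF_BAND,
    hf_band: tuple[float, float] = DEFAULT_HF_BAND,
    resample_hz: float = DEFAULT_RESAMPLE_HZ,
) -> tuple[float, float, float, float]:
    """LF, HF, total power (ms²) and LF/HF from the resampled tachogram.

    The tachogram (valid intervals against their end-beat times) is cubic-
    interpolated onto a uniform grid — invalid intervals are bridged by the
    interpolation — linearly detrended, and the PSD is an averaged (Welch)
    periodogram over at least 4 half-overlapping Hann segments, each spanning
    at least two cycles of the lowest LF frequency. Epochs too short for that
    (under ~25 s of valid beats at the default bands) return NaNs.
    """
    nan4 = (math.nan, math.nan, math.nan, math.nan)
    t = rr.beat_times_ms[1:][rr.valid]
    v = rr.rr_ms[rr.valid]
    min_span_ms = 2.5 * _MIN_SEGMENT_CYCLES / lf_band[0] * 1000.0
    if t.size < 8 or (t[-1] - t[0]) < min_span_ms:
        return nan4
    step_ms = 1000.0 / resample_hz
    grid = np.arange(t[0], t[-1], step_ms)
    if grid.size < 40:
        return nan4
    x = interpolate.CubicSpline(t, v)(grid)
    x = sps.detrend(x, type="linear")
    nper = int(2 * grid.size / 5)  # >= 4 segments at 50% overlap
    freqs, psd = sps.welch(
        x, fs=resample_hz, window="hann", nperseg=nper, noverlap=nper // 2,
        detrend=False,
    )

    def band_power(band: tuple[float, float]) -> float:
        mask = (freqs >= band[0]) & (freqs < band[1])
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[mask], freqs[mask]))

    lf = band_power(lf_band)
    hf = band_power(hf_band)
    total = lf + hf
    ratio = lf / hf if hf > 0 else math.nan
    return lf, hf, total, ratio


def sample_entropy(rr: RRSeries, m: int = 2, r_frac: float = 0.2) -> float:
    """Sample entropy −ln(A/B) of the valid NN series.

    Template length ``m``, tolerance r = ``r_frac``·SD(NN) (population SD),
    Chebyshev distance, self-matches excluded. Both A (length m+1) and B
    (length m) count ordered pairs over the N−m templates whose m+1-point
    extension exists; A = 0 or B = 0 gives NaN, except for the constant
    series where every template matches and the entropy is exactly 0.
    """
    x = rr.valid_nn()
    n = x.size
    if n < m + 2:
        return math.nan
    r = r_frac * float(x.std(ddof=0))
    n_templates = n - m  # drop the last m-window so the m+1 extension exists
    win_m = sliding_window_view(x, m)[:n_templates]
    win_m1 = sliding_window_view(x, m + 1)

    def count_pairs(win: np.ndarray) -> int:
        k = len(win)
        total = 0
        # row-wise to keep memory bounded for long sessions
        for i in range(k - 1):
            d = np.max(np.abs(win[i + 1 :] - win[i]), axis=1)
            total += int(np.count_nonzero(d <= r))
        return total

    b = count_pairs(win_m)
    a = count_pairs(win_m1)
    if a == 0 or b == 0:
        return math.nan
    return float(-math.log(a / b))


def _box_scales(lo: int, hi: int, n_scales: int = 10) -> np.ndarray:
    s = np.unique(np.round(np.logspace(math.log10(lo), math.log10(hi), n_scales)))
    return s.astype(int)


def dfa_fluctuations(x: np.ndarray, scales: np.ndarray) -> np.ndarray:
    """Detrended fluctuation F(n) of a series for each box size ``n``.

    The series is mean-centered and integrated; each non-overlapping box of
    ``n`` points is least-squares detrended (order 1) and F(n) is the RMS of
    all residuals. Scales with fewer than 4 full boxes give NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.cumsum(x - x.mean())
    out = np.full(len(scales), math.nan)
    for k, n in enumerate(scales):
        n = int(n)
        n_boxes = len(y) // n
        if n_boxes < 4:
            continue
        boxes = y[: n_boxes * n].reshape(n_boxes, n)
        t = np.arange(n)
        coef = np.polynomial.polynomial.polyfit(t, boxes.T, 1)
        trend = coef[0][:, None] + coef[1][:, None] * t
        out[k] = math.sqrt(float(np.mean((boxes - trend) ** 2)))
    return out


def _alpha(x: np.ndarray, lo: int, hi: int, finite_size_correction: bool = True) -> float:
    scales = _box_scales(lo, hi)
    f = dfa_fluctuations(x, scales)
    if finite_size_correction:
        # Exact small-box factor for uncorrelated data under linear
        # detrending: E[F²(n)] = σ²(n²−4)/(15n), i.e. the asymptotic
        # n^0.5 law times (1 − 4/n²). Dividing it out removes the upward
        # bias of the short-scale exponent (the usual correction against
        # uncorrelated surrogates); it matters only for boxes of a few beats.
        f = f / np.sqrt(1.0 - 4.0 / scales.astype(float) ** 2)
    ok = np.isfinite(f) & (f > 0)
    if ok.sum() < 3:
        return math.nan
    slope = np.polyfit(np.log(scales[ok]), np.log(f[ok]), 1)[0]
    return float(slope)


def dfa(
    rr: RRSeries,
    a1_scales: tuple[int, int] = DEFAULT_A1_SCALES,
    a2_scales: tuple[int, int] = DEFAULT_A2_SCALES,
    finite_size_correction: bool = True,
) -> tuple[float, float, float]:
    """Short- (α1, boxes 4–16) and long-range (α2, boxes 16–64) scaling
    exponents of the valid NN series, and their ratio α1/α2."""
    x = rr.valid_nn()
    a1 = (
        _alpha(x, *a1_scales, finite_size_correction)
        if x.size >= 4 * a1_scales[1] else math.nan
    )
    a2 = (
        _alpha(x, *a2_scales, finite_size_correction)
        if x.size >= 4 * a2_scales[1] else math.nan
    )
    ratio = a1 / a2 if (not math.isnan(a1) and not math.isnan(a2) and a2 != 0) else math.nan
    return a1, a2, ratio


def compute_summary(
    rr: RRSeries,
    epoch_label: str = "",
    modality: str = "",
    trial: int = 0,
    pnn_threshold_ms: float = 5.0,
    lf_band: tuple[float, float] = DEFAULT_LF_BAND,
    hf_band: tuple[float, float] = DEFAULT_HF_BAND,
    resample_hz: float = DEFAULT_RESAMPLE_HZ,
    a1_scales: tuple[int, int] = DEFAULT_A1_SCALES,
    a2_scales: tuple[int, int] = DEFAULT_A2_SCALES,
) -> HRVSummary:
    """Assemble the full 16-metric battery for one epoch and modality.

    Sub-metrics that are undefined for the series (too short, degenerate)
    propagate as NaN fields.
    """
    td = time_domain(rr, pnn_threshold_ms=pnn_threshold_ms)
    sd1, sd2, sd_ratio = poincare(rr)
    lf, hf, total, lf_hf = spectral(rr, lf_band, hf_band, resample_hz)
    sampen = sample_entropy(rr)
    a1, a2, a_ratio = dfa(rr, a1_scales, a2_scales)
    return HRVSummary(
        mean_rr=td["mean_rr"],
        mean_hr=td["mean_hr"],
        sdnn=td["sdnn"],
        rmssd=td["rmssd"],
        pnnx=td["pnnx"],
        lf=lf,
        hf=hf,
        total_power=total,
        lf_hf=lf_hf,
        sd1=sd1,
        sd2=sd2,
        sd1_sd2=sd_ratio,
        sampen=sampen,
        dfa_a1=a1,
        dfa_a2=a2,
        dfa_ratio=a_ratio,
        n_beats=len(rr.beat_times_ms),
        epoch_label=epoch_label,
        modality=modality,
        trial=trial,
    )
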