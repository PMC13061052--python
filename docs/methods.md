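# Methods

This note documents the models, conventions and numerical choices behind
`hrvpipe`, and what its synthetic studies do and do not establish about real
recordings.

## Synthetic studies

The generator emulates an anesthetized-rat stimulation/washout experiment
with two in-ear ECG channels and one chest lead.

**RR process.** Beats are placed sequentially from t = 0; each interval is

    RR_i = RR̄ + Δ_stim·1[t_i in stimulation] + A_LF·sin(2π f_LF t_i + φ_LF)
         + A_HF·sin(2π f_HF t_i + φ_HF) + σ·ε_i

with phases drawn once from the seeded generator. Intervals are modulated
directly rather than through integral pulse-frequency modulation: the ground
truth is then exact by construction, and at the modulation depths used here
(a few ms on a 150 ms mean) the two formulations are indistinguishable.
Defaults: RR̄ = 150 ms (400 BPM, the middle of the 200–500 BPM rodent
range), A_LF = 2 ms at 0.4 Hz, A_HF = 3 ms at 1.5 Hz (a plausible
anesthetized-rat respiratory rate), σ = 1.5 ms. These give SDNN ≈ 3 ms and
LF/HF < 1 — a modest-variability, vagally-dominated profile. A configuration
that could produce non-positive intervals is rejected up front.

**Waveform.** Each beat renders a three-Gaussian QRST template (Q −0.15 at
−12 ms, R 1.0 at 0 with ≈8 ms width, T 0.25 at +25 ms) evaluated at exact
off-grid beat times, plus 0.35 Hz baseline wander at 20 % of R amplitude and
white channel noise (SD in units of R amplitude; 0.1 ≈ 20 dB peak SNR;
defaults 0.08/0.12/0.05 for ear_left/ear_right/chest so the channels
differ). A dropout window replaces a channel's samples with its noise alone —
a sensor out of the canal still feeds the amplifier — rather than attenuating
them.

**What the simulator does not model:** motion artifacts with ECG-like
morphology, electrode-impedance drift, ectopic beats, respiration–cardiac
coupling beyond a fixed sinusoid, and non-stationary autonomic trends.
Passing tests therefore demonstrate correctness of the *analysis* under
controlled conditions, not robustness to every pathology of in-vivo data.

## Detection

Channels are band-passed 10–200 Hz (4th-order Butterworth) and
standardized. Filtering is zero-phase (`sosfiltfilt`): a causal filter would
shift every peak by the group delay, which is fatal when the quantity of
interest is millisecond-scale RR variation. The detection transform itself
runs on a narrower QRS-matched band (10–50 Hz): the rodent R-wave
concentrates its energy there, while the derivative stage would otherwise
amplify wideband noise to the point of swamping the QRS (measured
sensitivity at noise SD 0.3: 0.98 with the matched band vs 0.14 without).

Candidates are local maxima of the integrated derivative energy separated by
the refractory period 60000/hr_max ms (120 ms at the default 500 BPM
ceiling — tying it to the configured range keeps the detector species-
agnostic). An adaptive signal/noise-level threshold in the Pan–Tompkins
style classifies candidates, with an absolute floor of 2.5× the median
integrated energy so that long noise-only stretches (dropout) cannot drag
the threshold onto the noise floor. Accepted peaks are refined to the
extremum of the band-passed waveform within ±10 ms, making localization
polarity-robust and unbiased.

Artifact screening flags intervals outside 120–300 ms (the 200–500 BPM
range) or deviating more than 30 % from the running median of the last 9
valid intervals. Flags are applied in a single forward pass in which flagged
intervals leave the median buffer; this makes the operation idempotent.
Intervals are never deleted, so the beat-time axis remains intact for
spectral resampling; successive-difference statistics skip pairs spanning a
flagged interval.

## Fusion

"Compared and averaged" is implemented as averaging matched peak *times*
(greedy chronological one-to-one matching within 30 ms — under half the
minimum rodent RR, so matches are unambiguous), not averaging the two RR
series: the fused output stays a genuine point process from which intervals
are re-derived. Beats seen by only one channel while both are usable are
dropped as likely artifacts (conservative, logged). Quality gating is
windowed (30 s, coverage ≥ 0.5 of the minimum plausible beat count at
hr_min) so a mid-session sensor loss triggers the single-channel fallback
only where it happened. Averaging two channels with independent localization
jitter reduces RR error by ≈ √2, which the acceptance checks measure.

## Metric conventions

- **Mean HR** is the mean of instantaneous per-beat rate 60000/NN_i, not
  60000/mean(NN); the two differ by Jensen's inequality on any variable
  series, and the per-beat convention is the one consistent with jointly
  reported mean RR/HR pairs in this assay class.
- **PNN5** uses a strict inequality (|ΔNN| > 5 ms). The 5 ms threshold is
  the rodent analogue of the human 50 ms criterion, scaled for 200–500 BPM.
- **SDNN** is reported with sample variance (ddof 1); the Poincaré
  identities are defined with population (ddof 0) estimators, and both
  functions expose `ddof` so identity checks use matched conventions.
- **SD1/SD2**: SD1 = √(mean ΔNN²/2) = RMSSD/√2 (uncentered second moment —
  with a centered variance the identity only holds up to mean(ΔNN)²), and
  SD2 = √(2·Var(NN) − SD1²) floored at 0, so SD1² + SD2² = 2·SDNN² holds to
  machine precision. SD1/SD2 is undefined (NaN) when SD2 = 0, e.g. under
  perfect alternation.
- **Spectral bands**: LF 0.2–0.75 Hz, HF 0.75–3.0 Hz — rodent-HRV
  conventions (rat baroreflex and respiratory frequencies sit an order of
  magnitude above the human bands); both are configuration parameters, as is
  the 20 Hz resampling rate. The tachogram (valid intervals at their
  end-beat times) is cubic-spline resampled — invalid intervals are bridged,
  not zero-filled — linearly detrended, and analyzed with a Hann-window
  Welch periodogram at ≥ 4 half-overlapping segments, each at least two
  cycles of the LF floor (so epochs under ~25 s of valid beats report NaN).
  Total power is LF + HF by definition here, and LF/HF is undefined when
  HF = 0.
- **Sample entropy**: m = 2, r = 0.2·SD(NN) (population SD), Chebyshev
  distance, self-matches excluded, both template lengths counted over the
  N−m windows whose m+1 extension exists. A constant series yields SampEn 0
  (all templates match at r = 0); A = 0 or B = 0 yields NaN. Series shorter
  than m+2 are undefined; note that estimates on fewer than a few dozen
  intervals are statistically fragile even when computable.
- **DFA**: profile = cumulative sum of mean-centered NN; non-overlapping
  boxes, order-1 detrending, ~10 log-spaced box sizes per range (α1 4–16,
  α2 16–64 beats), requiring ≥ 4 full boxes per size and ≥ 3 usable sizes
  per exponent. The fluctuation function is divided by the analytic
  finite-size factor √(1 − 4/n²) before the log–log fit: for uncorrelated
  data E[F²(n)] = σ²(n²−4)/(15n), so the raw short-scale exponent is biased
  upward (≈ 0.59 instead of 0.5 over boxes 4–16); the correction — the usual
  normalization against uncorrelated surrogates — removes it. α ratio is
  α1/α2, undefined when α2 is.
- Undefined metrics propagate as NaN and render as blank cells, never as 0.

## Statistics

Sequential effects use the trial structure: each stimulation epoch is paired
with its subsequent washout, differences are S−W (a positive injected RR
shift yields a positive mean RR delta), the test is a two-sided paired t,
and the effect size is the paired d_z = mean(diff)/SD(diff) — d conventions
differ, so this is fixed here. |d| > 0.8 is labeled large and |d| > 0.5
medium. Modality agreement uses a two-sided Welch (unequal-variance)
independent t-test of per-epoch values pooled across trials; identical value
sets short-circuit to p = 1. Zero-spread differences leave d and p undefined
rather than infinite. No multiple-testing correction is applied by default,
matching per-metric reporting; callers can correct externally. "Normalized
HR" in the violin figure is instantaneous HR divided by the session mean HR
of the same modality.

## Problem sizes

The statistical-recovery checks simulate 8 trials of 30 s stimulation +
30 s washout (480 s studies) at 20 dB SNR, 20 studies per condition —
enough epochs for stable paired statistics while keeping a full
detection-to-statistics round under a second per study. Detection fidelity
is scored on 60 s single-trial studies (~400 beats); DFA calibration uses
1000-interval series, the identity sweep 500 random series, and the
brute-force sample-entropy cross-checks series of ≤ 100 intervals.

## Known limitations

- The fusion consensus is defined for the two-ear case; weighted or >2-lead
  voting is out of scope.
- Spectral estimates on 30 s epochs carry few Welch segments and are
  correspondingly noisy; α2 needs ≥ 256 valid intervals and is undefined on
  short epochs.
- The detector assumes R-dominant complexes of roughly rodent width; other
  species need the heart-rate range (and possibly the QRS-matched band)
  reconfigured.
- Statistics treat epochs as exchangeable within a session; between-subject
  mixed-effects modelling is out of scope.
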