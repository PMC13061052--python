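import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrvpipe import hrv
from hrvpipe.types import RRSeries

from conftest import rr_from_intervals


def _random_series(seed, n=200, mean=150.0, sd=8.0):
    rng = np.random.default_rng(seed)
    return rr_from_intervals(np.clip(mean + sd * rng.standard_normal(n), 20.0, None))


class TestTimeDomain:
    def test_constant_series(self):
        rr = rr_from_intervals(np.full(100, 150.0))
        td = hrv.time_domain(rr)
        assert td["mean_rr"] == pytest.approx(150.0)
        assert td["mean_hr"] == pytest.approx(400.0)
        assert td["sdnn"] == pytest.approx(0.0)
        assert td["rmssd"] == pytest.approx(0.0)
        assert td["pnnx"] == pytest.approx(0.0)

    def test_alternating_series(self, alt_series):
        td = hrv.time_domain(alt_series)
        assert td["mean_rr"] == pytest.approx(150.0)
        assert td["mean_hr"] == pytest.approx((60000 / 140 + 60000 / 160) / 2)
        assert td["sdnn"] == pytest.approx(10.0, rel=1e-2)
        assert td["rmssd"] == pytest.approx(20.0)
        assert td["pnnx"] == pytest.approx(100.0)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(11)
        x = 150 + 10 * rng.standard_normal(50)
        rr = rr_from_intervals(x)
        td = hrv.time_domain(rr, pnn_threshold_ms=5.0)
        d = np.diff(x)
        assert td["mean_rr"] == pytest.approx(x.mean(), rel=1e-12)
        assert td["mean_hr"] == pytest.approx(np.mean(60000.0 / x), rel=1e-12)
        assert td["sdnn"] == pytest.approx(x.std(ddof=1), rel=1e-12)
        assert td["rmssd"] == pytest.approx(np.sqrt(np.mean(d**2)), rel=1e-12)
        assert td["pnnx"] == pytest.approx(100.0 * np.mean(np.abs(d) > 5.0), rel=1e-12)

    def test_pnn_threshold_strict_inequality(self):
        rr = rr_from_intervals([150.0, 155.0, 150.0, 155.0])  # diffs exactly 5 ms
        td = hrv.time_domain(rr)
        assert td["pnnx"] == 0.0

    def test_invalid_intervals_excluded_from_successive_stats(self):
        rr = RRSeries([0, 150, 750, 900, 1050, 1200],
                      [150.0, 600.0, 150.0, 150.0, 150.0],
                      [True, False, True, True, True])
        td = hrv.time_domain(rr)
        # pairs spanning the invalid interval are skipped
        assert td["rmssd"] == pytest.approx(0.0)
        assert td["mean_rr"] == pytest.approx(150.0)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_pnnx_monotone_in_threshold(self, seed):
        rr = _random_series(seed, n=60)
        vals = [hrv.time_domain(rr, pnn_threshold_ms=th)["pnnx"] for th in (2, 5, 10, 20)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestPoincare:
    def test_perfect_alternation_kills_long_axis(self, alt_series):
        sd1, sd2, ratio = hrv.poincare(alt_series)
        assert sd1 == pytest.approx(20.0 / math.sqrt(2))
        assert sd2 == pytest.approx(0.0)
        assert math.isnan(ratio)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_sd1_is_rmssd_over_sqrt2(self, seed):
        rr = _random_series(seed)
        sd1, _, _ = hrv.poincare(rr)
        rmssd = hrv.time_domain(rr)["rmssd"]
        assert sd1 == pytest.approx(rmssd / math.sqrt(2), rel=1e-12)

    def test_variance_identity_with_matched_estimators(self):
        rr = _random_series(5, n=200)
        sd1, sd2, _ = hrv.poincare(rr, ddof=0)
        sdnn = hrv.time_domain(rr, ddof=0)["sdnn"]
        assert sd1**2 + sd2**2 == pytest.approx(2 * sdnn**2, rel=1e-9)


class TestSpectral:
    def test_constant_series_has_no_power(self):
        rr = rr_from_intervals(np.full(400, 150.0))
        lf, hf, total, _ = hrv.spectral(rr)
        assert total < 1e-6

    def _modulated(self, freq_hz, amp=5.0, duration_ms=300000.0):
        t = [0.0]
        while t[-1] < duration_ms:
            t.append(t[-1] + 150.0 + amp * math.sin(2 * math.pi * freq_hz * t[-1] / 1000.0))
        return RRSeries.from_times(np.array(t))

    def test_hf_modulation_lands_in_hf_band(self):
        lf, hf, total, _ = hrv.spectral(self._modulated(1.5))
        assert hf / total >= 0.95

    def test_lf_modulation_lands_in_lf_band(self):
        lf, hf, total, _ = hrv.spectral(self._modulated(0.4))
        assert lf / total >= 0.95

    def test_total_power_is_lf_plus_hf(self):
        rr = _random_series(7, n=2500)
        lf, hf, total, ratio = hrv.spectral(rr)
        assert total == lf + hf
        assert ratio == pytest.approx(lf / hf)

    def test_short_epoch_undefined(self):
        rr = rr_from_intervals(np.full(50, 150.0))  # 7.5 s only
        assert all(math.isnan(v) for v in hrv.spectral(rr))


def sampen_bruteforce(x, m, r):
    """Exhaustive O(N²) template-pair enumeration (Chebyshev distance)."""
    n = len(x)
    a = b = 0
    for i in range(n - m):
        for j in range(n - m):
            if i == j:
                continue
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
            if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                a += 1
    if a == 0 or b == 0:
        return math.nan
    return -math.log(a / b)


class TestSampleEntropy:
    def test_constant_series_zero_entropy(self):
        rr = rr_from_intervals(np.full(100, 150.0))
        assert hrv.sample_entropy(rr) == pytest.approx(0.0)

    def test_eight_interval_alternating_equals_bruteforce(self):
        x = np.array([140.0, 160.0] * 4)
        rr = rr_from_intervals(x)
        r = 0.2 * x.std(ddof=0)
        assert hrv.sample_entropy(rr, m=2) == pytest.approx(
            sampen_bruteforce(x, 2, r), abs=0.0
        )

    @pytest.mark.parametrize("seed", [0, 3, 9])
    def test_random_series_equals_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        x = 150 + 10 * rng.standard_normal(80)
        rr = rr_from_intervals(x)
        r = 0.2 * x.std(ddof=0)
        expected = sampen_bruteforce(x, 2, r)
        assert hrv.sample_entropy(rr, m=2) == pytest.approx(expected, rel=1e-12)

    def test_noise_more_entropic_than_sinusoid_of_equal_sd(self):
        rng = np.random.default_rng(23)
        noise = 150 + 5 * rng.standard_normal(500)
        k = np.arange(500)
        sine = 150 + 5 * math.sqrt(2) * np.sin(2 * math.pi * k / 25)
        assert hrv.sample_entropy(rr_from_intervals(noise)) > hrv.sample_entropy(
            rr_from_intervals(sine)
        )


class TestDFA:
    def test_white_noise_alpha1_near_half(self):
        rng = np.random.default_rng(7)
        rr = rr_from_intervals(150 + 5 * rng.standard_normal(1000))
        a1, a2, ratio = hrv.dfa(rr)
        assert 0.4 <= a1 <= 0.6
        assert ratio == pytest.approx(a1 / a2)

    def test_integrated_noise_alpha1_near_three_halves(self):
        rng = np.random.default_rng(7)
        rr = rr_from_intervals(150 + np.cumsum(rng.standard_normal(1000)))
        a1, _, _ = hrv.dfa(rr)
        assert 1.3 <= a1 <= 1.7

    def test_fluctuations_match_per_box_oracle(self):
        rng = np.random.default_rng(2)
        x = 150 + 10 * rng.standard_normal(64)
        scales = np.array([4, 8, 16])
        f = hrv.dfa_fluctuations(x, scales)
        y = np.cumsum(x - x.mean())
        for k, n in enumerate(scales):
            residuals = []
            for b in range(len(y) // n):
                seg = y[b * n : (b + 1) * n]
                t = np.arange(n)
                coef = np.polyfit(t, seg, 1)
                residuals.extend(seg - np.polyval(coef, t))
            expected = math.sqrt(np.mean(np.square(residuals)))
            assert f[k] == pytest.approx(expected, rel=1e-10)

    def test_short_series_alpha2_undefined(self):
        rr = _random_series(1, n=100)
        a1, a2, ratio = hrv.dfa(rr)
        assert not math.isnan(a1)
        assert math.isnan(a2) and math.isnan(ratio)


class TestComputeSummary:
    def test_composition_consistent_with_components(self, alt_series):
        s = hrv.compute_summary(alt_series, "stimulation", "ear", trial=1)
        assert s.mean_rr == pytest.approx(150.0)
        assert s.rmssd == pytest.approx(20.0)
        assert s.sd1 == pytest.approx(20.0 / math.sqrt(2))
        assert s.sd2 == pytest.approx(0.0)
        assert math.isnan(s.sd1_sd2)  # undefined, not imputed
        assert s.pnnx == pytest.approx(100.0)
        assert (s.epoch_label, s.modality, s.trial) == ("stimulation", "ear", 1)

    def test_time_domain_invariant_under_epoch_repetition(self):
        # cyclic pattern: the junction difference equals the interior ones,
        # so per-pair statistics are exactly repetition-invariant
        x = np.tile([140.0, 160.0], 50)
        one = hrv.compute_summary(rr_from_intervals(x))
        two = hrv.compute_summary(rr_from_intervals(np.tile(x, 2)))
        assert one.mean_rr == pytest.approx(two.mean_rr)
        assert one.mean_hr == pytest.approx(two.mean_hr)
        assert one.rmssd == pytest.approx(two.rmssd)
        assert one.pnnx == pytest.approx(two.pnnx)

    @pytest.mark.parametrize("shift_ms", [0.0, 12345.6])
    def test_metrics_invariant_under_time_shift(self, shift_ms):
        rr = _random_series(31, n=600)
        shifted = RRSeries(rr.beat_times_ms + shift_ms, rr.rr_ms, rr.valid)
        s0 = hrv.compute_summary(rr)
        s1 = hrv.compute_summary(shifted)
        for name, v0 in s0.metrics().items():
            v1 = s1.metric(name)
            assert (math.isnan(v0) and math.isnan(v1)) or v0 == pytest.approx(
                v1, rel=1e-9
            ), name

    def test_too_short_series_reports_undefined_everywhere(self):
        rr = rr_from_intervals([150.0])
        s = hrv.compute_summary(rr)
        assert math.isnan(s.sdnn) and math.isnan(s.sampen) and math.isnan(s.lf)
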