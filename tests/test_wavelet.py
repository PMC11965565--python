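"""Morlet spectra, ridge extraction, weighting, phase differences."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circapheno import wavelet
from circapheno.exceptions import ConfigurationError
from circapheno.preprocess import DetrendedSignal

DT = 1.0 / 6.0


def detrended(values, dt=DT, **kw):
    t = np.arange(len(values)) * dt
    return DetrendedSignal(times=t, detrended=np.asarray(values, float), **kw)


def make_ridge(mask_hours, dt=DT, period=24.0):
    n = int(round(140 / dt))
    t = np.arange(n) * dt
    mask = t < mask_hours
    return wavelet.Ridge(
        times=t,
        period_t=np.full(n, period),
        amplitude_t=np.ones(n),
        phase_t=np.zeros(n),
        power_t=np.where(mask, 1.0, 0.0),
        mask=mask,
        threshold=0.5,
        threshold_mode="adaptive",
    )


class TestSpectrum:
    def test_power_peaks_at_the_tone_period(self, times, sine24):
        spec = wavelet.cwt_spectrum(DetrendedSignal(times=times, detrended=sine24))
        mid = spec.power[:, spec.power.shape[1] // 2]
        assert spec.periods[np.argmax(mid)] == pytest.approx(24.0, abs=0.2)

    def test_two_tones_give_two_power_bands(self, times):
        x = np.sin(2 * np.pi * times / 24) + np.sin(2 * np.pi * times / 8)
        spec = wavelet.cwt_spectrum(DetrendedSignal(times=times, detrended=x))
        mid = spec.power[:, spec.power.shape[1] // 2]
        in_band = lambda p: np.argmin(np.abs(spec.periods - p))
        floor = mid[in_band(14.0)]
        assert mid[in_band(24.0)] > 10 * floor
        assert mid[in_band(8.0)] > 10 * floor

    def test_constant_signal_has_negligible_power(self, times):
        spec = wavelet.cwt_spectrum(
            DetrendedSignal(times=times, detrended=np.full_like(times, 3.0))
        )
        assert spec.power.max() < 1e-10

    def test_grid_beyond_series_span_rejected(self):
        d = detrended(np.sin(np.arange(200) * 0.1))
        with pytest.raises(ConfigurationError):
            wavelet.cwt_spectrum(d, periods_h=np.arange(6.0, 60.0, 0.1))

    def test_amplitude_calibration_on_known_tone(self, times):
        x = 2.0 * np.sin(2 * np.pi * times / 24 + 0.7)
        spec = wavelet.cwt_spectrum(DetrendedSignal(times=times, detrended=x))
        ridge = wavelet.extract_ridge(spec)
        # outside the boundary cone of influence (~2 scale widths)
        interior = (times > 50.0) & (times < times[-1] - 50.0)
        assert np.abs(ridge.amplitude_t[interior] - 2.0).max() < 0.05


class TestRidge:
    def test_noise_free_tone_ridge_spans_recording(self, sine24_detrended):
        ridge = wavelet.extract_ridge(wavelet.cwt_spectrum(sine24_detrended))
        assert ridge.ridge_length_h > 0.95 * sine24_detrended.span_h

    def test_damped_signal_tail_masked_under_global_threshold(self, times):
        signals = [
            np.exp(-g * times) * np.sin(2 * np.pi * times / 24)
            for g in (0.001, 0.001, 0.03, 0.03)
        ]
        batch = [
            wavelet.cwt_spectrum(DetrendedSignal(times=times, detrended=x))
            for x in signals
        ]
        strong = wavelet.extract_ridge(batch[0], mode="global", batch=batch)
        weak = wavelet.extract_ridge(batch[2], mode="global", batch=batch)
        assert weak.ridge_length_h < strong.ridge_length_h
        assert weak.ridge_length_h < 0.7 * times[-1]

    def test_pure_noise_ridge_vanishes_under_global_threshold(self, times, rng):
        signals = [np.sin(2 * np.pi * times / 24) for _ in range(4)]
        noise = rng.normal(0, 1, len(times))
        batch = [
            wavelet.cwt_spectrum(DetrendedSignal(times=times, detrended=x))
            for x in signals + [noise]
        ]
        ridge = wavelet.extract_ridge(batch[-1], mode="global", batch=batch)
        assert ridge.ridge_length_h < 0.1 * times[-1]

    def test_raising_threshold_never_lengthens_ridges(self, times, rng):
        x = np.exp(-0.01 * times) * np.sin(2 * np.pi * times / 24)
        spec = wavelet.cwt_spectrum(
            DetrendedSignal(times=times, detrended=x + 0.1 * rng.normal(size=len(times)))
        )
        lengths = [
            wavelet.extract_ridge(spec, threshold=thr).ridge_length_h
            for thr in np.linspace(0.0, spec.power.max(), 12)
        ]
        assert all(a >= b for a, b in zip(lengths, lengths[1:]))

    def test_all_below_threshold_gives_zero_length_not_error(self, sine24_detrended):
        spec = wavelet.cwt_spectrum(sine24_detrended)
        ridge = wavelet.extract_ridge(spec, threshold=2 * spec.power.max())
        assert ridge.ridge_length_h == 0.0


class TestReadouts:
    def test_chirp_period_tracked_along_the_sweep(self, times):
        inst_period = 22.0 + 6.0 * times / times[-1]
        phase = np.cumsum(2 * np.pi / inst_period) * DT
        spec = wavelet.cwt_spectrum(DetrendedSignal(times=times, detrended=np.sin(phase)))
        ridge = wavelet.extract_ridge(spec)
        summary = wavelet.ridge_readouts(ridge)
        assert 22.0 < summary.period_mean_h < 28.0
        interior = ridge.mask & (times > 30) & (times < times[-1] - 30)
        err = np.abs(ridge.period_t[interior] - inst_period[interior])
        assert err.mean() < 0.5

    def test_stationary_tone_low_period_variability(self, sine24_detrended):
        ridge = wavelet.extract_ridge(wavelet.cwt_spectrum(sine24_detrended))
        summary = wavelet.ridge_readouts(ridge)
        assert summary.period_mean_h == pytest.approx(24.0, abs=0.3)
        assert summary.period_cv < 0.02

    def test_short_ridge_excluded_from_parameter_readouts(self):
        summary = wavelet.ridge_readouts(make_ridge(40.0))
        assert not summary.included
        assert summary.ridge_length_h == pytest.approx(40.0, abs=0.5)
        assert np.isnan(summary.period_mean_h)


class TestRidgeWeight:
    def test_reflection_point_weighs_one_half(self):
        assert wavelet.ridge_weight(60.0, x0=60.0) == pytest.approx(0.5)

    def test_forty_hours_past_reflection(self):
        assert wavelet.ridge_weight(100.0, x0=60.0) == pytest.approx(
            1.0 / (1.0 + np.exp(-4.0)), abs=1e-12
        )

    def test_short_ridge_gets_small_positive_weight(self):
        w = wavelet.ridge_weight(0.0, x0=100.0)
        assert 0.0 < w < 0.01

    @given(st.floats(0.0, 137.0), st.floats(0.0, 137.0))
    @settings(max_examples=50, deadline=None)
    def test_weight_increases_with_ridge_length(self, a, b):
        lo, hi = sorted((a, b))
        assert wavelet.ridge_weight(lo, x0=60.0) <= wavelet.ridge_weight(hi, x0=60.0)

    def test_weighted_mean_of_constant_is_constant(self, rng):
        lengths = rng.uniform(10, 130, 20)
        mean, median = wavelet.batch_weighted_stats(np.full(20, 3.7), lengths)
        assert mean == pytest.approx(3.7)
        assert median == pytest.approx(3.7, abs=1e-6)


class TestPhaseDifference:
    def _ridge_pair(self, times, lag_h):
        a = wavelet.extract_ridge(
            wavelet.cwt_spectrum(
                DetrendedSignal(times=times, detrended=np.sin(2 * np.pi * times / 24))
            )
        )
        b = wavelet.extract_ridge(
            wavelet.cwt_spectrum(
                DetrendedSignal(
                    times=times, detrended=np.sin(2 * np.pi * (times - lag_h) / 24)
                )
            )
        )
        return a, b

    def test_identical_signals_have_zero_difference(self, times):
        a, b = self._ridge_pair(times, 0.0)
        pd_series = wavelet.phase_difference(a, b)
        assert abs(pd_series.circular_mean) < 0.05
        assert pd_series.circular_std < 0.05

    def test_eight_hour_lag_reads_two_pi_thirds(self, times):
        a, b = self._ridge_pair(times, 8.0)
        pd_series = wavelet.phase_difference(a, b)
        assert pd_series.circular_mean == pytest.approx(2 * np.pi / 3, abs=0.1)

    def test_antiphase_signals_read_pi(self, times):
        a, b = self._ridge_pair(times, 12.0)
        pd_series = wavelet.phase_difference(a, b)
        assert abs(pd_series.circular_mean) == pytest.approx(np.pi, abs=0.1)

    def test_phase_difference_is_antisymmetric(self, times):
        a, b = self._ridge_pair(times, 5.0)
        fwd = wavelet.phase_difference(a, b)
        rev = wavelet.phase_difference(b, a)
        assert fwd.circular_mean == pytest.approx(-rev.circular_mean, abs=1e-9)

    def test_insufficient_overlap_flagged(self, times):
        a, b = self._ridge_pair(times, 0.0)
        a.mask[:] = False
        a.mask[: int(20 / DT)] = True
        out = wavelet.phase_difference(a, b)
        assert out.excluded

    def test_histogram_is_probability_normalized(self, times):
        a, b = self._ridge_pair(times, 8.0)
        prob, edges = wavelet.phase_difference_histogram(wavelet.phase_difference(a, b))
        assert prob.sum() == pytest.approx(1.0)
        assert len(edges) == len(prob) + 1
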