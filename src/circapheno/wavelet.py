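"""Continuous wavelet transform, ridge extraction and phase differences.

A Morlet-based continuous wavelet transform resolves a recording's
oscillatory content in time and period simultaneously.  The *ridge* — the
per-time maximum of spectral power over the period grid — tracks the main
oscillatory component, giving time-resolved period, amplitude and phase.
Time points where ridge power falls below a detection threshold are
masked; the total unmasked duration ("ridge length") measures how long a
coherent oscillation was detectable and serves as a clock-strength
readout in its own right.  Two thresholding conventions are supported:
*adaptive* (a quarter of the signal's own maximal power — sensitive, for
period/phase readouts on amplitude-normalized signals) and *global* (a
quarter of the batch-median half-maximal power — comparable across
samples, for amplitude/ridge-length readouts on unnormalized signals).

Aggregating readouts across samples weights each sample by a logistic
function of its ridge length, so parameters estimated from long coherent
ridges dominate over parameters from short fragments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

from .exceptions import ConfigurationError
from .preprocess import DetrendedSignal

#: Morlet center frequency (dimensionless, conventional admissible value)
OMEGA0 = 6.0
#: |psi_hat(OMEGA0)| under L1 scale normalization; calibrates amplitude readout
_PEAK_RESPONSE = np.pi ** -0.25 * np.sqrt(2.0 * np.pi)

DEFAULT_PERIODS_H = np.arange(6.0, 40.0 + 1e-9, 0.1)
#: logistic steepness of the ridge-length weighting
WEIGHT_STEEPNESS = -0.1
MIN_RIDGE_H = 48.0


@dataclass
class WaveletSpectrum:
    times: np.ndarray
    periods: np.ndarray
    power: np.ndarray            # periods x times, variance-normalized |W|^2
    coefficients: np.ndarray     # complex W, periods x times
    normalized_input: bool = False
    sample_id: str = ""
    meta: dict = field(default_factory=dict)


@dataclass
class Ridge:
    times: np.ndarray
    period_t: np.ndarray
    amplitude_t: np.ndarray
    phase_t: np.ndarray
    power_t: np.ndarray
    mask: np.ndarray             # True where ridge power >= threshold
    threshold: float
    threshold_mode: str
    sample_id: str = ""

    @property
    def ridge_length_h(self) -> float:
        dt = self.times[1] - self.times[0]
        return float(self.mask.sum() * dt)


@dataclass
class RidgeSummary:
    sample_id: str
    ridge_length_h: float
    included: bool               # ridge >= MIN_RIDGE_H: period/amplitude/phase usable
    period_mean_h: float = np.nan
    period_median_h: float = np.nan
    period_cv: float = np.nan
    amplitude_mean: float = np.nan
    amplitude_median: float = np.nan
    amplitude_cv: float = np.nan


@dataclass
class PhaseDifferenceSeries:
    times: np.ndarray
    delta_phi: np.ndarray        # wrapped to (-pi, pi]
    circular_mean: float
    circular_std: float
    excluded: bool = False


def morlet_cwt(x: np.ndarray, dt_h: float, periods_h: np.ndarray) -> np.ndarray:
    """FFT-based analytic Morlet CWT on a period grid (L1 normalization).

    With this normalization a unit-amplitude sinusoid at an on-grid
    period yields |W| = _PEAK_RESPONSE / 2 at its ridge, so physical
    amplitude is recovered as 2|W| / _PEAK_RESPONSE.  The signal is
    mean-removed before the transform; the implicit zero extension
    attenuates amplitude readouts inside the cone of influence near the
    boundaries but leaves phase and period readouts clean.
    """
    x = np.asarray(x, float)
    n = len(x)
    pad = 0
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    xf = np.fft.fft(x - x.mean(), nfft)
    omega = 2.0 * np.pi * np.fft.fftfreq(nfft, dt_h)
    scales = OMEGA0 * np.asarray(periods_h) / (2.0 * np.pi)
    W = np.empty((len(scales), n), dtype=complex)
    for k, s in enumerate(scales):
        psi_hat = (
            np.pi ** -0.25 * np.sqrt(2.0 * np.pi)
            * np.exp(-0.5 * (s * omega - OMEGA0) ** 2)
            * (omega > 0)
        )
        W[k] = np.fft.ifft(xf * np.conj(psi_hat))[pad : pad + n]
    return W


def cwt_spectrum(
    d: DetrendedSignal,
    normalized: bool = False,
    periods_h: Optional[np.ndarray] = None,
) -> WaveletSpectrum:
    """Morlet wavelet power spectrum of a preprocessed signal.

    ``normalized=True`` analyzes the amplitude-normalized signal (input
    convention for period/phase readouts); ``False`` analyzes the plain
    detrended signal (amplitude / ridge-length readouts).  Power is
    |W|^2 normalized by the input variance.
    """
    periods_h = DEFAULT_PERIODS_H if periods_h is None else np.asarray(periods_h, float)
    if np.any(np.diff(periods_h) <= 0):
        raise ConfigurationError("period grid must be strictly increasing")
    if periods_h[-1] > d.span_h:
        raise ConfigurationError(
            f"max scan period {periods_h[-1]:.1f} h exceeds series span {d.span_h:.1f} h"
        )
    if normalized:
        if d.normalized is None:
            raise ConfigurationError("normalized spectrum requested but signal is not amplitude-normalized")
        x = d.normalized
    else:
        x = d.detrended
    W = morlet_cwt(x, d.dt_h, periods_h)
    var = np.var(x)
    power = np.abs(W) ** 2 / (var if var > 0 else 1.0)
    return WaveletSpectrum(
        times=d.times.copy(),
        periods=periods_h,
        power=power,
        coefficients=W,
        normalized_input=normalized,
        sample_id=d.sample_id,
        meta={"omega0": OMEGA0, "variance": var},
    )


def adaptive_threshold(spec: WaveletSpectrum) -> float:
    """Quarter of the signal's own maximal spectral power."""
    return float(spec.power.max()) / 4.0


def global_threshold(batch: Iterable[WaveletSpectrum]) -> float:
    """Quarter of the batch-median half-maximal spectral power."""
    maxima = np.array([s.power.max() for s in batch])
    if len(maxima) == 0:
        raise ConfigurationError("global threshold requires a non-empty batch")
    return float(np.median(maxima / 2.0)) / 4.0


def extract_ridge(
    spec: WaveletSpectrum,
    mode: str = "adaptive",
    batch: Optional[Sequence[WaveletSpectrum]] = None,
    threshold: Optional[float] = None,
) -> Ridge:
    """Trace the main oscillatory component and mask sub-threshold spans.

    The ridge is the per-time argmax of power over the period grid.
    Discontinuous (masked) stretches are allowed; ridge length counts
    only the above-threshold duration.  An all-masked ridge has length 0
    rather than raising.
    """
    if threshold is None:
        if mode == "adaptive":
            threshold = adaptive_threshold(spec)
        elif mode == "global":
            if batch is None:
                raise ConfigurationError("global mode requires the batch of spectra")
            threshold = global_threshold(batch)
        else:
            raise ConfigurationError("mode must be 'adaptive' or 'global'")
    idx = np.argmax(spec.power, axis=0)
    cols = np.arange(spec.power.shape[1])
    power_t = spec.power[idx, cols]
    coeff_t = spec.coefficients[idx, cols]
    return Ridge(
        times=spec.times.copy(),
        period_t=spec.periods[idx],
        amplitude_t=2.0 * np.abs(coeff_t) / _PEAK_RESPONSE,
        phase_t=np.angle(coeff_t),
        power_t=power_t,
        mask=power_t >= threshold,
        threshold=float(threshold),
        threshold_mode=mode,
        sample_id=spec.sample_id,
    )


def ridge_readouts(ridge: Ridge, min_ridge_h: float = MIN_RIDGE_H) -> RidgeSummary:
    """Per-sample period/amplitude summaries from the unmasked ridge.

    Samples whose ridge is detectable for less than ``min_ridge_h``
    (two full circadian cycles by default) are flagged excluded: their
    ridge length is still reported but period/amplitude/phase summaries
    are withheld as unreliable.
    """
    length = ridge.ridge_length_h
    summary = RidgeSummary(ridge.sample_id, length, included=length >= min_ridge_h)
    if not summary.included or not ridge.mask.any():
        return summary
    p = ridge.period_t[ridge.mask]
    a = ridge.amplitude_t[ridge.mask]
    summary.period_mean_h = float(p.mean())
    summary.period_median_h = float(np.median(p))
    summary.period_cv = float(p.std() / p.mean())
    summary.amplitude_mean = float(a.mean())
    summary.amplitude_median = float(np.median(a))
    summary.amplitude_cv = float(a.std() / a.mean()) if a.mean() > 0 else np.nan
    return summary


def ridge_weight(ridge_length_h, x0: float, steepness: float = WEIGHT_STEEPNESS):
    """Logistic relative weight of a sample by its ridge length.

    weight = 1 / (1 + exp(steepness * (length - x0))); with the fixed
    steepness of -0.1 the weight rises with ridge length and equals 0.5
    at the reflection point x0.
    """
    ridge_length_h = np.asarray(ridge_length_h, dtype=float)
    out = 1.0 / (1.0 + np.exp(steepness * (ridge_length_h - x0)))
    return float(out) if out.ndim == 0 else out


def batch_weighted_stats(
    values: Sequence[float],
    ridge_lengths_h: Sequence[float],
    x0: Optional[float] = None,
) -> Tuple[float, float]:
    """Ridge-length-weighted mean and median of a per-sample quantity.

    ``x0`` defaults to the midpoint of the batch's ridge-length range
    (the reflection point must lie between the extremes).
    """
    values = np.asarray(values, float)
    lengths = np.asarray(ridge_lengths_h, float)
    if len(values) != len(lengths) or len(values) == 0:
        raise ConfigurationError("values and ridge_lengths must be equal-length, non-empty")
    if x0 is None:
        x0 = 0.5 * (lengths.min() + lengths.max())
    w = ridge_weight(lengths, x0)
    w = np.atleast_1d(w)
    mean = float(np.sum(w * values) / np.sum(w))
    order = np.argsort(values)
    cw = np.cumsum(w[order]) / np.sum(w)
    median = float(np.interp(0.5, cw, values[order]))
    return mean, median


def phase_difference(
    r_a: Ridge,
    r_b: Ridge,
    min_overlap_h: float = MIN_RIDGE_H,
) -> PhaseDifferenceSeries:
    """Instantaneous phase difference between two reporters' ridges.

    delta_phi(t) = atan2(sin(phi_a - phi_b), cos(phi_a - phi_b)) on the
    common unmasked support; the circular mean locates the typical lag
    (2*pi corresponding to one circadian cycle) and the circular standard
    deviation quantifies phase-relationship stability over time.  With
    less than ``min_overlap_h`` of joint support the result is flagged
    excluded.
    """
    if len(r_a.times) != len(r_b.times) or not np.allclose(r_a.times, r_b.times):
        raise ConfigurationError("ridges must share one time grid")
    both = r_a.mask & r_b.mask
    dt = r_a.times[1] - r_a.times[0]
    raw = r_a.phase_t - r_b.phase_t
    delta = np.arctan2(np.sin(raw), np.cos(raw))
    if both.sum() * dt < min_overlap_h:
        return PhaseDifferenceSeries(r_a.times[both], delta[both], np.nan, np.nan, excluded=True)
    z = np.exp(1j * delta[both]).mean()
    circ_mean = float(np.angle(z))
    resultant = min(abs(z), 1.0)
    circ_std = float(np.sqrt(-2.0 * np.log(resultant))) if resultant > 0 else np.inf
    return PhaseDifferenceSeries(r_a.times[both], delta[both], circ_mean, circ_std)


def phase_difference_histogram(
    series: PhaseDifferenceSeries, n_bins: int = 24
) -> Tuple[np.ndarray, np.ndarray]:
    """Probability-normalized histogram of delta_phi over (-pi, pi]."""
    counts, edges = np.histogram(series.delta_phi, bins=n_bins, range=(-np.pi, np.pi))
    total = counts.sum()
    prob = counts / total if total > 0 else counts.astype(float)
    return prob, edges
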