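"""Synthetic data generation with known ground truth.

The centerpiece is a population of mean-field coupled Poincaré
oscillators: each cell is a planar limit-cycle oscillator with natural
radius R0, radial relaxation rate lambda and inherent period T_i (drawn
from Norm(24, 3) hours); all oscillators feel the population mean of the
X and Y coordinates scaled by the coupling strength kappa.  Strong
coupling keeps the heterogeneous ensemble synchronized and the summed
signal self-sustained; weak coupling lets the oscillators dephase, so the
population-level signal damps out even though every single cell keeps
oscillating.  This dephasing mechanism is what the amplitude-decay
analysis (see :mod:`circapheno.decay`) inverts to estimate kappa from
recordings.

The remaining generators produce the surrounding study inputs: noisy
luminescence recordings (oscillation + trend + initial transient spike +
Gaussian noise), feature tables with four planted circadian phenotype
archetypes, and dose-response growth-curve families generated from known
GR (growth-rate-inhibition) parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, NumericalInstabilityError
from .preprocess import TimeSeries


@dataclass
class SimulationConfig:
    """Parameters of the coupled Poincaré-oscillator population.

    One Euler step corresponds to ``dt`` hours; an oscillator with
    inherent period ``T_i = 24`` completes one cycle in 24 h.
    """

    n_oscillators: int = 300
    coupling_strength: float = 0.1
    mean_period_h: float = 24.0
    period_sd_h: float = 3.0
    natural_radius: float = 1.0
    relaxation: float = 1.0
    dt: float = 0.1
    duration_steps: int = 1380
    phase_init_max: float = math.pi / 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_oscillators < 1:
            raise ConfigurationError("n_oscillators must be >= 1")
        if self.coupling_strength < 0:
            raise ConfigurationError("coupling_strength must be >= 0")
        if self.dt <= 0:
            raise ConfigurationError("dt must be > 0")
        if self.period_sd_h < 0:
            raise ConfigurationError("period_sd_h must be >= 0")
        if self.duration_steps < 2:
            raise ConfigurationError("duration_steps must be >= 2")

    def draw_periods(self, rng: Optional[np.random.Generator] = None) -> np.ndarray:
        """Inherent periods T_i ~ Norm(mean_period_h, period_sd_h)."""
        rng = rng if rng is not None else np.random.default_rng(self.seed)
        return rng.normal(self.mean_period_h, self.period_sd_h, self.n_oscillators)


@dataclass
class PopulationSignal:
    """Mean-field output of a simulated oscillator population.

    ``mean_field`` follows the summed-output convention
    0.5 * (kappa / 2N) * sum_i Y_i and is therefore identically zero for
    an uncoupled population; ``ensemble_mean`` (0.5 * mean(Y)) carries the
    population signal independent of kappa and is the quantity the
    uncoupled dephasing limit is stated on.
    """

    times: np.ndarray
    mean_field: np.ndarray
    ensemble_mean: np.ndarray
    periods: np.ndarray
    config: SimulationConfig
    states: Optional[Tuple[np.ndarray, np.ndarray]] = None  # (X, Y) step x oscillator

    def __len__(self) -> int:
        return len(self.times)


def simulate_population(config: SimulationConfig, keep_states: bool = False) -> PopulationSignal:
    """Euler-integrate the coupled Poincaré population.

    Per step, each oscillator is updated with the radial relaxation toward
    the natural radius, its own angular rotation 2*pi/T_i, and the
    mean-field coupling term (kappa / 2N) * sum of X (resp. Y) over the
    ensemble.  Initial phases are drawn Uniform(0, phase_init_max) on the
    natural circle, emulating a resetting stimulus.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    periods = cfg.draw_periods(rng)
    theta = rng.uniform(0.0, cfg.phase_init_max, cfg.n_oscillators)
    X = cfg.natural_radius * np.cos(theta)
    Y = cfg.natural_radius * np.sin(theta)
    omega = 2.0 * np.pi / periods
    half_kappa = cfg.coupling_strength / 2.0  # (kappa/2N) * sum == (kappa/2) * mean

    n = cfg.duration_steps
    mean_field = np.empty(n)
    ensemble_mean = np.empty(n)
    states = (np.empty((n, cfg.n_oscillators)), np.empty((n, cfg.n_oscillators))) if keep_states else None

    for step in range(n):
        mx, my = X.mean(), Y.mean()
        mean_field[step] = 0.5 * half_kappa * my
        ensemble_mean[step] = 0.5 * my
        if states is not None:
            states[0][step] = X
            states[1][step] = Y
        r = np.hypot(X, Y)
        dX = cfg.relaxation * (cfg.natural_radius - r) * X - omega * Y + half_kappa * mx
        dY = cfg.relaxation * (cfg.natural_radius - r) * Y + omega * X + half_kappa * my
        X = X + cfg.dt * dX
        Y = Y + cfg.dt * dY
        if not (np.isfinite(X).all() and np.isfinite(Y).all()):
            raise NumericalInstabilityError(
                f"Euler integration diverged at step {step + 1} (dt={cfg.dt})"
            )

    times = np.arange(n) * cfg.dt
    return PopulationSignal(times, mean_field, ensemble_mean, periods, cfg, states)


@dataclass
class SyntheticRecordingSpec:
    """Recipe for a synthetic luminescence recording.

    ``base`` is either a :class:`PopulationSignal` (its ``ensemble_mean``
    is used so uncoupled populations still emit signal) or a closed-form
    damped sinusoid given by ``(A0, gamma_per_h, period_h, phase_rad)``.
    The rendered trace adds a polynomial trend, an initial transient spike
    (emulating the synchronization-stimulus peak that pre-processing
    removes) and additive Gaussian noise, then resamples to the recording
    grid.
    """

    base: Union[PopulationSignal, Tuple[float, float, float, float]]
    duration_h: float = 137.7
    sampling_interval_min: float = 10.0
    trend_coeffs: Sequence[float] = (0.0,)  # polynomial in t (hours), low order first
    spike_magnitude: float = 0.0
    spike_span_h: float = 5.0
    noise_sd: float = 0.0
    seed: int = 0
    sample_id: str = "synthetic"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sampling_interval_min <= 0:
            raise ConfigurationError("sampling_interval_min must be > 0")
        if self.spike_span_h < 0:
            raise ConfigurationError("spike_span_h must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


def render_recording(spec: SyntheticRecordingSpec) -> TimeSeries:
    """Render a noisy recording from a base oscillation.

    The generating parameters are stored in ``meta['ground_truth']`` so
    every downstream estimator can be checked against them.
    """
    dt_h = spec.sampling_interval_min / 60.0
    times = np.arange(0.0, spec.duration_h + dt_h / 2, dt_h)
    if isinstance(spec.base, PopulationSignal):
        base_sig = spec.base
        if len(base_sig) == 0:
            raise ConfigurationError("empty base signal")
        if times[-1] > base_sig.times[-1] + 1e-9:
            times = times[times <= base_sig.times[-1] + 1e-9]
        values = np.interp(times, base_sig.times, base_sig.ensemble_mean)
        truth: Dict[str, object] = {"kind": "population", "config": base_sig.config}
    else:
        a0, gamma, period, phase = spec.base
        values = a0 * np.exp(-gamma * times) * np.sin(2 * np.pi / period * times + phase)
        truth = {"kind": "damped_sinusoid", "A0": a0, "gamma": gamma,
                 "period_h": period, "phase": phase}
    if len(times) < 2:
        raise ConfigurationError("rendered recording would be empty")

    trend = np.polynomial.polynomial.polyval(times, np.asarray(spec.trend_coeffs, float))
    spike = np.zeros_like(times)
    if spec.spike_magnitude and spec.spike_span_h > 0:
        in_span = times < spec.spike_span_h
        # half-cosine pulse: maximal at t=0, zero at the end of the span
        spike[in_span] = spec.spike_magnitude * 0.5 * (
            1 + np.cos(np.pi * times[in_span] / spec.spike_span_h)
        )
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd, len(times)) if spec.noise_sd > 0 else 0.0

    truth.update(
        trend_coeffs=tuple(spec.trend_coeffs),
        spike_magnitude=spec.spike_magnitude,
        spike_span_h=spec.spike_span_h,
        noise_sd=spec.noise_sd,
        seed=spec.seed,
    )
    meta = dict(spec.meta)
    meta["ground_truth"] = truth
    return TimeSeries(times, values + trend + spike + noise, spec.sample_id, meta)


#: archetype centroids for (period_h, phase_diff_var_rad, circadian_band_pct)
PHENOTYPE_ARCHETYPES: Dict[str, Tuple[float, float, float]] = {
    "functional": (24.0, 0.30, 65.0),
    "weak": (25.0, 0.50, 20.0),
    "unstable": (26.0, 1.60, 40.0),
    "dysfunctional": (30.0, 1.40, 12.0),
}

#: per-feature Gaussian jitter applied around the centroids
PHENOTYPE_JITTER: Tuple[float, float, float] = (0.5, 0.12, 4.0)


def generate_phenotype_table(
    n_per_class: int,
    seed: int = 0,
    jitter: Optional[Sequence[float]] = None,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Feature table with four planted circadian phenotype archetypes.

    Returns ``(features, labels)``: features are the three clustering
    parameters (period, phase-difference variability, circadian band
    fraction) drawn around the archetype centroids with Gaussian jitter.
    """
    if n_per_class < 1:
        raise ConfigurationError("n_per_class must be >= 1")
    jit = np.asarray(PHENOTYPE_JITTER if jitter is None else jitter, float)
    rng = np.random.default_rng(seed)
    rows, labels, index = [], [], []
    for name, centroid in PHENOTYPE_ARCHETYPES.items():
        for i in range(n_per_class):
            rows.append(np.asarray(centroid) + rng.normal(0.0, 1.0, 3) * jit)
            labels.append(name)
            index.append(f"{name}_{i}")
    features = pd.DataFrame(
        rows, index=index, columns=["period_h", "phase_diff_var", "circadian_band_pct"]
    )
    return features, pd.Series(labels, index=index, name="phenotype")


def gr_sigmoid(c: np.ndarray, gr_inf: float, gec50: float, h_gr: float) -> np.ndarray:
    """Sigmoidal GR dose-response: GR(c) = GR_inf + (1-GR_inf)/(1+(c/GEC50)^h)."""
    c = np.asarray(c, dtype=float)
    return gr_inf + (1.0 - gr_inf) / (1.0 + (c / gec50) ** h_gr)


def generate_dose_response(
    gr_params: Dict[str, float],
    concentrations: Sequence[float],
    k0: float,
    seed: int = 0,
    duration_h: float = 96.0,
    interval_h: float = 2.0,
    y0: float = 100.0,
    noise_sd_frac: float = 0.02,
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Dose-labelled growth curves generated from known GR parameters.

    For each concentration the growth rate is k(c) = k(0) * log2(GR(c)+1)
    (the inverse of the GR definition), and an exponential count
    trajectory with multiplicative Gaussian noise is emitted.  A
    drug-free control (concentration 0) is always included.
    """
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ConfigurationError("concentrations must be positive")
    if np.any(np.diff(conc) <= 0):
        raise ConfigurationError("concentrations must be sorted increasing")
    gr_inf = gr_params["GR_inf"]
    if not -1.0 <= gr_inf <= 1.0:
        raise ConfigurationError("GR_inf must lie in [-1, 1]")
    gr_c = gr_sigmoid(conc, gr_inf, gr_params["GEC50"], gr_params["h_GR"])
    if np.any(gr_c + 1.0 <= 0.0):
        raise ConfigurationError("GR(c)+1 <= 0 requested: growth rate undefined")

    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_h + interval_h / 2, interval_h)
    records = []
    for c, gr in [(0.0, 1.0)] + list(zip(conc, gr_c)):
        k_c = k0 * math.log2(gr + 1.0)
        counts = y0 * np.exp(k_c * times)
        if noise_sd_frac > 0:
            counts = counts * (1.0 + rng.normal(0.0, noise_sd_frac, len(times)))
        for t, y in zip(times, counts):
            records.append((t, c, y))
    curves = pd.DataFrame(records, columns=["time_h", "conc_uM", "count"])
    truth = dict(gr_params)
    truth.update(k0=k0, y0=y0, noise_sd_frac=noise_sd_frac, seed=seed)
    return curves, truth


def write_recording_csv(path, recordings: Sequence[TimeSeries]) -> None:
    """Write recordings as CSV with header ``time_h, <sample_id>...``."""
    times = recordings[0].times
    data = {"time_h": times}
    for rec in recordings:
        if len(rec) != len(times) or not np.allclose(rec.times, times):
            raise ConfigurationError("all recordings must share one time grid")
        data[rec.sample_id] = rec.values
    pd.DataFrame(data).to_csv(path, index=False)


def read_recording_csv(path) -> list[TimeSeries]:
    """Read recordings from a ``time_h, <sample_id>...`` CSV."""
    df = pd.read_csv(path)
    times = df["time_h"].to_numpy(float)
    return [
        TimeSeries(times, df[col].to_numpy(float), sample_id=str(col))
        for col in df.columns
        if col != "time_h"
    ]
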