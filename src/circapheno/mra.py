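"""Multiresolution (wavelet-detail) decomposition into frequency bands.

An undecimated (stationary/MODWT-style) discrete wavelet transform with a
db20 Daubechies wavelet splits the detrended signal into dyadic details
D_j, each covering periods between 2^j * dt and 2^(j+1) * dt.  At the
30-min working resolution the details map onto interpretable bands:
noise (1-4 h, D1-D2), ultradian (4-16 h, D3-D4), circadian (16-32 h, D5)
and infradian (32-256 h, D6-D8).  Band fractions — the share of signal
variance carried by each band — summarize how much of a recording is
genuinely circadian versus fast noise or slow drift.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict

import numpy as np
import pywt

from .exceptions import ConfigurationError, TooShortError
from .preprocess import DetrendedSignal

BANDS: Dict[str, tuple] = {
    "noise": (1, 2),       # 1-4 h
    "ultradian": (3, 4),   # 4-16 h
    "circadian": (5, 5),   # 16-32 h
    "infradian": (6, 8),   # 32-256 h
}

TARGET_DT_H = 0.5
_LEVEL = 8
_WAVELET = "db20"


def band_edges_h(level: int, dt_h: float = TARGET_DT_H) -> tuple:
    """Period span (hours) covered by detail level ``level`` at ``dt_h``."""
    return (2**level * dt_h, 2 ** (level + 1) * dt_h)


@dataclass
class MRADecomposition:
    times: np.ndarray
    details: Dict[int, np.ndarray]  # level -> reconstructed detail series
    smooth: np.ndarray
    band_fractions: Dict[str, float]  # percent of input variance
    dt_h: float = TARGET_DT_H
    norm: str = "variance"


def resample(d: DetrendedSignal, target_dt_min: float = 30.0) -> DetrendedSignal:
    """Decimate a detrended signal onto the MRA working grid (30 min)."""
    target_dt_h = target_dt_min / 60.0
    ratio = target_dt_h / d.dt_h
    if abs(ratio - round(ratio)) > 1e-6:
        raise ConfigurationError(
            f"source interval {d.dt_h * 60:.1f} min does not divide target {target_dt_min:.1f} min"
        )
    step = int(round(ratio))
    if step == 1:
        return d
    return replace(
        d,
        times=d.times[::step],
        detrended=d.detrended[::step],
        trend=None if d.trend is None else d.trend[::step],
        normalized=None if d.normalized is None else d.normalized[::step],
        envelope=None if d.envelope is None else d.envelope[::step],
    )


def decompose(d: DetrendedSignal, norm: str = "variance") -> MRADecomposition:
    """Undecimated db20 wavelet decomposition with band accounting.

    ``norm`` selects the band-fraction definition: ``"variance"`` (share
    of variance, default) or ``"amplitude"`` (share of mean absolute
    deviation).  Reflection (odd) padding extends the series to the
    dyadic length the stationary transform requires.
    """
    if abs(d.dt_h - TARGET_DT_H) > 1e-6:
        raise ConfigurationError("decompose expects 30-min sampling; call resample first")
    if norm not in ("variance", "amplitude"):
        raise ConfigurationError("norm must be 'variance' or 'amplitude'")
    x = d.detrended
    n = len(x)
    if n < 96:
        raise TooShortError("series too short for the circadian detail level (need >= 96 points)")
    block = 1 << _LEVEL
    npad = (-n) % block
    xp = np.pad(x, (0, npad), mode="reflect", reflect_type="odd") if npad else x
    components = pywt.mra(xp, _WAVELET, level=_LEVEL, transform="swt")
    # pywt.mra returns [smooth, D_J, D_{J-1}, ..., D_1]; sum reconstructs input
    smooth = components[0][:n]
    details = {
        level: components[_LEVEL - level + 1][:n] for level in range(1, _LEVEL + 1)
    }

    def _measure(series: np.ndarray) -> float:
        return float(np.var(series)) if norm == "variance" else float(np.mean(np.abs(series)))

    total = _measure(x)
    fractions = {}
    for name, (lo, hi) in BANDS.items():
        band_sum = np.sum([details[j] for j in range(lo, hi + 1)], axis=0)
        fractions[name] = 100.0 * _measure(band_sum) / total if total > 0 else 0.0
    return MRADecomposition(
        times=d.times.copy(),
        details=details,
        smooth=smooth,
        band_fractions=fractions,
        dt_h=d.dt_h,
        norm=norm,
    )
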