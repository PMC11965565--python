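"""Growth-curve smoothing, exponential growth rates and GR drug-response metrics.

Drug sensitivity is quantified in the growth-rate-inhibition (GR)
framework, which normalizes the treated growth rate k(c) to the
untreated rate k(0):

    GR(c) = 2^(k(c)/k(0)) - 1

so GR = 1 means no effect, GR = 0 complete cytostasis and GR < 0 net
cell loss (cytotoxicity); unlike endpoint viability ratios it is robust
to differences in division rate between cell lines.  Dose-dependent GR
values are fitted with a three-parameter sigmoid (GR_inf, GEC50, h_GR),
from which the derived potency GR50 (concentration where GR crosses 0.5)
and the overall-effect summary GR_AOC (area over the fitted curve versus
the GR = 1 baseline, averaged over the tested log-concentration range)
follow in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import ConfigurationError
from .simulate import gr_sigmoid


@dataclass
class GrowthCurve:
    times: np.ndarray
    counts: np.ndarray
    smoothed: Optional[np.ndarray] = None
    sample_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.counts = np.asarray(self.counts, float)
        if np.any(self.counts < 0):
            raise ConfigurationError("counts must be non-negative")

    @property
    def y0(self) -> float:
        src = self.smoothed if self.smoothed is not None else self.counts
        return float(src[0])


@dataclass
class GrowthRateFit:
    k: float                      # per hour
    y0: float
    r_squared: float
    saturating: bool = False      # late-window slope < half the early-window slope


@dataclass
class GRFit:
    GR_inf: float
    GEC50: float
    h_GR: float
    GR50: float                   # may be +inf when GR never crosses 0.5
    GR_AOC: float
    per_dose_GR: Dict[float, float]
    fit_ok: bool = True
    message: str = ""


def rloess(x: np.ndarray, y: np.ndarray, span_frac: float = 0.1, robust_iters: int = 4) -> np.ndarray:
    """Robust local quadratic regression (tricube + bisquare weights).

    Local least squares with a 2nd-degree polynomial over a span of the
    nearest ``span_frac`` fraction of points, iteratively reweighted with
    bisquare robustness weights (6x median absolute residual scale), so
    isolated outliers barely perturb the smooth.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    k = max(int(math.ceil(span_frac * n)), 8)
    k = min(k, n)
    robust_w = np.ones(n)
    fitted = y.copy()
    for _ in range(robust_iters + 1):
        out = np.empty(n)
        for i in range(n):
            dist = np.abs(x - x[i])
            idx = np.argpartition(dist, k - 1)[:k]
            h = dist[idx].max()
            tw = (1 - np.clip(dist[idx] / (h if h > 0 else 1.0), 0, 1) ** 3) ** 3
            w = tw * robust_w[idx]
            good = w > 1e-12
            if good.sum() < 3:
                # too few effective points for a quadratic: robust fallback
                out[i] = np.median(y[idx])
                continue
            xi = x[idx][good] - x[i]
            sw = np.sqrt(w[good])
            design = np.column_stack([np.ones_like(xi), xi, xi * xi])
            coeffs, *_ = np.linalg.lstsq(design * sw[:, None], y[idx][good] * sw, rcond=None)
            out[i] = coeffs[0]
        fitted = out
        # robustify on relative residuals: count data carries
        # magnitude-proportional noise, so absolute residuals would
        # zero-weight the large-count tail of a clean exponential
        scale = np.maximum(np.abs(fitted), 1e-12 * (np.abs(y).max() + 1e-300))
        resid = (y - fitted) / scale
        if np.max(np.abs(resid)) < 1e-6:
            break
        # floored scale: relative residuals below ~0.1% are measurement-
        # insignificant and must not drive the bisquare weights to zero
        s = max(np.median(np.abs(resid)), 1e-3)
        robust_w = np.clip(1 - (resid / (6.0 * s)) ** 2, 0, None) ** 2
    return fitted


def smooth_growth(g: GrowthCurve, span_frac: float = 0.1) -> GrowthCurve:
    """Smooth a growth curve with robust local quadratic regression."""
    if len(g.times) < 10:
        raise ConfigurationError("growth smoothing needs at least 10 points")
    smoothed = np.clip(rloess(g.times, g.counts, span_frac), 0.0, None)
    return GrowthCurve(g.times, g.counts, smoothed, g.sample_id, dict(g.meta))


def fit_growth_rate(g: GrowthCurve) -> GrowthRateFit:
    """Exponential growth rate k (per hour) from a (smoothed) curve.

    Counts are normalized to their initial value y0 and fitted with
    y0*exp(k*t).  A saturation flag is raised when the late-window
    log-slope drops below half the early-window log-slope, signalling
    that the exponential model underestimates the early-phase rate.
    """
    y = g.smoothed if g.smoothed is not None else g.counts
    t = g.times - g.times[0]
    y0 = float(y[0])
    if y0 <= 0:
        raise ConfigurationError("initial value y0 must be positive")
    z = y / y0

    def model(t, k):
        return np.exp(k * t)

    k0_guess = np.polyfit(t[z > 0], np.log(z[z > 0]), 1)[0] if np.all(z > 0) else 0.01
    popt, _ = curve_fit(model, t, z, p0=[k0_guess], maxfev=10000)
    k = float(popt[0])
    resid = z - model(t, k)
    var = np.var(z)
    r2 = 1.0 - np.var(resid) / var if var > 0 else 1.0

    saturating = False
    half = len(t) // 2
    if half >= 3 and np.all(z > 0):
        early = np.polyfit(t[:half], np.log(z[:half]), 1)[0]
        late = np.polyfit(t[half:], np.log(z[half:]), 1)[0]
        if early > 0 and late < 0.5 * early:
            saturating = True
    return GrowthRateFit(k=k, y0=y0, r_squared=float(r2), saturating=saturating)


def gr_value(k_c, k_0: float):
    """Growth-rate inhibition GR = 2^(k_c/k_0) - 1 (k_0 must be positive)."""
    if k_0 <= 0:
        raise ConfigurationError("control growth rate k_0 must be positive")
    return 2.0 ** (np.asarray(k_c, float) / k_0) - 1.0


def gr50_from_params(gr_inf: float, gec50: float, h_gr: float) -> float:
    """Concentration where the fitted sigmoid crosses GR = 0.5 (+inf if never)."""
    if gr_inf >= 0.5:
        return math.inf
    return gec50 * (0.5 / (0.5 - gr_inf)) ** (1.0 / h_gr)


def gr_aoc(gr_inf: float, gec50: float, h_gr: float, c_min: float, c_max: float) -> float:
    """Area over the fitted GR curve vs the GR=1 baseline, mean over log10 dose."""
    grid = np.logspace(np.log10(c_min), np.log10(c_max), 256)
    return float(1.0 - np.mean(gr_sigmoid(grid, gr_inf, gec50, h_gr)))


def fit_gr_curve(
    per_dose_gr: Dict[float, float],
    concentrations: Optional[Sequence[float]] = None,
) -> GRFit:
    """Fit the GR sigmoid to per-dose GR values and derive GR50 / GR_AOC.

    Bounds: GR_inf in [-1, 1], h_GR in (0.1, 10], GEC50 within
    [min dose / 10, max dose * 10].  A flat response (GR range < 0.1) is
    not fitted: ``fit_ok=False`` with GR_inf set to the mean GR.
    """
    if concentrations is None:
        concentrations = sorted(per_dose_gr)
    conc = np.asarray(concentrations, float)
    if len(conc) < 5:
        raise ConfigurationError("GR sigmoid fit needs at least 5 doses")
    gr = np.array([per_dose_gr[c] for c in conc], float)

    if np.ptp(gr) < 0.1:
        mean_gr = float(gr.mean())
        return GRFit(
            GR_inf=mean_gr, GEC50=np.nan, h_GR=np.nan, GR50=math.inf,
            GR_AOC=float(1.0 - mean_gr), per_dose_GR=dict(zip(conc, gr)),
            fit_ok=False, message="flat response: GR range < 0.1",
        )

    lo = [-1.0, conc.min() / 10.0, 0.1]
    hi = [1.0, conc.max() * 10.0, 10.0]
    p0 = [float(np.clip(gr[-1], -1, 1)), float(np.median(conc)), 1.0]
    popt, _ = curve_fit(
        lambda c, gi, ge, h: gr_sigmoid(c, gi, ge, h),
        conc, gr, p0=p0, bounds=(lo, hi), maxfev=20000,
    )
    gi, ge, h = map(float, popt)
    return GRFit(
        GR_inf=gi, GEC50=ge, h_GR=h,
        GR50=gr50_from_params(gi, ge, h),
        GR_AOC=gr_aoc(gi, ge, h, conc.min(), conc.max()),
        per_dose_GR=dict(zip(conc, gr)),
    )


def per_dose_gr_from_curves(
    dose_curves: Dict[float, GrowthCurve],
    control: GrowthCurve,
    span_frac: float = 0.1,
) -> Dict[float, float]:
    """Per-dose GR values from dose-labelled growth curves.

    Each trajectory (and the drug-free control) is smoothed and fitted
    with the exponential model over its full span; GR follows from the
    treated/control rate ratio.
    """
    k0 = fit_growth_rate(smooth_growth(control, span_frac)).k
    out = {}
    for c, curve in dose_curves.items():
        k_c = fit_growth_rate(smooth_growth(curve, span_frac)).k
        out[float(c)] = float(gr_value(k_c, k0))
    return out
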