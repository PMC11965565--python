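# Methods

This note records the models, estimators, numerical choices and known
limitations behind `circapheno`, in the order data flows through the
pipeline.

## Oscillator-population model

A cell population is modelled as N mean-field-coupled Poincaré
oscillators in Cartesian coordinates. Each oscillator carries a planar
limit cycle of natural radius R₀ with radial relaxation rate λ and
angular velocity 2π/T_i; all oscillators additionally feel the
population means of X and Y scaled by κ/2. The update is explicit Euler
with step Δt (default 0.1 h):

    X ← X + Δt·[ λ(R₀ − r)X − (2π/T_i)Y + (κ/2N)ΣX ]
    Y ← Y + Δt·[ λ(R₀ − r)Y + (2π/T_i)X + (κ/2N)ΣY ]

with r = √(X²+Y²). The radial term is written in its attracting form
λ(R₀ − r): λ is the correction strength *toward* the natural radius, and
the attracting sign is required for the limit cycle to be stable under
Euler integration. Defaults emulate a dexamethasone-reset culture:
N = 300, T_i ~ Norm(24, 3) h, initial phases Uniform(0, π/5) on the
natural circle, R₀ = λ = 1, 1380 steps (138 h). A NaN during integration
raises a numerical-instability error naming the offending step.

Two population signals are exposed. `mean_field` follows the summed-
output convention 0.5·(κ/2N)·ΣY, whose κ prefactor makes amplitude grow
with coupling — this is the signal the (A₀, γ) reference curve is built
from. Because it is identically zero at κ = 0, `ensemble_mean`
(0.5·mean Y) is provided alongside; it carries the dephasing-limit
behaviour (uncoupled heterogeneous populations damp, uncoupled identical
ones do not) and is the base signal for rendered recordings. The 0.5
amplitude factor is retained as a fixed output scale.

Mechanistically, population-level damping here is *dephasing*: every
single oscillator keeps cycling, but with σ_T = 3 h the ensemble phases
spread at ~2πσ_T/T̄² ≈ 0.033 rad/h, so the uncoupled summed signal loses
its envelope within a few days, while κ ≳ 0.05 holds the ensemble
synchronized. Spatial structure, per-cell coupling heterogeneity and
stochastic (Langevin) forcing are out of scope.

## Synthetic recordings and the other generators

`render_recording` layers what a raw luminescence trace contains on top
of a base oscillation (population signal or closed-form damped
sinusoid): a polynomial trend, an initial half-cosine transient spike
(default 5 h, emulating the synchronization-stimulus peak), and additive
Gaussian noise, sampled at 10 min. Generating parameters are stored in
the output metadata so every estimator can be checked against truth.
What these recordings do *not* emulate: multiplicative/shot noise,
photobleaching nonlinearity, culture-medium exhaustion beyond a smooth
trend, or replicate-to-replicate batch effects — so green tests certify
the estimators on the stated signal model, not on every artifact real
recordings can carry.

The phenotype-table generator plants four archetypes on the three
clustering features (period h, phase-difference variability rad,
circadian band %): functional (24, 0.30, 65), weak (25, 0.50, 20),
unstable (26, 1.60, 40), dysfunctional (30, 1.40, 12), with Gaussian
jitter (0.5 h, 0.12 rad, 4 points) — centred on the qualitative
definitions of the four classes, with jitter small enough that the
classes remain distinct but overlap at the margins. The dose–response
generator inverts the GR definition, k(c) = k(0)·log₂(GR(c)+1), and
emits exponential count trajectories with 2 % multiplicative noise by
default.

## Pre-processing

Recordings are trimmed (first 5 h removed; span capped at 137.7 h, with
per-sample overrides for recordings that need extra tail truncation) and
detrended with a zero-phase windowed-sinc FIR low-pass at a 48-h cutoff
period (Blackman window, 8 cutoff-periods of taps). A least-squares line
is removed before filtering and restored after; the residual is padded
by odd-symmetric reflection, which continues value and slope smoothly.
Verified post-conditions: a 24-h tone rides through a linear drift with
correlation > 0.99 to the pure tone, a 96-h oscillation is removed to
< 3 % residual, a constant detrends to ~0, and re-detrending changes the
signal by < 1 % RMS. Within roughly half a cutoff period of the edges a
bias on the order of the boundary oscillation-to-mean offset remains, as
for any finite-span low-pass; consequently decay fitting for coupling
inference operates on raw simulated signals, not detrended ones, and
wavelet amplitude readouts are most accurate ≳ 2 scale-widths from the
boundaries. Residual DC after filtering is assigned to the trend.

Amplitude normalization divides the detrended signal by its continuous
envelope — the magnitude of the analytic (Hilbert) signal, smoothed with
a 48-h sliding mean. Any envelope value below machine tolerance raises a
division-guard error rather than emitting infinities.

## Autocorrelation

The sample ACF uses the adjusted (unbiased) normalization, clipped to
[−1, 1]: the biased estimator's (1 − τ/n) factor would cap the lag-24 h
value of a pure sinusoid at ~0.82 for a 133-h recording and distort the
index's interpretation as rhythm strength. The second peak is detected
on a Gaussian-smoothed copy (σ = 2 h, configurable; ties toward the
smaller lag), but the reported index is the *raw* ACF at the detected
lag — smoothing a 24-h cosine peak with σ = 2 h attenuates it by ~13 %,
which would bias every index downward. Peaks ≤ 0 or inside the ±2/√n
(~95.4 %) band mark the sample non-significant; this is a flag, not an
exception, and such samples are excluded from period summaries
downstream. The analytic oracle for a damped sinusoid includes the
finite-window factor [L/(L−τ)]·(1−e^(−2γ(L−τ)))/(1−e^(−2γL)), which the
tests verify to 0.05.

## Multiresolution analysis

Signals are decimated to Δt = 30 min (pure decimation; the detrended
input has no appreciable super-Nyquist content) and decomposed with an
undecimated (stationary, translation-invariant) db20 wavelet transform
to level 8, padded to dyadic length by odd reflection. Detail D_j spans
periods 2^j·Δt to 2^(j+1)·Δt, so D1–D2 = noise (1–4 h), D3–D4 =
ultradian (4–16 h), D5 = circadian (16–32 h), D6–D8 = infradian
(32–256 h). Band fractions are variance shares of the summed in-band
details (an amplitude-based variant — mean-absolute shares — is
switchable); variance was chosen for its energy interpretation. The
undecimated transform is redundant rather than orthogonal: band
variances plus smooth recover total variance only to within ~5–10 %,
which the energy-accounting test acknowledges; the decimated orthogonal
alternative cannot reach level 8 on a 276-point series with a 40-tap
filter.

## Continuous wavelet transform

The CWT is an analytic Morlet (ω₀ = 6) evaluated by FFT on a period grid
(default 6–40 h × 0.1 h), L1 scale normalization, mean removed, zero
extension. The normalization is calibrated so a unit sinusoid reads
amplitude 1.0 at its ridge (within 1 % mid-span; the zero extension
attenuates amplitudes inside the boundary cone of influence, ~2 scale
widths). Power is |W|² over input variance. Period/phase readouts come
from amplitude-normalized inputs with the *adaptive* threshold
(max power/4 per signal); amplitude/ridge-length readouts from
unnormalized inputs with the *global* threshold (median over the
analysis batch of half-maximal powers, divided by 4 — the batch defaults
to the whole analysis run). The ridge is the per-time power argmax;
below-threshold spans are masked but do not break the ridge's identity,
and ridge length is the total unmasked duration. Ridges shorter than
48 h (two circadian cycles) are excluded from period/amplitude/phase
summaries; ridge length itself is always reported. Cross-sample
aggregation weights samples by the logistic 1/(1+e^(−0.1(L−x₀))) with x₀
defaulting to the midpoint of the batch's ridge-length range. Phase
differences use atan2 wrapping; their dispersion statistic is the
circular standard deviation √(−2 ln R) — a coefficient of variation is
meaningless for angles. Chirp tracking is accurate to ~0.2 h on average
(≤ ~1 h pointwise) for sweep rates around 0.05 h/h; synchrosqueezing and
multi-ridge tracking are out of scope.

## Decay fitting and coupling inversion

Nonlinear least squares (trust-region, initial guesses A₀ = max|signal|,
γ from the log-envelope slope, T_s = 24 h, φ = 0) fits either the plain
exponential envelope model or the damped sinusoid. Fits with R² < 0.6
are rejected — a flag, not an exception; rejected fits cannot enter
coupling estimation. The reference curve simulates the population over a
log-spaced κ grid (default 25 points in [10⁻⁵, 0.1], constant seed so
all grid points share one period draw) and must consist entirely of
accepted fits. Inversion is nearest-neighbour in z-scored
(log A₀, log γ) space with γ floored at 10⁻⁶ before the log; endpoint
matches are flagged as boundary estimates. The numeric inversion is this
package's formalization of an otherwise graphical comparison; closed-loop
tests (simulate with a different seed → fit → invert) recover κ within
one grid step for > 80 % of grid points. A two-sample t-test utility
(equal variances) supports group comparisons of fitted parameters at
p ≤ 0.05.

## Growth and GR metrics

Growth curves are smoothed by robust local quadratic regression: tricube
distance weights over the nearest ~10 % of points (minimum window 8),
iteratively reweighted with bisquare weights on *relative* residuals
(floored scale 10⁻³) — count data carries magnitude-proportional noise,
so absolute-residual robustification would zero-weight the large-count
tail of a clean exponential. Windows left with fewer than three
effective points fall back to the window median. Growth rate k (per
hour) comes from fitting y₀e^(kt) to counts normalized to their initial
value; a saturation flag is raised when the late-half log-slope falls
below half the early-half slope. GR values use the endpoint convention —
one rate fitted per full trajectory — configurable in principle to
time-resolved variants. The GR sigmoid fit is bounded (GR_inf ∈ [−1,1],
h ∈ (0.1,10], GEC₅₀ within a decade of the tested range); GR₅₀ follows
in closed form, GR₅₀ = GEC₅₀·(0.5/(0.5−GR_inf))^(1/h) (+∞ when
GR_inf ≥ 0.5), and GR_AOC = 1 − mean fitted GR over the tested log-dose
range. Flat responses (GR range < 0.1) are flagged unfit with GR_inf set
to the mean GR. Confluency-based lines run identically with units noted
in metadata.

## Phenotyping

Features are averaged across the two reporters per line before
integration. Pearson correlations carry t-distribution p-values with the
usual star thresholds. PCA (exact SVD, 2 components) runs on min–max
scaled features. K-means (10 restarts, fixed seed) scans k = 2–7 on the
three-feature table; the elbow is located by the Kneedle difference-curve
criterion (sensitivity 1) on the dispersion curve anchored at k = 1
(without the k = 1 anchor a genuine two-cluster structure produces no
detectable elbow), falling back to the best-silhouette k when no knee
exists. Cluster labels are assigned by deterministic centroid rules —
functional: highest circadian band among at-or-below-median-variability
clusters; dysfunctional: lowest band among above-median-variability
clusters (ties toward the longest period); unstable: highest remaining
variability; weak: the rest — which depend only on centroid geometry and
are overridable. UMAP uses 3 neighbours, seeded, with a
neighbour-preservation score reported on fixtures. Mutation scoring maps
variant classes to severities via a shipped YAML (silent 1; missense /
in-frame / splice-region 2; truncating 3; unknown classes raise in
strict mode or score 2 with a warning), sums severities per line by
default (mean switchable — the per-line normalization convention is
genuinely ambiguous), averages per group, and clusters per-gene burdens
(capped at 2) with Hamming distance and single linkage. A default
16-gene core-clock panel (standard TTFL components) ships as plain text;
clock-associated panels are user-supplied.

## Chronosensitivity

Sensitivity metrics are median-binarized with values at the median going
to the upper class (class sizes are reported so the tie rule is
auditable). Predictors are min–max scaled before the single-component
SVD LDA so |coefficient| contributions are comparable; contributions are
|w_j|/Σ|w|·100 and always sum to 100. A collinear within-class scatter
triggers a shrinkage-regularized fallback with a warning. The
chronosensitivity index is BCD/WCD with BCD the distance between class
means on LD1 and WCD the mean distance of members to their own class
mean; the effectiveness cut-off is index > 2 (class centres at least
twice the member scatter apart), with index = +∞ flagged when WCD
degenerates to 0. LOOCV accuracy is the fraction of held-out lines
classified correctly (folds whose training set loses a class are skipped
with a warning and removed from the denominator); ridge/lasso
(regularization 1.0 / 0.1) keep the continuous metric and score
agreement as 1 − mean|pred−true|/range (1 − normalized RMSE switchable —
the verbal definition admits both). Multiple-testing correction across
drugs is deliberately absent: rankings are reported raw.

## Pipeline and problem sizes

The demo pipeline generates 4 phenotype archetypes × n lines (default 3)
× 2 reporters (the second reporter is the same population signal shifted
by an archetype-specific lag), ~138-h recordings at 10-min sampling,
96-h growth curves at 2-h sampling, and 6-dose log-spaced dose–response
families per drug; per-archetype coupling strengths (0.05, 3·10⁻⁴, 0.02,
10⁻⁵), periods (24–29 h), noise levels and growth rates (0.015–
0.030 h⁻¹, anticorrelated with clock strength) are the panel's one-time
study conditions. Stage outputs are tidy CSVs under one run directory
with a manifest (config hash, seed, per-stage status); a rerun with an
unchanged configuration reuses cached stage outputs, and a stage failure
is recorded in the manifest with downstream stages skipped. All
randomness flows from explicit integer seeds (library, CLI and tests
alike); simulations and the reference curve are sized (N = 300, 1380
Euler steps, 13–25 κ grid points) so the full test suite and the
acceptance script each run in minutes on one CPU.

## Known limitations

- Estimates within ~half a filter/scale width of recording boundaries
  (detrend, envelope, wavelet amplitude) carry edge bias; tests and
  summaries evaluate interiors where the claim demands accuracy.
- The κ inversion assumes the experimental signal shares the simulator's
  noise-free mean-field form; strong measurement noise biases γ upward
  and thus κ downward.
- The rhythmicity index's analytic oracle assumes a single damped tone;
  multi-component signals have no closed form.
- Phenotype label rules are heuristics over centroid geometry; with
  k ≠ 4 only the first four rules apply and extra clusters get generic
  names.
- The synthetic panel's feature distributions are idealized; silhouette
  scores and LOOCV accuracies on it are upper bounds relative to noisy
  laboratory panels.
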