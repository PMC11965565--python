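# circapheno

Deep circadian phenotyping and chronosensitivity analysis for long-term
reporter recordings of cultured cells.

Cancer cell lines differ widely in how strong and stable their cellular
circadian clocks are, and those differences shape how the cells respond
to drugs. `circapheno` turns multi-day bioluminescence recordings of
clock-gene reporters (e.g. *Bmal1*-luc and *Per2*-luc) into a
quantitative circadian profile, classifies cell lines into circadian
phenotypes, quantifies drug response in the growth-rate-inhibition (GR)
framework, and scores how strongly each drug's sensitivity pattern
depends on the clock.

## What it computes

**Rhythm strength and stability** from a detrended recording
(48-h-cutoff windowed-sinc detrending, optional amplitude-envelope
normalization):

- *Autocorrelation*: the height of the correlogram's second peak is the
  rhythmicity index (0–1), its lag the dominant period; peaks inside the
  ±2/√n band are non-rhythmic.
- *Multiresolution analysis*: an undecimated db20 wavelet transform at
  Δt = 30 min splits signal variance into noise (1–4 h), ultradian
  (4–16 h), circadian (16–32 h) and infradian (32–256 h) bands.
- *Continuous wavelet transform*: a Morlet spectrum over 6–40 h periods;
  the ridge (per-time power maximum) gives time-resolved period,
  amplitude and phase; its above-threshold duration ("ridge length")
  measures clock strength; Bmal1–Per2 phase differences
  Δφ(t) = atan2(sin(φ₁−φ₂), cos(φ₁−φ₂)) and their circular spread
  measure clock stability. Cross-sample summaries weight each sample by
  a logistic function of ridge length, w = 1/(1+e^(−0.1(L−x₀))).

**Intercellular coupling** via a mean-field population of Poincaré
oscillators: each cell obeys

    dX_i = λ(R₀−r_i)X_i − (2π/T_i)Y_i + (κ/2N)ΣX,
    dY_i = λ(R₀−r_i)Y_i + (2π/T_i)X_i + (κ/2N)ΣY,

with inherent periods T_i ~ Norm(24, 3) h. Fitting the population signal
with A₀e^(−γt)sin(2πt/T_s+φ) and matching (A₀, γ) against a simulated
κ-grid reference curve inverts the observed damping into a coupling
strength estimate.

**Phenotypes**: Pearson correlation pruning, min–max scaling, PCA,
k-means (k chosen by the elbow of the within-cluster dispersion curve)
on period, phase-difference variability and circadian band fraction,
with deterministic centroid rules naming the clusters *functional*,
*weak*, *unstable*, *dysfunctional*; UMAP embeddings and circadian-gene
mutation severity scores (1 = silent … 3 = truncating) complete the
genomic view.

**Drug response**: GR(c) = 2^(k(c)/k(0)) − 1 from robustly smoothed
growth curves, sigmoid fits yielding GR_inf, GEC₅₀, h_GR and the derived
GR₅₀ and GR_AOC.

**Chronosensitivity**: cell lines are median-split on a sensitivity
metric, a single-component LDA separates the groups from circadian
features, and the chronosensitivity index = BCD/WCD (between-class
distance of LD1 means over mean within-class scatter) scores the
separation; an index above 2 marks a drug whose sensitivity is
effectively clock-determined. Leave-one-out cross-validation, logistic
regression and lasso/ridge regressions validate the discrimination.

A synthetic-data module generates every input with known ground truth —
oscillator populations, noisy recordings, growth curves, dose–response
families and planted phenotype archetypes — so the entire pipeline is
testable end to end.

## Worked example

`examples/` holds one short script per capability. For instance:

```bash
$ python examples/01_simulate_population.py
kappa=   1e-01  A0= 2.595e-02  gamma= 0.0047 /h  period=23.77 h  R^2=0.999
kappa=   1e-03  A0= 2.960e-04  gamma= 0.0254 /h  period=24.21 h  R^2=0.976
kappa=   1e-05  A0= 2.962e-06  gamma= 0.0256 /h  period=24.21 h  R^2=0.976
```

Strong coupling (κ = 0.1) yields a high-amplitude population signal that
barely decays (γ ≈ 0.005 h⁻¹, self-sustained); weak coupling (κ = 10⁻⁵)
gives a low-amplitude signal that damps at γ ≈ 0.026 h⁻¹ as the
oscillators dephase.

```bash
$ python examples/05_phenotypes_and_chronosensitivity.py
elbow-selected k = 4, silhouette = 0.800
phenotype counts: {'functional': 4, 'weak': 4, 'unstable': 4, 'dysfunctional': 4}
agreement with planted archetypes: 100%

                  drug  index    bcd   wcd  effective  loocv_accuracy
  clock_dependent_drug 15.251 11.941 0.783       True           1.000
clock_independent_drug  1.228  0.927 0.755      False           0.438
```

The drug whose sensitivity was generated from clock strength scores a
chronosensitivity index far above the cut-off of 2 and is classified
perfectly in leave-one-out validation; the clock-independent drug sits
below the cut-off at chance-level accuracy.

The full pipeline (simulate panel → features → phenotypes → GR fits →
chronosensitivity ranking) also runs from the shell:

```bash
circapheno run-all --seed 7 --out demo_run
```

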