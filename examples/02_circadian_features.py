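"""Feature extraction from a noisy synthetic reporter recording.

Renders a damped 24-h oscillation with trend, initial transient spike
and measurement noise (the anatomy of a raw luminescence trace), then
runs the preprocessing and feature stack: trim, sinc detrend, envelope
normalization, autocorrelation, multiresolution bands and wavelet ridge.
"""

from circapheno import autocorr, mra, wavelet
from circapheno.preprocess import normalize_envelope, sinc_detrend, trim
from circapheno.simulate import SyntheticRecordingSpec, render_recording

rec = render_recording(
    SyntheticRecordingSpec(
        base=(1.0, 0.008, 24.5, 0.0),       # A0, gamma (1/h), period (h), phase
        trend_coeffs=(2.0, -0.01),          # slow linear drift
        spike_magnitude=5.0,                # synchronization transient
        noise_sd=0.05,
        seed=1,
        sample_id="demo_Bmal1",
    )
)
d = normalize_envelope(sinc_detrend(trim(rec)))

ac = autocorr.analyze(d)
print(f"rhythmicity index = {ac.rhythmicity_index:.3f} at lag {ac.period_lag_h:.1f} h"
      f" (significant: {ac.significant})")

bands = mra.decompose(mra.resample(d)).band_fractions
print("band fractions (% of variance):",
      {k: round(v, 1) for k, v in bands.items()})

ridge = wavelet.extract_ridge(wavelet.cwt_spectrum(d, normalized=True))
summary = wavelet.ridge_readouts(ridge)
print(f"ridge length = {summary.ridge_length_h:.1f} h, "
      f"mean period = {summary.period_mean_h:.2f} h, period CV = {summary.period_cv:.3f}")
print()
print("A strong clock shows: index near 1, circadian band dominating,")
print("and a ridge tracking ~24.5 h over most of the recording.")
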