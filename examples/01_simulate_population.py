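"""Coupled Poincaré-oscillator populations: coupling shapes damping.

Simulates a 300-cell population at strong and weak mean-field coupling,
fits the damped-sinusoid model to each population signal and prints the
fitted initial amplitude A0 and decay rate gamma.  Strong coupling keeps
the heterogeneous ensemble synchronized (gamma near zero); weak coupling
lets the cells drift apart so the summed signal damps out.
"""

import numpy as np

from circapheno.decay import fit_decay
from circapheno.preprocess import DetrendedSignal
from circapheno.simulate import SimulationConfig, simulate_population

for kappa in (0.1, 1e-3, 1e-5):
    sig = simulate_population(SimulationConfig(coupling_strength=kappa, seed=42))
    fit = fit_decay(DetrendedSignal(times=sig.times, detrended=sig.mean_field))
    print(
        f"kappa={kappa:8.0e}  A0={fit.A0:10.3e}  gamma={fit.gamma:7.4f} /h  "
        f"period={fit.Ts:5.2f} h  R^2={fit.r_squared:.3f}"
    )

print()
print("gamma falls and A0 rises with coupling strength: the two ends of")
print("this trend are the self-sustained and the dephasing-damped regime.")
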