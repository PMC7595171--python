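"""Umbrella sampling + WHAM on an analytic landscape.

Draws exact Boltzmann samples for 24 harmonic umbrella windows spanning a
harmonic potential, solves the WHAM equations, attaches Bayesian-bootstrap
errors, and reports the deviation from the known analytic profile.
"""

import numpy as np

import nsh2kit as nk

pot = nk.Potential1D("harmonic", K=50.0)  # analytic PMF: 25 x^2 kJ/mol
refs = np.linspace(-0.6, 0.6, 24)
windows = [
    nk.UmbrellaWindow(ref=float(r), k=1000.0, samples=nk.sample_boltzmann_1d(
        pot, nk.HarmonicBias(1000.0, float(r)), 300.0, n=20_000, seed=10 + i))
    for i, r in enumerate(refs)
]
ws = nk.UmbrellaWindowSet(windows, temperature=300.0)
profile = nk.bayesian_bootstrap(ws, bins=200, n_boot=100, seed=1)

mask = np.abs(profile.bin_centers) <= 0.6
dev = profile.free_energy[mask] - 0.5 * 50.0 * profile.bin_centers[mask] ** 2
dev -= dev.mean()
print(f"windows: {ws.n_windows}, samples/window: 20000, bins: 200")
print(f"max |G - analytic| over the window span: {np.max(np.abs(dev)):.3f} kJ/mol")
print(f"mean bootstrap error (|x| < 0.5 nm):     "
      f"{profile.error[np.abs(profile.bin_centers) < 0.5].mean():.3f} kJ/mol")
print()
print("The recovered profile agrees with the analytic potential to a small")
print("fraction of kBT; the per-bin errors come from reweighting whole window")
print("histograms (Bayesian bootstrap of complete histograms).")
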