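import numpy as np
import pytest

import nsh2kit as nk


@pytest.fixture(scope="session")
def two_state_clean():
    """Noise-free two-state ensemble (ground truth exactly realized)."""
    return nk.build_two_state_ensemble(200, 0.5, noise_sd=0.0, seed=101)


@pytest.fixture(scope="session")
def two_state_noisy():
    """Two-state ensemble at the default study conditions (noise 0.3 A)."""
    return nk.build_two_state_ensemble(2000, 0.7, noise_sd=0.3, seed=202)


@pytest.fixture(scope="session")
def harmonic_window_set():
    """24 exact-sampled umbrella windows over a harmonic landscape."""
    pot = nk.Potential1D("harmonic", K=50.0)
    refs = np.linspace(-0.6, 0.6, 24)
    windows = [
        nk.UmbrellaWindow(
            ref=float(r), k=1000.0,
            samples=nk.sample_boltzmann_1d(
                pot, nk.HarmonicBias(1000.0, float(r)), 300.0, n=20000,
                seed=300 + i,
            ),
        )
        for i, r in enumerate(refs)
    ]
    return nk.UmbrellaWindowSet(windows, temperature=300.0)
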