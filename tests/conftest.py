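import numpy as np
import pytest

from trapforge import SimConfig, simulate_bead_only, simulate_ensemble_trace


@pytest.fixture(scope="session")
def bead_only_trace():
    """10 s bead-only record at 0.04 pN/nm, 5 kHz."""
    return simulate_bead_only(SimConfig(k_trap=0.04, duration_s=10.0, seed=11))


@pytest.fixture(scope="session")
def ensemble_sim():
    """A 30 s simulated record with ground truth (30 mM Pi, slip pathway)."""
    cfg = SimConfig(k_trap=0.04, duration_s=30.0, seed=3, pi_mM=30.0, k_adp0=0.0)
    trace, truth = simulate_ensemble_trace(cfg)
    return cfg, trace, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
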