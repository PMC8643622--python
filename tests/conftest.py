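import numpy as np
import pytest

from zmwfccs.simkit import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20210930)


@pytest.fixture
def small_config():
    """Cheap, fine-grained config: few molecules, short trace, dt-level
    position updates — for tests that exercise the physics directly."""
    return SimulationConfig(
        conc_G=0.3, conc_R=0.3, conc_GR=0.2,
        k_on=0.07, k_off=3.61, ligand_conc=40.0,
        duration=1.0, dt=4.0, diffusion_stride=1,
        brightness_G=50.0, brightness_R=50.0,
        background_G=0.1, background_R=0.1)


@pytest.fixture
def telegraph_trace(rng):
    """Two-state brightness trace with known switching rates.

    Returns (trace, k1, k2, levels, bin_ms); k1/k2 in ms^-1 with
    bin width 10 us.
    """
    k1, k2 = 2.0, 3.0          # ms^-1
    bin_ms = 0.01
    n = 40_000
    p1 = k1 / (k1 + k2)
    p_01 = 1 - np.exp(-k1 * bin_ms)
    p_10 = 1 - np.exp(-k2 * bin_ms)
    state = np.empty(n, dtype=bool)
    s = rng.random() < p1
    for i in range(n):
        u = rng.random()
        s = (not s) if (u < (p_10 if s else p_01)) else s
        state[i] = s
    lo, hi = 2.0, 10.0
    return np.where(state, hi, lo), k1, k2, (lo, hi), bin_ms
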