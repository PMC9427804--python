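import numpy as np
import pytest

from eakit.kinetics import BiExpParams, MonoExpParams, Syllectogram, eval_mono_exp
from eakit.simulate import NoiseSpec, simulate_syllectogram

#: Typical healthy-donor kinetics: a 2.51 s half-life (k = ln2 / 2.51).
HEALTHY_K = 0.27615


@pytest.fixture
def healthy_params() -> MonoExpParams:
    return MonoExpParams(a0=1000.0, k=HEALTHY_K)


@pytest.fixture
def noiseless_5s(healthy_params) -> Syllectogram:
    """Exact 5 s mono-exponential recording at 100 Hz (501 samples)."""
    return simulate_syllectogram(healthy_params, 5.0, 100.0, NoiseSpec("none"))


@pytest.fixture
def noisy_5s(healthy_params) -> Syllectogram:
    """Same curve with additive Gaussian noise at 0.5% of A0, fixed seed."""
    return simulate_syllectogram(healthy_params, 5.0, 100.0, NoiseSpec(sd=5.0, seed=42))


@pytest.fixture
def biexp_params() -> BiExpParams:
    return BiExpParams(i_fast=3.0, tau_fast=1.0, i_slow=1.0, tau_slow=15.0, baseline=0.5)


@pytest.fixture
def noiseless_20s(biexp_params) -> Syllectogram:
    return simulate_syllectogram(biexp_params, 20.0, 100.0, NoiseSpec("none"))


def mono_curve(a0: float, k: float, duration: float = 5.0, rate: float = 100.0) -> Syllectogram:
    t = np.arange(int(round(duration * rate)) + 1) / rate
    return Syllectogram(t, eval_mono_exp(MonoExpParams(a0, k), t))
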