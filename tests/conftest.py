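import numpy as np
import pytest

from gaitri import run_table3, run_table4


@pytest.fixture(scope="session")
def table3():
    """Full sine case grid under the default (doubled) alpha spacing."""
    return run_table3("doubled")


@pytest.fixture(scope="session")
def table4_small():
    """Monte Carlo factor/joint/mode grid at reduced simulation count."""
    return run_table4(n_sim=200, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_group(rng, m=None, t=None):
    """Small random curve group for oracle comparisons."""
    from gaitri import WaveformGroup
    from gaitri.waveform import fourier_grid

    m = m or int(rng.integers(2, 6))
    t = t or int(rng.integers(5, 21))
    matrix = rng.normal(0.0, 10.0, size=(m, t))
    return WaveformGroup.from_matrix(matrix, fourier_grid(t))
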