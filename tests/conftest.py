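import numpy as np
import pytest

from astakin import IRFModel, KineticScheme


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def sharp_irf():
    """Quasi-delta IRF: narrow enough that convolution is invisible on a
    picosecond grid."""
    return IRFModel(mu=0.0, sigma=1e-5)


@pytest.fixture
def fs_irf():
    """Instrument-like 120-fs-FWHM Gaussian IRF."""
    return IRFModel.from_fwhm_fs(120.0)


def random_scheme(rng, n_max=6):
    """A random valid compartmental scheme: nonnegative transfers, positive
    ground losses, log-uniform rates in [1, 1e4] ns^-1."""
    n = int(rng.integers(1, n_max + 1))
    K = np.zeros((n, n))
    for j in range(n):
        # sparse random transfers out of j
        for i in range(n):
            if i != j and rng.random() < 0.4:
                K[i, j] = 10 ** rng.uniform(0, 4)
        loss = 10 ** rng.uniform(0, 4)
        K[j, j] = -(K[:, j].sum() + loss)
    inp = rng.random(n) + 0.05
    inp /= inp.sum()
    labels = [f"c{i}" for i in range(n)]
    return KineticScheme(labels=labels, K=K, input=inp)
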