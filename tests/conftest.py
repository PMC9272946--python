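import numpy as np
import pytest

from dividemri import build_protocol

B_VALUES = [0.2, 0.5, 0.8, 1.2, 1.5]


@pytest.fixture(scope="session")
def study_scheme():
    """The 80-volume protocol: 5 b-values x {LTE, STE} x 8 directions."""
    return build_protocol(B_VALUES, shapes=(1.0, 0.0), n_directions=8)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_dtd(rng, n_components=None, max_diff=2.5):
    """Random axisymmetric mixture for property tests."""
    from dividemri import MicroTensor, TensorDistribution

    m = int(n_components or rng.integers(2, 6))
    w = rng.dirichlet(np.ones(m))
    comps = []
    for i in range(m):
        lam_par = rng.uniform(0.1, max_diff)
        lam_perp = rng.uniform(0.05, lam_par)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        comps.append((w[i], MicroTensor(lam_par, lam_perp, u)))
    return TensorDistribution(comps)
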