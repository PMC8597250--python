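import numpy as np
import pytest

import lowrankdti as lr


@pytest.fixture
def tiny_interactions(tmp_path):
    """2x3 drug-target table with labels d1,d2 / t1,t2,t3."""
    path = tmp_path / "tiny.txt"
    path.write_text(
        "\tt1\tt2\tt3\n"
        "d1\t1\t0\t1\n"
        "d2\t0\t0\t1\n",
        encoding="utf-8",
    )
    return path


@pytest.fixture(scope="session")
def default_instance():
    """The generator's default instance (60 drugs x 50 targets, rank 4)."""
    return lr.generate(lr.SyntheticSpec(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_factors(m, n, r, seed):
    """Random valid SVD-form factors (orthonormal U/V, sorted d)."""
    g = np.random.default_rng(seed)
    U, _ = np.linalg.qr(g.standard_normal((m, r)))
    V, _ = np.linalg.qr(g.standard_normal((n, r)))
    d = np.sort(g.uniform(0.1, 3.0, size=r))[::-1]
    return lr.LowRankFactors(U, d, V)
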