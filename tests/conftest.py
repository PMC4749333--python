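import numpy as np
import pytest

from refstab import CqMatrix, RQMatrix


@pytest.fixture
def toy_rq():
    """Three genes where A and B track each other perfectly and C is flat."""
    return RQMatrix(
        genes=["A", "B", "C"],
        samples=["s1", "s2", "s3"],
        rq=np.array([[1.0, 2.0, 4.0], [2.0, 4.0, 8.0], [1.0, 1.0, 1.0]]),
    )


@pytest.fixture
def toy_cq():
    """Cq matrix matching toy_rq under Cq = 20 - log2(rq) (efficiency 1)."""
    rq = np.array([[1.0, 2.0, 4.0], [2.0, 4.0, 8.0], [1.0, 1.0, 1.0]])
    return CqMatrix(
        genes=["A", "B", "C"],
        samples=["s1", "s2", "s3"],
        cq_mean=20.0 - np.log2(rq),
        rep_sd=np.zeros((3, 3)),
    )


def random_rq(rng, n_genes=6, n_samples=8):
    """Log-normal random relative quantities."""
    return RQMatrix(
        genes=[f"g{i}" for i in range(n_genes)],
        samples=[f"s{i}" for i in range(n_samples)],
        rq=np.exp2(rng.normal(0.0, 1.0, size=(n_genes, n_samples))),
    )
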