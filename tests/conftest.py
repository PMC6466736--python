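import numpy as np
import pytest

from pbtest.covariance_model import CorrelationModel, CovarianceSpec, build_covariance


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_pd(n, rng, diag_boost=None):
    """Random symmetric positive-definite matrix of size n."""
    A = rng.normal(size=(n, n))
    boost = n if diag_boost is None else diag_boost
    return A @ A.T + boost * np.eye(n)


def random_standardized(n, rng):
    """Random standardized structure matrix (1' S^-1 1 = 1)."""
    return CovarianceSpec.from_sigma(random_pd(n, rng)).S


@pytest.fixture
def paired_design():
    """20 complete pairs (n = 40), group indicator alternating within pair."""
    L = 20
    labels = tuple(f"p{i // 2}" for i in range(2 * L))
    x = np.tile([0.0, 1.0], L)
    X = np.column_stack([np.ones(2 * L), x])
    return labels, x, X


def paired_cov(rho, weights=None, L=20):
    labels = tuple(f"p{i // 2}" for i in range(2 * L))
    w = np.ones(2 * L) if weights is None else weights
    return build_covariance(w, CorrelationModel(labels, rho))
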