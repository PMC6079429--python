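"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest
from scipy import stats

from dvclust.model import CASE, CONTROL, ExpressionDataset


def exchangeable_cov(n: int, sigma2: float, rho: float) -> np.ndarray:
    """Dense compound-symmetry covariance matrix (oracle building block)."""
    return sigma2 * ((1.0 - rho) * np.eye(n) + rho * np.ones((n, n)))


def dense_cs_logpdf(x, mu, sigma2, rho) -> float:
    """Oracle: exchangeable-normal log density via the dense covariance."""
    x = np.asarray(x, dtype=float)
    cov = exchangeable_cov(x.size, sigma2, rho)
    return float(
        stats.multivariate_normal(mean=np.full(x.size, mu), cov=cov).logpdf(x)
    )


def dense_cluster_logpdf(x_case, x_control, params) -> float:
    """Oracle: block-diagonal (case + control) dense log density."""
    return dense_cs_logpdf(
        x_case, params.mu_c, params.sigma2_c, params.rho_c
    ) + dense_cs_logpdf(x_control, params.mu_n, params.sigma2_n, params.rho_n)


def make_dataset(values, m_c=None) -> ExpressionDataset:
    """Wrap a matrix as a dataset; first ``m_c`` columns are cases."""
    values = np.asarray(values, dtype=float)
    g, m = values.shape
    if m_c is None:
        m_c = m // 2
    group = np.array([CASE] * m_c + [CONTROL] * (m - m_c), dtype=object)
    probe_ids = [f"p{i}" for i in range(g)]
    return ExpressionDataset(values, probe_ids, group)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_dataset(rng):
    """8 probes, 5 cases + 4 controls of plain normal noise."""
    return make_dataset(rng.normal(size=(8, 9)), m_c=5)
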