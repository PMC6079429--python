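"""Synthetic expression data from the four study scenarios.

The generators draw probe-by-sample matrices from the three-cluster
marginal mixture with known ground truth:

* ``SimI``  — mixture of block exchangeable-covariance multivariate normals
  using the packaged default parameters (estimates from a 60-case/60-control
  hepatocellular-carcinoma miRNA discovery cohort).
* ``SimII`` — same means and covariance structure, but each probe vector is
  multivariate t with 3 degrees of freedom (heavy tails; normality violated).
* ``SimIII``/``SimIV`` — the normal / t scenarios with all between-subject
  correlations forced to zero.

Cluster sizes are fixed counts ``round(pi_k * G)`` (largest-remainder
corrected), not multinomial draws, so truth label counts are exact at every
seed; probe order is then shuffled so membership is not positional.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np

from .model import (
    CASE,
    CLUSTER_KINDS,
    CONTROL,
    ClusterParams,
    ExpressionDataset,
    MixtureModel,
)

__all__ = [
    "SCENARIOS",
    "ScenarioConfig",
    "SimulationTruth",
    "default_params",
    "simulate_dataset",
    "sample_exchangeable_block",
]

SCENARIOS = ("SimI", "SimII", "SimIII", "SimIV")
_T_SCENARIOS = ("SimII", "SimIV")
_ZERO_RHO_SCENARIOS = ("SimIII", "SimIV")


def default_params(m_c: int = 50, m_n: int = 50) -> MixtureModel:
    """The packaged generating parameters (mixture fitted to the discovery
    cohort): pi = (0.31, 0.58, 0.11) over (OV, EV, UV) with six
    (mu, sigma2, rho) triples."""
    clusters = (
        ClusterParams("OV", mu_c=-0.14, sigma2_c=1.49, rho_c=0.08,
                      mu_n=0.14, sigma2_n=0.45, rho_n=0.32),
        ClusterParams("EV", mu_c=0.03, sigma2_c=1.01, rho_c=0.04,
                      mu_n=-0.03, sigma2_n=1.01, rho_n=0.11),
        ClusterParams("UV", mu_c=0.13, sigma2_c=0.28, rho_c=0.04,
                      mu_n=-0.13, sigma2_n=1.69, rho_n=-0.01),
    )
    return MixtureModel(np.array([0.31, 0.58, 0.11]), clusters, m_c, m_n)


@dataclass
class ScenarioConfig:
    """One simulation scenario, fully determined by its fields and seed.

    ``t_matching`` controls how the heavy-tailed scenarios interpret the
    normal-scenario covariance: ``"scale"`` uses it as the multivariate-t
    scale matrix (the t's covariance is then df/(df-2) times larger);
    ``"covariance"`` rescales so the t's covariance matches exactly.
    """

    scenario: str = "SimI"
    G: int = 1000
    m_c: int = 50
    m_n: int = 50
    params: MixtureModel | None = None
    df: float = 3.0
    seed: int = 0
    t_matching: str = "scale"

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.G < 3:
            raise ValueError("G must be at least 3")
        if self.scenario in _T_SCENARIOS and self.df <= 0:
            raise ValueError("df must be positive for the t scenarios")
        if self.t_matching not in ("scale", "covariance"):
            raise ValueError(f"unknown t_matching {self.t_matching!r}")
        if self.params is None:
            self.params = default_params(self.m_c, self.m_n)


@dataclass
class SimulationTruth:
    """True cluster label per probe plus the generating configuration."""

    labels: np.ndarray
    config: ScenarioConfig


@lru_cache(maxsize=64)
def _chol_factor(n: int, sigma2: float, rho: float) -> np.ndarray:
    """Cholesky factor of sigma2 * ((1 - rho) I + rho J), cached."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if n > 1 and not (-1.0 / (n - 1) < rho < 1):
        raise ValueError(f"rho={rho} outside the positive-definite range")
    cov = sigma2 * ((1.0 - rho) * np.eye(n) + rho * np.ones((n, n)))
    return np.linalg.cholesky(cov)


def sample_exchangeable_block(
    n: int,
    mu: float,
    sigma2: float,
    rho: float,
    rng: np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """Draw from the exchangeable normal N(mu 1, sigma2 ((1-rho) I + rho J)).

    Returns a ``(size, n)`` array (``size=1`` still returns 2-D).  Negative
    rho is supported down to the positive-definiteness bound -1/(n-1).
    """
    if n == 1:
        return rng.normal(mu, np.sqrt(sigma2), size=(size, 1))
    chol = _chol_factor(n, float(sigma2), float(rho))
    z = rng.standard_normal((size, n))
    return mu + z @ chol.T


def _standardized_block(
    n: int, sigma2: float, rho: float, rng: np.random.Generator, size: int
) -> np.ndarray:
    """Zero-mean draw from the exchangeable normal (mu folded in later)."""
    return sample_exchangeable_block(n, 0.0, sigma2, rho, rng, size)


def simulate_dataset(config: ScenarioConfig) -> tuple[ExpressionDataset, SimulationTruth]:
    """Generate one dataset plus its ground-truth cluster labels.

    Each probe's full expression vector is one draw from its cluster's
    block distribution (case block independent of control block for the
    normal scenarios; the t scenarios share one chi-square mixing variable
    per probe across the whole vector, the classic multivariate-t
    construction).
    """
    params = config.params
    assert params is not None
    rng = np.random.default_rng(config.seed)

    counts = _fixed_counts(params.pi, config.G)
    labels_ordered = np.repeat(np.array(CLUSTER_KINDS, dtype=object), counts)

    values = np.empty((config.G, config.m_c + config.m_n))
    row = 0
    heavy = config.scenario in _T_SCENARIOS
    for k, cluster in enumerate(params.clusters):
        g_k = counts[k]
        if g_k == 0:
            continue
        c = cluster
        if config.scenario in _ZERO_RHO_SCENARIOS:
            c = replace(c, rho_c=0.0, rho_n=0.0)
        scale_c, scale_n = c.sigma2_c, c.sigma2_n
        if heavy and config.t_matching == "covariance":
            if config.df <= 2:
                raise ValueError("covariance matching requires df > 2")
            shrink = (config.df - 2.0) / config.df
            scale_c, scale_n = scale_c * shrink, scale_n * shrink
        z_c = _standardized_block(config.m_c, scale_c, c.rho_c, rng, g_k)
        z_n = _standardized_block(config.m_n, scale_n, c.rho_n, rng, g_k)
        z = np.hstack([z_c, z_n])
        if heavy:
            u = rng.chisquare(config.df, size=g_k)
            z *= np.sqrt(config.df / u)[:, None]
        mu = np.concatenate(
            [np.full(config.m_c, c.mu_c), np.full(config.m_n, c.mu_n)]
        )
        values[row : row + g_k] = mu + z
        row += g_k

    order = rng.permutation(config.G)
    values = values[order]
    labels = labels_ordered[order]

    width = len(str(config.G))
    probe_ids = [f"probe_{i + 1:0{width}d}" for i in range(config.G)]
    group = np.array(
        [CASE] * config.m_c + [CONTROL] * config.m_n, dtype=object
    )
    data = ExpressionDataset(values, probe_ids, group)
    return data, SimulationTruth(labels, config)


def _fixed_counts(pi: np.ndarray, G: int) -> np.ndarray:
    """round(pi_k * G) with largest-remainder correction to sum to G."""
    raw = pi * G
    counts = np.round(raw).astype(int)
    diff = G - counts.sum()
    if diff != 0:
        remainders = raw - np.floor(raw)
        order = np.argsort(-remainders if diff > 0 else remainders, kind="stable")
        for i in range(abs(diff)):
            counts[order[i % 3]] += int(np.sign(diff))
    return counts
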