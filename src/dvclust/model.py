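"""Core data containers and exchangeable-covariance normal densities.

The mixture model treats each probe's expression vector across all subjects
as a single observation.  Within each of three clusters — OV (over-variable:
case variance exceeds control variance), EV (equal variance) and UV
(under-variable) — the case block and the control block are independent
multivariate normals with compound-symmetry (exchangeable) covariance
``sigma2 * ((1 - rho) * I + rho * J)``: one mean, one variance and one
pairwise between-subject correlation per group.

The exchangeable covariance has only two distinct eigenvalues,

    lambda1 = sigma2 * (1 - rho)              (multiplicity n - 1)
    lambda2 = sigma2 * (1 + (n - 1) * rho)    (multiplicity 1)

which makes exact density evaluation O(n) per vector and lets the whole
probe-by-cluster log-density matrix be computed from per-probe sufficient
statistics (group mean and within-group sum of squares).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ExpressionDataset",
    "ClusterParams",
    "MixtureModel",
    "FitResult",
    "cs_mvn_logpdf",
    "cluster_logpdf",
    "posterior_probs",
    "log_density_matrix",
    "CASE",
    "CONTROL",
    "CLUSTER_KINDS",
]

CASE = "case"
CONTROL = "control"
#: Fixed cluster order: index 0 = OV, 1 = EV, 2 = UV.
CLUSTER_KINDS = ("OV", "EV", "UV")

# Numerical floor for the covariance eigenvalues; guards degenerate M-step
# outputs without affecting well-conditioned values.
EIGEN_FLOOR = 1e-12


class InvalidParameterError(ValueError):
    """Raised when covariance parameters violate positive-definiteness."""


@dataclass
class ExpressionDataset:
    """Probe-by-sample expression matrix with a two-level group label.

    Parameters
    ----------
    values
        ``(G, m)`` array of (preprocessed) expression values; rows are
        probes, columns are samples.
    probe_ids
        ``G`` unique probe identifiers.
    group
        Per-sample label, each ``"case"`` or ``"control"``.
    """

    values: np.ndarray
    probe_ids: list[str]
    group: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.group = np.asarray(self.group, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D probe x sample matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must all be finite")
        g, m = self.values.shape
        if len(self.probe_ids) != g:
            raise ValueError("probe_ids length does not match number of rows")
        if len(set(self.probe_ids)) != g:
            dupes = {p for p in self.probe_ids if self.probe_ids.count(p) > 1}
            raise ValueError(f"duplicate probe ids: {sorted(dupes)[:5]}")
        if self.group.shape != (m,):
            raise ValueError("group length does not match number of columns")
        bad = [str(x) for x in self.group if x not in (CASE, CONTROL)]
        if bad:
            raise ValueError(f"unknown group labels: {sorted(set(bad))}")
        if self.m_c < 2 or self.m_n < 2:
            raise ValueError("need at least 2 cases and 2 controls")

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    @property
    def m_c(self) -> int:
        return int(np.sum(self.group == CASE))

    @property
    def m_n(self) -> int:
        return int(np.sum(self.group == CONTROL))

    @property
    def case_values(self) -> np.ndarray:
        """``(G, m_c)`` view of the case columns."""
        return self.values[:, self.group == CASE]

    @property
    def control_values(self) -> np.ndarray:
        """``(G, m_n)`` view of the control columns."""
        return self.values[:, self.group == CONTROL]

    def sample_variances(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-probe sample variances ``(s_c^2, s_n^2)`` (ddof=1)."""
        return (
            self.case_values.var(axis=1, ddof=1),
            self.control_values.var(axis=1, ddof=1),
        )


def _rho_lower(n: int) -> float:
    """Lower positive-definiteness bound for the exchangeable correlation."""
    return -1.0 / (n - 1) if n > 1 else 0.0


@dataclass
class ClusterParams:
    """Parameters of one cluster: (mu, sigma2, rho) per group plus a kind tag.

    ``kind`` records which variance-order constraint the cluster represents
    (OV: sigma2_c > sigma2_n, UV: sigma2_c < sigma2_n, EV: equal).  During
    EM the OV/UV inequalities may be transiently violated; ``validate`` with
    ``strict_kind=True`` checks them.
    """

    kind: str
    mu_c: float
    sigma2_c: float
    rho_c: float
    mu_n: float
    sigma2_n: float
    rho_n: float

    def validate(self, m_c: int, m_n: int, strict_kind: bool = False) -> None:
        if self.kind not in CLUSTER_KINDS:
            raise InvalidParameterError(f"unknown cluster kind {self.kind!r}")
        if self.sigma2_c <= 0 or self.sigma2_n <= 0:
            raise InvalidParameterError("variances must be positive")
        if not (_rho_lower(m_c) < self.rho_c < 1):
            raise InvalidParameterError(
                f"rho_c={self.rho_c} outside ({_rho_lower(m_c):.4g}, 1)"
            )
        if not (_rho_lower(m_n) < self.rho_n < 1):
            raise InvalidParameterError(
                f"rho_n={self.rho_n} outside ({_rho_lower(m_n):.4g}, 1)"
            )
        if strict_kind:
            if self.kind == "OV" and not self.sigma2_c > self.sigma2_n:
                raise InvalidParameterError("OV cluster requires sigma2_c > sigma2_n")
            if self.kind == "UV" and not self.sigma2_c < self.sigma2_n:
                raise InvalidParameterError("UV cluster requires sigma2_c < sigma2_n")
            if self.kind == "EV" and not np.isclose(self.sigma2_c, self.sigma2_n):
                raise InvalidParameterError("EV cluster requires sigma2_c == sigma2_n")

    def variance_ratio(self) -> float:
        return self.sigma2_c / self.sigma2_n


@dataclass
class MixtureModel:
    """Three-component mixture in fixed (OV, EV, UV) order.

    ``pi`` holds the mixing proportions; ``clusters`` the per-cluster
    parameters; ``m_c``/``m_n`` the group sizes the model is defined for
    (the rho bounds depend on them).
    """

    pi: np.ndarray
    clusters: tuple[ClusterParams, ClusterParams, ClusterParams]
    m_c: int
    m_n: int

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (3,) or np.any(self.pi < 0):
            raise ValueError("pi must be 3 nonnegative proportions")
        if not np.isclose(self.pi.sum(), 1.0):
            raise ValueError(f"pi must sum to 1, got {self.pi.sum()}")
        if tuple(c.kind for c in self.clusters) != CLUSTER_KINDS:
            raise ValueError("clusters must be ordered (OV, EV, UV)")

    def validate(self, strict_kind: bool = False) -> None:
        for c in self.clusters:
            c.validate(self.m_c, self.m_n, strict_kind=strict_kind)


@dataclass
class DVCall:
    """Per-probe differential-variability call from any detector.

    ``labels`` are OV/EV/UV; ``dv_flags`` marks OV or UV; ``directions`` is
    the sign of the sample-variance difference ``s_c^2 - s_n^2``.
    """

    probe_ids: list[str]
    labels: np.ndarray
    dv_flags: np.ndarray
    directions: np.ndarray


@dataclass
class FitResult:
    """Outcome of an EM fit: model, responsibilities and diagnostics."""

    model: MixtureModel
    responsibilities: np.ndarray
    assignments: np.ndarray
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    seed: int
    loglik: float = field(init=False)

    def __post_init__(self) -> None:
        self.loglik = float(self.loglik_trace[-1])


def cs_mvn_logpdf(x: Sequence[float], mu: float, sigma2: float, rho: float) -> float:
    """Log density of the exchangeable (compound-symmetry) normal.

    Evaluates ``N(mu * 1, sigma2 * ((1 - rho) I + rho J))`` at ``x`` in
    O(n) using the two-eigenvalue decomposition of the covariance.  For a
    single observation (n = 1) ``rho`` is irrelevant and ignored.

    Parameters
    ----------
    x
        Observation vector of length ``n >= 1``.
    mu, sigma2, rho
        Common mean, variance and pairwise correlation.  ``rho`` must lie
        in ``(-1/(n-1), 1)`` for positive-definiteness.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("x must be a 1-D vector of length >= 1")
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    n = x.size
    if sigma2 <= 0:
        raise InvalidParameterError("sigma2 must be positive")
    if n == 1:
        rho = 0.0
    elif not (_rho_lower(n) < rho < 1):
        raise InvalidParameterError(
            f"rho={rho} outside the positive-definite range ({_rho_lower(n):.4g}, 1)"
        )
    xbar = x.mean()
    w = float(np.sum((x - xbar) ** 2))
    b = n * (xbar - mu) ** 2
    lam1 = max(sigma2 * (1.0 - rho), EIGEN_FLOOR)
    lam2 = max(sigma2 * (1.0 + (n - 1) * rho), EIGEN_FLOOR)
    return -0.5 * (
        n * np.log(2.0 * np.pi)
        + (n - 1) * np.log(lam1)
        + np.log(lam2)
        + w / lam1
        + b / lam2
    )


def cluster_logpdf(
    x_case: Sequence[float], x_control: Sequence[float], params: ClusterParams
) -> float:
    """Log density ``log f_k(x)`` of one probe under one cluster.

    Cases and controls are independent, so the probe's log density is the
    sum of the two exchangeable-normal block log densities.
    """
    return cs_mvn_logpdf(
        x_case, params.mu_c, params.sigma2_c, params.rho_c
    ) + cs_mvn_logpdf(x_control, params.mu_n, params.sigma2_n, params.rho_n)


def group_sufficient_stats(data: ExpressionDataset) -> dict[str, np.ndarray]:
    """Per-probe sufficient statistics for density evaluation and EM.

    Returns per-group mean ``xbar`` and within-probe sum of squares
    ``W = sum_j (x_j - xbar)^2`` for every probe — all the likelihood needs
    besides the parameters.
    """
    out = {}
    for tag, block in (("c", data.case_values), ("n", data.control_values)):
        xbar = block.mean(axis=1)
        w = np.sum((block - xbar[:, None]) ** 2, axis=1)
        out[f"xbar_{tag}"] = xbar
        out[f"w_{tag}"] = w
        out[f"n_{tag}"] = block.shape[1]
    return out


def _block_logpdf_from_stats(
    xbar: np.ndarray, w: np.ndarray, n: int, mu: float, sigma2: float, rho: float
) -> np.ndarray:
    lam1 = max(sigma2 * (1.0 - rho), EIGEN_FLOOR)
    lam2 = max(sigma2 * (1.0 + (n - 1) * rho), EIGEN_FLOOR)
    b = n * (xbar - mu) ** 2
    return -0.5 * (
        n * np.log(2.0 * np.pi)
        + (n - 1) * np.log(lam1)
        + np.log(lam2)
        + w / lam1
        + b / lam2
    )


def log_density_matrix(
    data: ExpressionDataset,
    model: MixtureModel,
    stats: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """``(G, 3)`` matrix of per-probe, per-cluster log densities log f_k."""
    if model.m_c != data.m_c or model.m_n != data.m_n:
        raise ValueError("model group sizes do not match the dataset")
    if stats is None:
        stats = group_sufficient_stats(data)
    cols = []
    for p in model.clusters:
        lc = _block_logpdf_from_stats(
            stats["xbar_c"], stats["w_c"], stats["n_c"], p.mu_c, p.sigma2_c, p.rho_c
        )
        ln = _block_logpdf_from_stats(
            stats["xbar_n"], stats["w_n"], stats["n_n"], p.mu_n, p.sigma2_n, p.rho_n
        )
        cols.append(lc + ln)
    return np.column_stack(cols)


def posterior_probs(
    data: ExpressionDataset,
    model: MixtureModel,
    stats: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Posterior cluster probabilities ``p_gk`` for every probe.

    Row ``g`` is ``pi_k f_k(x_g) / sum_j pi_j f_j(x_g)``, computed in log
    space with log-sum-exp; rows sum to 1.
    """
    logf = log_density_matrix(data, model, stats)
    with np.errstate(divide="ignore"):
        logpi = np.log(model.pi)
    a = logf + logpi
    amax = a.max(axis=1)
    bad = ~np.isfinite(amax)
    if np.any(bad):
        idx = int(np.flatnonzero(bad)[0])
        raise FloatingPointError(
            f"all cluster densities vanished for probe {data.probe_ids[idx]!r}"
        )
    shifted = np.exp(a - amax[:, None])
    return shifted / shifted.sum(axis=1, keepdims=True)
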