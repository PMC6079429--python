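"""EM estimation of the constrained three-cluster mixture (the "gs" method).

The observed-data likelihood is a three-component mixture of block
exchangeable-covariance normals (see :mod:`dvclust.model`).  The M-step has
a closed form for the unconstrained clusters via the two-eigenvalue
decomposition: with per-probe group mean ``xbar_g``, within sum of squares
``W_g`` and responsibilities ``p_gk``,

    mu_hat   = sum_g p_gk xbar_g / sum_g p_gk
    lam1_hat = sum_g p_gk W_g / ((n - 1) sum_g p_gk)
    lam2_hat = sum_g p_gk n (xbar_g - mu_hat)^2 / sum_g p_gk
    sigma2   = ((n - 1) lam1_hat + lam2_hat) / n,   rho = 1 - lam1_hat/sigma2

The EV cluster shares one variance across groups while keeping separate
correlations; no closed form exists, so (sigma2, rho_c, rho_n) are jointly
maximized numerically on transformed coordinates, initialized at the pooled
closed form.  The OV/UV variance inequalities are not projected inside the
loop (projection can break EM monotonicity); instead clusters are relabeled
by their variance ratio at convergence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .model import (
    CLUSTER_KINDS,
    EIGEN_FLOOR,
    ClusterParams,
    DVCall,
    ExpressionDataset,
    FitResult,
    MixtureModel,
    _rho_lower,
    group_sufficient_stats,
    log_density_matrix,
)

__all__ = ["FitConfig", "initialize", "e_step", "m_step", "fit", "assign_clusters", "detect_dv"]

logger = logging.getLogger(__name__)

_STARVATION_TOL = 1e-8


@dataclass
class FitConfig:
    """Knobs for the EM fit.

    tol
        Relative log-likelihood change below which EM stops (default 1e-6).
    max_iter
        Iteration cap per restart (default 1000).
    n_starts
        Number of initializations; the first uses the variance-ratio
        strategy, the rest perturb it (default 5).
    seed
        Base seed; restarts derive their perturbations from it.
    init_method
        ``"variance-ratio"`` or ``"random"``.
    """

    tol: float = 1e-6
    max_iter: int = 1000
    n_starts: int = 5
    seed: int = 0
    init_method: str = "variance-ratio"

    def __post_init__(self) -> None:
        if self.tol <= 0 or self.max_iter < 1 or self.n_starts < 1:
            raise ValueError("tol > 0, max_iter >= 1 and n_starts >= 1 required")
        if self.init_method not in ("variance-ratio", "random"):
            raise ValueError(f"unknown init_method {self.init_method!r}")


# ---------------------------------------------------------------------------
# weighted moment machinery

def _weighted_group_update(
    w_probe: np.ndarray, stats: dict, tag: str
) -> tuple[float, float, float, float, float]:
    """Responsibility-weighted closed-form update for one group.

    Returns ``(mu, sigma2, rho, sw, sb)`` where ``sw``/``sb`` are the
    weighted within/between sums reused by the EV optimization.
    """
    n = stats[f"n_{tag}"]
    xbar = stats[f"xbar_{tag}"]
    wss = stats[f"w_{tag}"]
    sp = float(w_probe.sum())
    mu = float(w_probe @ xbar) / sp
    sw = float(w_probe @ wss)
    sb = float(w_probe @ (n * (xbar - mu) ** 2))
    lam1 = max(sw / ((n - 1) * sp), EIGEN_FLOOR)
    lam2 = max(sb / sp, EIGEN_FLOOR)
    sigma2 = ((n - 1) * lam1 + lam2) / n
    rho = 1.0 - lam1 / sigma2
    return mu, sigma2, rho, sw, sb


def _fit_ev_cluster(
    w_probe: np.ndarray, stats: dict, prev: ClusterParams | None = None
) -> ClusterParams:
    """Equal-variance cluster update: shared sigma2, free rho per group.

    Maximizes the expected complete-data log-likelihood over
    ``(log sigma2, logit-transformed rho_c, rho_n)`` by quasi-Newton search,
    starting from the pooled unconstrained closed form.
    """
    sp = float(w_probe.sum())
    mu_c, s2_c, rho_c, sw_c, sb_c = _weighted_group_update(w_probe, stats, "c")
    mu_n, s2_n, rho_n, sw_n, sb_n = _weighted_group_update(w_probe, stats, "n")
    n_c, n_n = stats["n_c"], stats["n_n"]
    lo_c, lo_n = _rho_lower(n_c), _rho_lower(n_n)

    def _unpack(theta):
        s2 = np.exp(theta[0])
        rc = lo_c + (1.0 - lo_c) * expit(theta[1])
        rn = lo_n + (1.0 - lo_n) * expit(theta[2])
        return s2, rc, rn

    def negq(theta):
        s2, rc, rn = _unpack(theta)
        val = 0.0
        for n, rho, sw, sb in ((n_c, rc, sw_c, sb_c), (n_n, rn, sw_n, sb_n)):
            lam1 = max(s2 * (1.0 - rho), EIGEN_FLOOR)
            lam2 = max(s2 * (1.0 + (n - 1) * rho), EIGEN_FLOOR)
            val += (
                sp * (n - 1) * np.log(lam1)
                + sp * np.log(lam2)
                + sw / lam1
                + sb / lam2
            )
        return 0.5 * val

    # pooled start: responsibility- and size-weighted average of the two
    # unconstrained variances
    s2_0 = (n_c * s2_c + n_n * s2_n) / (n_c + n_n)

    def _z(rho, lo):
        frac = np.clip((rho - lo) / (1.0 - lo), 1e-6, 1.0 - 1e-6)
        return logit(frac)

    theta0 = np.array([np.log(max(s2_0, EIGEN_FLOOR)), _z(rho_c, lo_c), _z(rho_n, lo_n)])
    res = minimize(negq, theta0, method="L-BFGS-B")
    # keep the best of {optimizer result, pooled start, previous parameters}
    # so the M-step never loses likelihood (EM monotonicity)
    candidates = [(negq(theta0), theta0), (res.fun, res.x)]
    if prev is not None:
        theta_prev = np.array(
            [np.log(max(prev.sigma2_c, EIGEN_FLOOR)), _z(prev.rho_c, lo_c), _z(prev.rho_n, lo_n)]
        )
        candidates.append((negq(theta_prev), theta_prev))
    s2, rc, rn = _unpack(min(candidates, key=lambda t: t[0])[1])
    return ClusterParams("EV", mu_c, s2, rc, mu_n, s2, rn)


def _fit_free_cluster(kind: str, w_probe: np.ndarray, stats: dict) -> ClusterParams:
    mu_c, s2_c, rho_c, _, _ = _weighted_group_update(w_probe, stats, "c")
    mu_n, s2_n, rho_n, _, _ = _weighted_group_update(w_probe, stats, "n")
    return ClusterParams(kind, mu_c, s2_c, rho_c, mu_n, s2_n, rho_n)


# ---------------------------------------------------------------------------
# EM steps

def initialize(
    data: ExpressionDataset,
    config: FitConfig,
    rng: np.random.Generator | None = None,
) -> MixtureModel:
    """Initial mixture from the per-probe variance-ratio quartiles.

    Probes are ranked by ``r_g = log(s_c^2 / s_n^2)``; the top quarter seeds
    the OV cluster, the bottom quarter the UV cluster, the middle half the
    EV cluster, with method-of-moments parameters per seed set.  With
    ``init_method="random"`` the variances are then jittered multiplicatively
    by ``exp(U(-0.2, 0.2))``.
    """
    if data.n_probes < 3:
        raise ValueError("need at least 3 probes to initialize 3 clusters")
    stats = group_sufficient_stats(data)
    s_c2, s_n2 = data.sample_variances()
    r = np.log(np.maximum(s_c2, EIGEN_FLOOR) / np.maximum(s_n2, EIGEN_FLOOR))
    g = data.n_probes
    n_tail = max(1, g // 4)
    order = np.argsort(r, kind="stable")
    idx_uv, idx_ov = order[:n_tail], order[-n_tail:]
    idx_ev = order[n_tail:-n_tail]
    if idx_ev.size == 0:
        idx_ev = order  # tiny data: let EV see everything

    def hard(idx):
        w = np.zeros(g)
        w[idx] = 1.0
        return w

    try:
        ov = _fit_free_cluster("OV", hard(idx_ov), stats)
        ev = _fit_ev_cluster(hard(idx_ev), stats)
        uv = _fit_free_cluster("UV", hard(idx_uv), stats)
        clusters = [ov, ev, uv]
        for c in clusters:
            c.validate(data.m_c, data.m_n)
    except Exception:  # degenerate seed sets: fall back to global moments
        w_all = np.ones(g)
        base = _fit_ev_cluster(w_all, stats)
        clusters = [
            replace(base, kind="OV", sigma2_c=1.5 * base.sigma2_c),
            replace(base, kind="EV"),
            replace(base, kind="UV", sigma2_c=0.67 * base.sigma2_c),
        ]
    # nudge the inequality constraints if the moment estimates violate them
    ov, ev, uv = clusters
    if ov.sigma2_c <= ov.sigma2_n:
        ov = replace(ov, sigma2_c=1.1 * ov.sigma2_n)
    if uv.sigma2_c >= uv.sigma2_n:
        uv = replace(uv, sigma2_c=uv.sigma2_n / 1.1)
    clusters = [ov, ev, uv]

    if config.init_method == "random":
        if rng is None:
            rng = np.random.default_rng(config.seed)
        jittered = []
        for c in clusters:
            f_c, f_n = np.exp(rng.uniform(-0.2, 0.2, size=2))
            if c.kind == "EV":
                f_n = f_c
            jittered.append(replace(c, sigma2_c=c.sigma2_c * f_c, sigma2_n=c.sigma2_n * f_n))
        clusters = jittered

    pi = np.array([idx_ov.size, g - idx_ov.size - idx_uv.size, idx_uv.size], dtype=float)
    pi /= pi.sum()
    return MixtureModel(pi, tuple(clusters), data.m_c, data.m_n)


def e_step(
    data: ExpressionDataset,
    model: MixtureModel,
    stats: dict | None = None,
) -> tuple[np.ndarray, float]:
    """Responsibilities and the observed-data log-likelihood."""
    if stats is None:
        stats = group_sufficient_stats(data)
    logf = log_density_matrix(data, model, stats)
    with np.errstate(divide="ignore"):
        a = logf + np.log(model.pi)
    amax = a.max(axis=1)
    if not np.all(np.isfinite(amax)):
        idx = int(np.flatnonzero(~np.isfinite(amax))[0])
        raise FloatingPointError(
            f"all cluster densities vanished for probe {data.probe_ids[idx]!r}"
        )
    shifted = np.exp(a - amax[:, None])
    norm = shifted.sum(axis=1)
    resp = shifted / norm[:, None]
    loglik = float(np.sum(amax + np.log(norm)))
    return resp, loglik


def m_step(
    data: ExpressionDataset,
    responsibilities: np.ndarray,
    prev: MixtureModel | None = None,
    stats: dict | None = None,
) -> MixtureModel:
    """Maximize the expected complete-data log-likelihood.

    A cluster whose total responsibility falls below 1e-8 keeps its previous
    parameters (component starvation) and a warning is logged.
    """
    resp = np.asarray(responsibilities, dtype=float)
    if resp.shape != (data.n_probes, 3):
        raise ValueError("responsibilities must be G x 3")
    if stats is None:
        stats = group_sufficient_stats(data)
    pi = resp.sum(axis=0) / resp.shape[0]
    clusters = []
    for k, kind in enumerate(CLUSTER_KINDS):
        w = resp[:, k]
        if w.sum() < _STARVATION_TOL:
            if prev is None:
                raise ValueError(f"cluster {kind} starved and no previous parameters")
            logger.warning("cluster %s starved (total responsibility %.3g)", kind, w.sum())
            clusters.append(prev.clusters[k])
            continue
        if kind == "EV":
            clusters.append(_fit_ev_cluster(w, stats, prev.clusters[k] if prev else None))
        else:
            clusters.append(_fit_free_cluster(kind, w, stats))
    return MixtureModel(pi, tuple(clusters), data.m_c, data.m_n)


def _repair_constraints(
    data: ExpressionDataset,
    model: MixtureModel,
    stats: dict,
) -> MixtureModel:
    """Relabel clusters by variance ratio so kinds match their constraints.

    The cluster with the largest sigma2_c/sigma2_n becomes OV, the smallest
    UV; the middle one is refitted under the equal-variance constraint if it
    was previously unconstrained.  A vanishing variance gap in the final OV
    or UV cluster is opened by a hair so the strict inequality holds.
    """
    ratios = np.array([c.variance_ratio() for c in model.clusters])
    perm = list(np.argsort(-ratios, kind="stable"))  # descending: OV, EV, UV
    if perm != [0, 1, 2]:
        resp, _ = e_step(data, model, stats)
        pi = model.pi[perm]
        clusters = [model.clusters[p] for p in perm]
        clusters = [replace(c, kind=kind) for c, kind in zip(clusters, CLUSTER_KINDS)]
        if not np.isclose(clusters[1].sigma2_c, clusters[1].sigma2_n):
            clusters[1] = _fit_ev_cluster(resp[:, perm[1]], stats)
        model = MixtureModel(pi, tuple(clusters), model.m_c, model.m_n)
    ov, ev, uv = model.clusters
    eps = 1e-9
    if ov.sigma2_c <= ov.sigma2_n:
        ov = replace(ov, sigma2_c=ov.sigma2_n * (1.0 + eps))
    if uv.sigma2_c >= uv.sigma2_n:
        uv = replace(uv, sigma2_c=uv.sigma2_n / (1.0 + eps))
    return MixtureModel(model.pi, (ov, ev, uv), model.m_c, model.m_n)


def fit(data: ExpressionDataset, config: FitConfig | None = None) -> FitResult:
    """Fit the mixture by EM with restarts; keep the best log-likelihood.

    Each restart alternates E and M steps until the relative log-likelihood
    change drops below ``config.tol`` or ``config.max_iter`` is reached.
    After selecting the best restart, cluster labels are repaired so the
    OV/EV/UV variance ordering holds, and responsibilities are refreshed
    under the final model.
    """
    if config is None:
        config = FitConfig()
    stats = group_sufficient_stats(data)
    rng = np.random.default_rng(config.seed)
    best: tuple[float, MixtureModel, list[float], bool, int] | None = None
    for start in range(config.n_starts):
        method = config.init_method if start == 0 else "random"
        model = initialize(data, replace(config, init_method=method), rng)
        trace: list[float] = []
        ll_prev = -np.inf
        converged = False
        for _ in range(config.max_iter):
            resp, ll = e_step(data, model, stats)
            trace.append(ll)
            if np.isfinite(ll_prev) and abs(ll - ll_prev) / (abs(ll) + 1.0) < config.tol:
                converged = True
                break
            ll_prev = ll
            model = m_step(data, resp, prev=model, stats=stats)
        if not converged:
            warnings.warn(
                f"EM did not converge in {config.max_iter} iterations (restart {start})",
                RuntimeWarning,
                stacklevel=2,
            )
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], model, trace, converged, len(trace))
    assert best is not None
    _, model, trace, converged, n_iter = best
    model = _repair_constraints(data, model, stats)
    resp, _ = e_step(data, model, stats)
    return FitResult(
        model=model,
        responsibilities=resp,
        assignments=assign_clusters(resp),
        loglik_trace=np.asarray(trace),
        converged=converged,
        n_iter=n_iter,
        seed=config.seed,
    )


def assign_clusters(responsibilities: np.ndarray) -> np.ndarray:
    """Maximum-posterior cluster label per probe; ties go to the lowest
    cluster index (OV before EV before UV)."""
    resp = np.asarray(responsibilities, dtype=float)
    if resp.ndim != 2 or resp.shape[1] != 3:
        raise ValueError("responsibilities must be G x 3")
    kinds = np.array(CLUSTER_KINDS, dtype=object)
    return kinds[np.argmax(resp, axis=1)]


def detect_dv(
    data: ExpressionDataset, config: FitConfig | None = None
) -> tuple[DVCall, FitResult]:
    """Run the full model-based detector: fit, assign, flag DV probes.

    Returns the per-probe call (labels, DV flags, variance-difference signs)
    together with the underlying :class:`FitResult`.
    """
    result = fit(data, config)
    labels = result.assignments
    dv_flags = labels != "EV"
    s_c2, s_n2 = data.sample_variances()
    directions = np.sign(s_c2 - s_n2).astype(int)
    call = DVCall(list(data.probe_ids), labels, dv_flags, directions)
    logger.info(
        "gs detection: %d OV, %d EV, %d UV of %d probes (seed=%s)",
        int(np.sum(labels == "OV")),
        int(np.sum(labels == "EV")),
        int(np.sum(labels == "UV")),
        data.n_probes,
        None if config is None else config.seed,
    )
    return call, result
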