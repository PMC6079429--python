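"""EM estimation: monotonicity, oracle equivalence, determinism, recovery."""

import warnings

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import minimize
from scipy.special import expit, logit

from dvclust.em import FitConfig, assign_clusters, detect_dv, e_step, fit, initialize, m_step
from dvclust.model import CLUSTER_KINDS, MixtureModel, posterior_probs
from dvclust.simulate import ScenarioConfig, simulate_dataset

from conftest import dense_cluster_logpdf, make_dataset


def _sim(scenario="SimI", G=1000, seed=0, **kw):
    return simulate_dataset(ScenarioConfig(scenario=scenario, G=G, seed=seed, **kw))


class TestInitialize:
    def test_recovers_well_separated_clusters(self):
        """Variance-ratio start labels most probes correctly on SimI data."""
        data, truth = _sim(seed=3)
        model = initialize(data, FitConfig())
        labels = assign_clusters(posterior_probs(data, model))
        assert np.mean(labels == truth.labels) >= 0.9

    def test_flat_variance_ratio_still_valid(self, rng):
        """All probes with identical case/control variance patterns give an
        EV-dominant but non-degenerate start."""
        row = rng.normal(size=10)
        data = make_dataset(np.tile(row, (12, 1)) + rng.normal(scale=1e-6, size=(12, 10)))
        model = initialize(data, FitConfig())
        model.validate()
        assert model.pi[1] == max(model.pi)
        ov, ev, uv = model.clusters
        assert ov.sigma2_c > ov.sigma2_n and uv.sigma2_c < uv.sigma2_n

    def test_same_seed_same_init(self):
        data, _ = _sim(G=200, seed=5)
        cfg = FitConfig(seed=9, init_method="random")
        a = initialize(data, cfg, np.random.default_rng(9))
        b = initialize(data, cfg, np.random.default_rng(9))
        for ca, cb in zip(a.clusters, b.clusters):
            assert ca == cb
        assert np.array_equal(a.pi, b.pi)


def _interior_model(m_c, m_n):
    """Hand-set mixture with parameters well inside the valid region, so a
    dense-covariance oracle can evaluate every cluster."""
    from dvclust.model import ClusterParams

    clusters = (
        ClusterParams("OV", -0.2, 1.6, 0.1, 0.2, 0.5, 0.2),
        ClusterParams("EV", 0.0, 1.0, 0.05, 0.0, 1.0, 0.1),
        ClusterParams("UV", 0.1, 0.3, 0.05, -0.1, 1.7, 0.0),
    )
    return MixtureModel(np.array([0.3, 0.5, 0.2]), clusters, m_c, m_n)


class TestESstep:
    def test_single_component_loglik_is_cluster_density_sum(self, rng):
        data = make_dataset(rng.normal(size=(6, 8)))
        model = _interior_model(4, 4)
        model.pi = np.array([1.0, 0.0, 0.0])
        _, ll = e_step(data, model)
        direct = sum(
            dense_cluster_logpdf(
                data.case_values[g], data.control_values[g], model.clusters[0]
            )
            for g in range(6)
        )
        assert ll == pytest.approx(direct, abs=1e-8)

    def test_loglik_matches_dense_mixture_oracle(self, rng):
        """Observed-data log-likelihood vs. brute-force dense evaluation."""
        data = make_dataset(rng.normal(size=(5, 7)), m_c=4)
        model = _interior_model(4, 3)
        _, ll = e_step(data, model)
        direct = 0.0
        for g in range(5):
            dens = [
                np.exp(dense_cluster_logpdf(data.case_values[g], data.control_values[g], c))
                for c in model.clusters
            ]
            direct += np.log(np.dot(model.pi, dens))
        assert ll == pytest.approx(direct, abs=1e-8)

    def test_probe_permutation_equivariance(self, rng):
        data = make_dataset(rng.normal(size=(9, 8)))
        model = _interior_model(4, 4)
        resp, _ = e_step(data, model)
        perm = rng.permutation(9)
        shuffled = make_dataset(data.values[perm])
        resp_p, _ = e_step(shuffled, model)
        assert np.allclose(resp_p, resp[perm])


def _mle_exchangeable_oracle(block):
    """Direct numerical MLE of (mu, sigma2, rho) for one exchangeable-normal
    sample of G i.i.d. rows (independent oracle for the M-step closed form)."""
    g, n = block.shape
    lo = -1.0 / (n - 1)

    def negll(theta):
        mu, s2 = theta[0], np.exp(theta[1])
        rho = lo + (1 - lo) * expit(theta[2])
        cov = s2 * ((1 - rho) * np.eye(n) + rho * np.ones((n, n)))
        return -np.sum(stats.multivariate_normal(np.full(n, mu), cov).logpdf(block))

    res = minimize(negll, np.array([block.mean(), np.log(block.var()), 0.0]),
                   method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
    mu, s2 = res.x[0], np.exp(res.x[1])
    rho = lo + (1 - lo) * expit(res.x[2])
    return mu, s2, rho


class TestMStep:
    def test_single_cluster_update_matches_numerical_mle(self, rng):
        """Closed-form weighted update equals direct likelihood maximization
        when all responsibility sits on one cluster."""
        from dvclust.simulate import sample_exchangeable_block

        case = sample_exchangeable_block(6, 0.3, 1.4, 0.25, rng, size=40)
        ctrl = sample_exchangeable_block(5, -0.2, 0.7, 0.1, rng, size=40)
        data = make_dataset(np.hstack([case, ctrl]), m_c=6)
        resp = np.zeros((40, 3))
        resp[:, 0] = 1.0
        prev = initialize(data, FitConfig())
        model = m_step(data, resp, prev=prev)
        ov = model.clusters[0]
        for block, got in ((case, (ov.mu_c, ov.sigma2_c, ov.rho_c)),
                           (ctrl, (ov.mu_n, ov.sigma2_n, ov.rho_n))):
            mu, s2, rho = _mle_exchangeable_oracle(block)
            assert got[0] == pytest.approx(mu, abs=1e-4)
            assert got[1] == pytest.approx(s2, abs=1e-4)
            assert got[2] == pytest.approx(rho, abs=1e-4)

    def test_pi_equals_responsibility_column_means(self, rng):
        data = make_dataset(rng.normal(size=(15, 8)))
        resp = rng.dirichlet(np.ones(3), size=15)
        model = m_step(data, resp)
        assert np.allclose(model.pi, resp.mean(axis=0))
        assert model.pi.sum() == pytest.approx(1.0)

    def test_zero_within_group_scatter_survives(self, rng):
        """Identical case values per probe hit the eigenvalue floor, not a crash."""
        case = np.tile(rng.normal(size=(10, 1)), (1, 5))
        ctrl = rng.normal(size=(10, 4))
        data = make_dataset(np.hstack([case, ctrl]), m_c=5)
        resp = np.full((10, 3), 1 / 3)
        model = m_step(data, resp)
        for c in model.clusters:
            assert c.sigma2_c > 0 and c.sigma2_n > 0

    def test_starved_cluster_keeps_previous_parameters(self, rng):
        data = make_dataset(rng.normal(size=(10, 8)))
        prev = initialize(data, FitConfig())
        resp = np.zeros((10, 3))
        resp[:, 1] = 1.0
        model = m_step(data, resp, prev=prev)
        assert model.clusters[0] == prev.clusters[0]
        assert model.clusters[2] == prev.clusters[2]


class TestFit:
    def test_loglik_trace_monotone_on_random_datasets(self, rng):
        for _ in range(20):
            data = make_dataset(rng.normal(size=(30, 10)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = fit(data, FitConfig(n_starts=1, max_iter=50, seed=1))
            assert np.all(np.diff(res.loglik_trace) >= -1e-8)

    def test_same_seed_identical_result(self):
        data, _ = _sim(G=150, seed=8)
        r1 = fit(data, FitConfig(seed=4, n_starts=2))
        r2 = fit(data, FitConfig(seed=4, n_starts=2))
        assert r1.loglik == r2.loglik
        assert np.array_equal(r1.responsibilities, r2.responsibilities)
        assert np.array_equal(r1.assignments, r2.assignments)

    def test_simI_recovers_mixing_proportions_and_partition(self):
        data, truth = _sim(G=1000, seed=21)
        res = fit(data, FitConfig(seed=21))
        assert np.all(np.abs(res.model.pi - np.array([0.31, 0.58, 0.11])) <= 0.05)
        from dvclust.evaluate import jaccard_index

        assert jaccard_index(truth.labels, res.assignments) >= 0.8

    def test_final_loglik_matches_direct_mixture_maximization(self, rng):
        """On a small toy with an interior optimum, the EM solution agrees
        with (and is not beaten by) a direct simplex maximization of the
        observed-data likelihood built on dense covariances."""
        data, _ = _sim(G=15, m_c=4, m_n=3, seed=0)
        cfg = FitConfig(n_starts=1, tol=1e-10, max_iter=3000, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit(data, cfg)

        lo_c, lo_n = -1.0 / 3, -1.0 / 2

        def unpack(theta):
            pi = np.exp(theta[:3] - theta[:3].max())
            pi = pi / pi.sum()
            out = []
            j = 3
            for k in range(3):
                mu_c, mu_n = theta[j], theta[j + 1]
                s2_c = np.exp(theta[j + 2])
                s2_n = s2_c if k == 1 else np.exp(theta[j + 5])
                rho_c = lo_c + (1 - lo_c) * expit(theta[j + 3])
                rho_n = lo_n + (1 - lo_n) * expit(theta[j + 4])
                out.append((mu_c, s2_c, rho_c, mu_n, s2_n, rho_n))
                j += 5 if k == 1 else 6
            return pi, out

        def dense_block_logpdf(block, mu, s2, rho):
            # generic dense-covariance MVN logpdf for all probes at once
            n = block.shape[1]
            cov = s2 * ((1 - rho) * np.eye(n) + rho * np.ones((n, n)))
            L = np.linalg.cholesky(cov)
            dev = block - mu
            half = np.linalg.solve(L, dev.T)
            quad = np.sum(half**2, axis=0)
            logdet = 2 * np.sum(np.log(np.diag(L)))
            return -0.5 * (n * np.log(2 * np.pi) + logdet + quad)

        def negll(theta):
            pi, params = unpack(theta)
            logf = np.column_stack([
                dense_block_logpdf(data.case_values, mu_c, s2_c, rho_c)
                + dense_block_logpdf(data.control_values, mu_n, s2_n, rho_n)
                for (mu_c, s2_c, rho_c, mu_n, s2_n, rho_n) in params
            ])
            a = logf + np.log(pi)
            amax = a.max(axis=1)
            return -float(np.sum(amax + np.log(np.exp(a - amax[:, None]).sum(axis=1))))

        def pack(model):
            theta = [np.log(model.pi[0]), np.log(model.pi[1]), np.log(model.pi[2])]
            for k, c in enumerate(model.clusters):
                z_c = logit(np.clip((c.rho_c - lo_c) / (1 - lo_c), 1e-9, 1 - 1e-9))
                z_n = logit(np.clip((c.rho_n - lo_n) / (1 - lo_n), 1e-9, 1 - 1e-9))
                theta += [c.mu_c, c.mu_n, np.log(c.sigma2_c), z_c, z_n]
                if k != 1:
                    theta += [np.log(c.sigma2_n)]
            return np.array(theta)

        # polish the EM optimum: direct optimization cannot improve it by
        # more than the stated tolerance
        direct = minimize(negll, pack(res.model), method="Nelder-Mead",
                          options={"maxiter": 20000, "xatol": 1e-7, "fatol": 1e-9})
        assert res.loglik >= -direct.fun - 1e-3

    def test_reported_kinds_respect_variance_ordering(self, rng):
        for seed in range(3):
            data = make_dataset(rng.normal(size=(40, 12)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = fit(data, FitConfig(seed=seed, n_starts=2, max_iter=200))
            ov, ev, uv = res.model.clusters
            assert ov.sigma2_c > ov.sigma2_n
            assert uv.sigma2_c < uv.sigma2_n
            assert ev.sigma2_c == pytest.approx(ev.sigma2_n)
            assert ov.variance_ratio() >= ev.variance_ratio() >= uv.variance_ratio()


class TestAssignClusters:
    def test_argmax_and_tie_break(self):
        resp = np.array([[0.5, 0.3, 0.2], [1 / 3, 1 / 3, 1 / 3], [0.1, 0.4, 0.5]])
        assert list(assign_clusters(resp)) == ["OV", "OV", "UV"]

    def test_matches_brute_force_rowwise_max(self, rng):
        resp = rng.dirichlet(np.ones(3), size=50)
        labels = assign_clusters(resp)
        kinds = np.array(CLUSTER_KINDS, dtype=object)
        for g in range(50):
            assert labels[g] == kinds[int(np.argmax(resp[g]))]


class TestDetectDV:
    def test_simI_ov_count_near_truth(self):
        data, truth = _sim(seed=13)
        call, _ = detect_dv(data, FitConfig(seed=13))
        n_ov = int(np.sum(call.labels == "OV"))
        assert abs(n_ov - 310) <= 50  # binomial-noise band around the true 310

    def test_directions_follow_sample_variances(self):
        data, _ = _sim(G=100, seed=17)
        call, _ = detect_dv(data, FitConfig(seed=17, n_starts=1))
        s_c2, s_n2 = data.sample_variances()
        assert np.array_equal(call.directions, np.sign(s_c2 - s_n2).astype(int))
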