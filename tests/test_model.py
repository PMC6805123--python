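import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from herbiscape.grid import build_adjacency
from herbiscape.model import (
    AbundanceData,
    DesignMatrices,
    ModelConfig,
    ModelState,
    SpatialModel,
    build_design_matrix,
    build_rsr_basis,
    cell_integrated_loglik,
    negbin_logpmf,
    total_log_posterior,
)


class TestNegBinLogPmf:
    def test_normalizes(self):
        n = np.arange(1001)
        total = np.exp(negbin_logpmf(n, 3.0, 2.0)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_geometric_special_case(self):
        # phi = 1 is geometric with success prob phi/(phi+lam) = 1/4
        assert np.exp(negbin_logpmf(2, 3.0, 1.0)) == pytest.approx(
            0.25 * 0.75**2, abs=1e-12
        )

    def test_poisson_limit(self):
        n = np.arange(21)
        nb = np.exp(negbin_logpmf(n, 3.0, 1e8))
        poisson = st.poisson.pmf(n, 3.0)
        assert np.max(np.abs(nb - poisson)) < 1e-6

    def test_matches_scipy_parameterization(self, rng):
        # independent route: scipy's nbinom with n=phi, p=phi/(phi+lam)
        for _ in range(20):
            lam = rng.uniform(0.2, 8.0)
            phi = rng.uniform(0.3, 6.0)
            k = rng.integers(0, 30)
            expected = st.nbinom.logpmf(k, phi, phi / (phi + lam))
            assert negbin_logpmf(k, lam, phi) == pytest.approx(expected, rel=1e-10)

    def test_domain_validation(self):
        with pytest.raises(ValueError):
            negbin_logpmf(1, -1.0, 2.0)
        with pytest.raises(ValueError):
            negbin_logpmf(1, 1.0, 0.0)


def _naive_cell_loglik(y, rate, lam, phi, n_max):
    """Brute-force oracle: direct probability-space summation."""
    total = 0.0
    for n in range(n_max + 1):
        p = np.exp(st.nbinom.logpmf(n, phi, phi / (phi + lam)))
        for yi, ri in zip(y, rate):
            p *= st.poisson.pmf(yi, n * ri)
        total += p
    return np.log(total)


class TestCellIntegratedLoglik:
    def test_empty_cell_contributes_zero(self):
        assert cell_integrated_loglik([], [], 2.0, 1.0) == 0.0

    def test_geometric_closed_form(self):
        # one site, y=0, gamma*d=1, lam=phi=1: sum (1/2)^(N+1) e^-N
        value = cell_integrated_loglik([0], [1.0], 1.0, 1.0, n_max=1000)
        expected = np.log(0.5 / (1 - np.exp(-1.0) / 2))
        assert value == pytest.approx(expected, abs=1e-10)

    def test_matches_bruteforce_on_random_cells(self, rng):
        for _ in range(50):
            n_sites = rng.integers(1, 4)
            y = rng.poisson(3.0, n_sites)
            rate = rng.uniform(0.2, 3.0, n_sites)
            lam = rng.uniform(0.5, 5.0)
            phi = rng.uniform(0.5, 5.0)
            ours = cell_integrated_loglik(y, rate, lam, phi, n_max=100)
            assert ours == pytest.approx(
                _naive_cell_loglik(y, rate, lam, phi, 100), abs=1e-10
            )

    def test_nmax_beyond_tail_changes_nothing(self):
        y, rate, lam, phi = [4, 2], [0.8, 1.1], 3.0, 2.0
        # 1 - 1e-12 NegBin quantile
        qtail = int(st.nbinom.ppf(1 - 1e-12, phi, phi / (phi + lam)))
        base = cell_integrated_loglik(y, rate, lam, phi, n_max=qtail)
        bigger = cell_integrated_loglik(y, rate, lam, phi, n_max=qtail + 200)
        assert abs(bigger - base) < 1e-8

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            cell_integrated_loglik([-1], [1.0], 1.0, 1.0)


class TestDesignMatrix:
    def test_no_quadratics_gives_intercept_plus_covariates(self):
        table = pd.DataFrame({"a": [0.1, -0.2, 0.1], "b": [1.0, 0.0, -1.0]})
        x, names, quad = build_design_matrix(table)
        assert x.shape == (3, 3)
        assert names == ["intercept", "a", "b"]
        assert quad == {}
        assert np.all(x[:, 0] == 1.0)

    def test_quadratic_column_is_elementwise_square(self):
        z = np.array([-1.2247, 0.0, 1.2247])
        table = pd.DataFrame({"z": z})
        x, names, quad = build_design_matrix(table, ["z"])
        assert names == ["intercept", "z", "z^2"]
        assert quad == {"z^2": "z"}
        assert np.allclose(x[:, 2], [1.49989009, 0.0, 1.49989009])
        assert np.allclose(x[:, 2], z**2)

    def test_missing_quadratic_parent_raises(self):
        with pytest.raises(KeyError):
            build_design_matrix(pd.DataFrame({"a": [1.0, 2.0]}), ["zz"])


def assert_spans_match(k, eigenvalues, oracle_vecs, tol=1e-8):
    """Columns agree up to sign; within degenerate eigenvalue groups the
    spanned subspaces (projectors) must agree instead."""
    start = 0
    vals = np.asarray(eigenvalues)
    for end in range(1, len(vals) + 1):
        if end < len(vals) and abs(vals[end] - vals[end - 1]) < 1e-8:
            continue
        block_ours = k[:, start:end]
        block_oracle = oracle_vecs[:, start:end]
        p_ours = block_ours @ block_ours.T
        p_oracle = block_oracle @ block_oracle.T
        assert np.max(np.abs(p_ours - p_oracle)) < tol
        start = end


class TestRSRBasis:
    def test_orthogonality_invariants(self, rng):
        a, q = build_adjacency((6, 6))
        x = np.column_stack([np.ones(36), rng.standard_normal((36, 2))])
        basis = build_rsr_basis(x, a, q, rank=5)
        assert np.max(np.abs(basis.k.T @ x)) < 1e-8
        assert np.allclose(basis.k.T @ basis.k, np.eye(5), atol=1e-8)
        # K'QK symmetric positive definite
        eigs = np.linalg.eigvalsh(basis.prior_precision)
        assert np.all(eigs > 0)

    def test_intercept_only_columns_sum_to_zero(self):
        a, q = build_adjacency((3, 3))
        x = np.ones((9, 1))
        basis = build_rsr_basis(x, a, q, rank=2)
        assert np.max(np.abs(basis.k.sum(axis=0))) < 1e-8

    def test_matches_dense_eigendecomposition_oracle(self):
        a, q = build_adjacency((3, 3))
        x = np.ones((9, 1))
        rank = 2
        basis = build_rsr_basis(x, a, q, rank=rank)
        # oracle: independent dense construction via lstsq projector
        a_dense = a.toarray()
        proj = np.eye(9) - x @ np.linalg.lstsq(x, np.eye(9), rcond=None)[0]
        op = proj @ a_dense @ proj
        vals, vecs = np.linalg.eigh((op + op.T) / 2)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        assert np.allclose(basis.eigenvalues, vals[:rank], atol=1e-10)
        assert_spans_match(basis.k, basis.eigenvalues, vecs[:, :rank])

    def test_rank_beyond_positive_eigenvalues_rejected(self):
        a, q = build_adjacency((2, 2))
        with pytest.raises(ValueError):
            build_rsr_basis(np.ones((4, 1)), a, q, rank=4)

    def test_singular_design_rejected(self):
        a, q = build_adjacency((3, 3))
        x = np.ones((9, 2))  # duplicated intercept
        with pytest.raises(np.linalg.LinAlgError):
            build_rsr_basis(x, a, q, rank=2)


def _toy_model(rng, n_y=4, n_x=5, n_sites=8, rank=3):
    g = n_y * n_x
    x_lambda = np.column_stack([np.ones(g), rng.standard_normal((g, 2))])
    x_gamma = np.column_stack([np.ones(n_sites), rng.standard_normal(n_sites)])
    cells = rng.integers(0, g, n_sites)
    design = DesignMatrices(
        x_lambda=x_lambda,
        x_gamma=x_gamma,
        lambda_names=["intercept", "a", "b"],
        gamma_names=["intercept", "t"],
        effort=rng.uniform(5, 20, n_sites),
        cell_index=cells,
    )
    a, q = build_adjacency((n_y, n_x))
    basis = build_rsr_basis(x_lambda, a, q, rank=rank)
    y = rng.poisson(3.0, n_sites)
    data = AbundanceData(design=design, y=y)
    state = ModelState(
        beta_lambda=np.array([0.4, 0.3, -0.2]),
        beta_gamma=np.array([-1.0, 0.1]),
        eps=0.1 * rng.standard_normal(n_sites),
        delta=0.2 * rng.standard_normal(rank),
        tau=1.3,
        phi=2.1,
        sigma=0.5,
    )
    return data, basis, state


class TestTotalLogPosterior:
    def test_out_of_support_sigma_is_minus_inf(self, rng):
        data, basis, state = _toy_model(rng)
        state.sigma = 120.0
        assert total_log_posterior(state, data, basis, ModelConfig()) == -np.inf

    def test_zero_data_equals_prior_alone(self, rng):
        data, basis, state = _toy_model(rng)
        # no cameras: empty site table contributes nothing
        design = data.design
        empty = DesignMatrices(
            x_lambda=design.x_lambda,
            x_gamma=design.x_gamma[:0],
            lambda_names=design.lambda_names,
            gamma_names=design.gamma_names,
            effort=design.effort[:0],
            cell_index=design.cell_index[:0],
        )
        nodata = AbundanceData(design=empty, y=np.array([]))
        state.eps = np.array([])
        config = ModelConfig()
        model = SpatialModel(data=nodata, basis=basis, config=config)
        assert total_log_posterior(state, nodata, basis, config) == pytest.approx(
            model.log_prior(state), rel=1e-12
        )

    def test_matches_independent_term_by_term_oracle(self, rng):
        data, basis, state = _toy_model(rng)
        config = ModelConfig()
        ours = total_log_posterior(state, data, basis, config)

        # oracle: sum the same terms cell by cell in a different order,
        # with scipy densities for every prior
        design = data.design
        lam = np.exp(design.x_lambda @ state.beta_lambda + basis.k @ state.delta)
        gamma = np.exp(design.x_gamma @ state.beta_gamma + state.eps)
        rate = gamma * design.effort
        loglik = 0.0
        for j in sorted(set(design.cell_index)):
            mask = design.cell_index == j
            loglik += cell_integrated_loglik(
                data.y[mask], rate[mask], lam[j], state.phi, config.n_max
            )
        beta = np.concatenate([state.beta_lambda, state.beta_gamma])
        prior = st.norm.logpdf(beta, 0, np.sqrt(1 / config.beta_precision)).sum()
        prior += st.norm.logpdf(state.eps, 0, state.sigma).sum()
        prior += np.log(1 / config.sigma_upper)
        cov = np.linalg.inv(state.tau * basis.prior_precision)
        prior += st.multivariate_normal.logpdf(state.delta, mean=None, cov=cov)
        prior += st.gamma.logpdf(state.tau, config.tau_shape, scale=1 / config.tau_rate)
        prior += st.gamma.logpdf(state.phi, config.phi_shape, scale=1 / config.phi_rate)
        assert ours == pytest.approx(loglik + prior, abs=1e-9)
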