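"""Fitting interface: a scikit-learn style estimator around the model.

:class:`SpatialAbundanceModel` bundles design construction, the RSR basis,
the blocked adaptive-Metropolis sampler and posterior products behind a
``fit`` / ``predict``-shaped surface.  The sampler updates, per iteration:

* one adaptive-covariance block over (beta_lambda, beta_gamma) — joint so
  that the weakly identified intercept ridge between abundance and
  detection scales mixes;
* one adaptive-covariance block over the Moran-basis coefficients delta;
* all site errors eps by simultaneous per-cell Metropolis (cells are
  conditionally independent given the rest, so per-cell accept/reject of a
  joint proposal for the sites of that cell is a valid kernel);
* random-walk scalars for phi (NegBin dispersion), sigma (site-error SD)
  and tau (RSR precision).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .grid import LandscapeGrid, build_adjacency, is_connected
from .mcmc import (
    AdaptiveCovProposal,
    AdaptiveScale,
    PosteriorSamples,
    gelman_rubin,
    summarize_posterior,
)
from .model import (
    AbundanceData,
    DesignMatrices,
    ModelConfig,
    ModelState,
    SpatialModel,
    build_design_matrix,
    build_rsr_basis,
)

__all__ = ["CameraSurvey", "SpatialAbundanceModel", "posterior_predictive_pvalue"]


@dataclass
class CameraSurvey:
    """Per-site camera-trap data for one species.

    ``table`` must contain ``site_id``, ``cell`` (0-based grid cell index),
    ``effort_days`` and ``count`` columns plus one column per standardized
    site covariate named in ``covariate_names``.
    """

    table: pd.DataFrame
    covariate_names: list[str]

    REQUIRED = ("site_id", "cell", "effort_days", "count")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"survey table lacks required column {col!r}")
        if (self.table["effort_days"] < 1).any():
            raise ValueError("all effort values must be >= 1 day")
        if (self.table["count"] < 0).any():
            raise ValueError("counts must be non-negative")
        for name in self.covariate_names:
            if name not in self.table.columns:
                raise ValueError(f"survey table lacks covariate column {name!r}")

    @property
    def n_sites(self) -> int:
        return len(self.table)


class SpatialAbundanceModel(BaseEstimator):
    """Hierarchical Poisson / Negative-Binomial / RSR abundance model.

    Parameters mirror the model configuration: ``n_max`` truncates the
    latent-abundance sum, ``basis_rank`` sets the number of Moran
    eigenvectors (default ~10% of cells), ``quadratic_lambda`` /
    ``quadratic_gamma`` name standardized covariates whose squares enter the
    respective design, and the remaining arguments are prior
    hyper-parameters and sampler settings.  The study-scale sampler settings
    (3 chains x 500,000 iterations, 400,000 burn-in, thinning 20) are
    available by passing them explicitly; the defaults are desk-scale.

    Fitted attributes (trailing underscore): ``samples_``, ``summary_``,
    ``rhat_``, ``acceptance_``, ``design_``, ``basis_``, ``model_``.
    """

    def __init__(
        self,
        n_max: int = 100,
        basis_rank: int | None = None,
        adjacency_rule: str = "rook",
        quadratic_lambda: tuple[str, ...] = (),
        quadratic_gamma: tuple[str, ...] = (),
        n_iter: int = 20_000,
        n_burn: int = 10_000,
        thin: int = 10,
        n_chains: int = 3,
        beta_precision: float = 1e-3,
        sigma_upper: float = 100.0,
        tau_shape: float = 0.1,
        tau_rate: float = 0.1,
        phi_shape: float = 0.1,
        phi_rate: float = 0.1,
        store_eps: bool = True,
        random_state: int | None = None,
    ):
        self.n_max = n_max
        self.basis_rank = basis_rank
        self.adjacency_rule = adjacency_rule
        self.quadratic_lambda = quadratic_lambda
        self.quadratic_gamma = quadratic_gamma
        self.n_iter = n_iter
        self.n_burn = n_burn
        self.thin = thin
        self.n_chains = n_chains
        self.beta_precision = beta_precision
        self.sigma_upper = sigma_upper
        self.tau_shape = tau_shape
        self.tau_rate = tau_rate
        self.phi_shape = phi_shape
        self.phi_rate = phi_rate
        self.store_eps = store_eps
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            n_max=self.n_max,
            basis_rank=self.basis_rank,
            adjacency_rule=self.adjacency_rule,
            beta_precision=self.beta_precision,
            sigma_upper=self.sigma_upper,
            tau_shape=self.tau_shape,
            tau_rate=self.tau_rate,
            phi_shape=self.phi_shape,
            phi_rate=self.phi_rate,
        )

    def build(self, survey: CameraSurvey, grid: LandscapeGrid) -> SpatialModel:
        """Assemble designs, RSR basis and the likelihood without sampling."""
        if self.n_burn >= self.n_iter:
            raise ValueError("n_burn must be smaller than n_iter")
        cov_table = grid.covariate_table()
        x_lambda, lam_names, quad_l = build_design_matrix(
            cov_table, self.quadratic_lambda
        )
        site_cov = survey.table[list(survey.covariate_names)]
        x_gamma, gam_names, quad_g = build_design_matrix(
            site_cov, self.quadratic_gamma
        )
        design = DesignMatrices(
            x_lambda=x_lambda,
            x_gamma=x_gamma,
            lambda_names=lam_names,
            gamma_names=gam_names,
            effort=survey.table["effort_days"].to_numpy(dtype=float),
            cell_index=survey.table["cell"].to_numpy(dtype=int),
            quadratic_of={**quad_l, **quad_g},
        )
        adjacency, icar_q = build_adjacency(grid, self.adjacency_rule)
        if not is_connected(adjacency):
            import warnings

            warnings.warn("landscape grid is not connected", stacklevel=2)
        basis = build_rsr_basis(x_lambda, adjacency, icar_q, self.basis_rank)
        data = AbundanceData(design=design, y=survey.table["count"].to_numpy(float))
        return SpatialModel(data=data, basis=basis, config=self._model_config())

    # ------------------------------------------------------------------
    def fit(self, survey: CameraSurvey, grid: LandscapeGrid) -> "SpatialAbundanceModel":
        """Run the MCMC and store posterior draws and diagnostics."""
        model = self.build(survey, grid)
        self.model_ = model
        self.design_ = model.data.design
        self.basis_ = model.basis
        self.grid_ = grid

        init = _glm_initial_state(model)
        names = self._param_names(model)
        n_kept = (self.n_iter - self.n_burn) // self.thin
        draws = np.empty((self.n_chains, n_kept, len(names)))
        ss = np.random.SeedSequence(self.random_state)
        acc_all: list[dict[str, float]] = []
        for c, child in enumerate(ss.spawn(self.n_chains)):
            rng = np.random.default_rng(child)
            chain, acc = _run_chain(
                model,
                _jitter(init, rng),
                self.n_iter,
                self.n_burn,
                self.thin,
                rng,
                self._pack_factory(model),
            )
            draws[c] = chain
            acc_all.append(acc)
        acceptance = {
            k: float(np.mean([a[k] for a in acc_all])) for k in acc_all[0]
        }
        self.samples_ = PosteriorSamples(
            draws=draws,
            names=names,
            n_iter=self.n_iter,
            n_burn=self.n_burn,
            thin=self.thin,
            seed=self.random_state,
            acceptance=acceptance,
        )
        self.acceptance_ = acceptance
        beta_names = self.samples_.select("beta_lambda") + self.samples_.select(
            "beta_gamma"
        )
        scalar_names = beta_names + ["phi", "sigma", "tau"]
        self.rhat_ = pd.Series(
            {n: gelman_rubin(self.samples_.get(n)) for n in scalar_names},
            name="r_hat",
        )
        self.summary_ = summarize_posterior(self.samples_, names=scalar_names)
        return self

    # ------------------------------------------------------------------
    def _param_names(self, model: SpatialModel) -> list[str]:
        d = model.data.design
        names = [f"beta_lambda[{n}]" for n in d.lambda_names]
        names += [f"beta_gamma[{n}]" for n in d.gamma_names]
        names += ["phi", "sigma", "tau"]
        names += [f"delta[{i}]" for i in range(model.basis.rank)]
        if self.store_eps:
            names += [f"eps[{i}]" for i in range(d.n_sites)]
        return names

    def _pack_factory(self, model: SpatialModel):
        store_eps = self.store_eps

        def pack(state: ModelState) -> np.ndarray:
            parts = [
                state.beta_lambda,
                state.beta_gamma,
                [state.phi, state.sigma, state.tau],
                state.delta,
            ]
            if store_eps:
                parts.append(state.eps)
            return np.concatenate([np.atleast_1d(np.asarray(p, float)) for p in parts])

        return pack

    def state_from_draw(self, draw: np.ndarray) -> ModelState:
        """Rebuild a ModelState from one stored draw (site errors included
        only if they were stored; otherwise zeros)."""
        d = self.design_
        p = d.x_lambda.shape[1]
        q = d.x_gamma.shape[1]
        r = self.basis_.rank
        s = d.n_sites
        off = 0
        beta_lambda = draw[off : off + p]; off += p
        beta_gamma = draw[off : off + q]; off += q
        phi, sigma, tau = draw[off : off + 3]; off += 3
        delta = draw[off : off + r]; off += r
        eps = draw[off : off + s] if self.store_eps else np.zeros(s)
        return ModelState(
            beta_lambda=beta_lambda.copy(),
            beta_gamma=beta_gamma.copy(),
            eps=np.asarray(eps, float).copy(),
            delta=delta.copy(),
            tau=float(tau),
            phi=float(phi),
            sigma=float(sigma),
        )


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _glm_initial_state(model: SpatialModel) -> ModelState:
    """Poisson GLM ignoring the latent layer: regress counts on the cell and
    site covariates with a log effort offset; the fitted coefficients seed
    beta, everything else starts at neutral values inside the support."""
    import statsmodels.api as sm

    d = model.data.design
    x_cells = d.x_lambda[d.cell_index]
    x_site = d.x_gamma[:, 1:]  # drop the duplicate intercept
    exog = np.hstack([x_cells, x_site])
    p = d.x_lambda.shape[1]
    q = d.x_gamma.shape[1]
    beta_lambda = np.zeros(p)
    beta_gamma = np.zeros(q)
    try:
        glm = sm.GLM(
            model.data.y,
            exog,
            family=sm.families.Poisson(),
            offset=np.log(d.effort),
        ).fit(maxiter=50)
        coef = np.asarray(glm.params)
        beta_lambda[:] = coef[:p]
        beta_gamma[1:] = coef[p:]
    except Exception:
        pass  # zeros are a valid, if slow, start
    return ModelState(
        beta_lambda=beta_lambda,
        beta_gamma=beta_gamma,
        eps=np.zeros(d.n_sites),
        delta=np.zeros(model.basis.rank),
        tau=1.0,
        phi=1.0,
        sigma=1.0,
    )


def _jitter(state: ModelState, rng: np.random.Generator) -> ModelState:
    out = state.copy()
    out.beta_lambda = out.beta_lambda + 0.1 * rng.standard_normal(out.beta_lambda.size)
    out.beta_gamma = out.beta_gamma + 0.1 * rng.standard_normal(out.beta_gamma.size)
    out.phi = float(out.phi * np.exp(0.2 * rng.standard_normal()))
    out.sigma = float(out.sigma * np.exp(0.2 * rng.standard_normal()))
    out.tau = float(out.tau * np.exp(0.2 * rng.standard_normal()))
    return out


# ---------------------------------------------------------------------------
# the blocked sampler
# ---------------------------------------------------------------------------

def _run_chain(
    model: SpatialModel,
    state: ModelState,
    n_iter: int,
    n_burn: int,
    thin: int,
    rng: np.random.Generator,
    pack,
) -> tuple[np.ndarray, dict[str, float]]:
    lik = model.likelihood
    d = model.data.design
    p = d.x_lambda.shape[1]
    qg = d.x_gamma.shape[1]
    beta_block = AdaptiveCovProposal(p + qg)
    delta_block = AdaptiveCovProposal(model.basis.rank)
    eps_scale = AdaptiveScale(0.5, target=0.35)
    phi_scale = AdaptiveScale(0.5, target=0.35)
    sigma_scale = AdaptiveScale(0.5, target=0.35)
    tau_scale = AdaptiveScale(0.5, target=0.35)

    # caches
    lam_cam = np.exp(lik.x_lambda_cam @ state.beta_lambda + model.k_cam @ state.delta)
    rates = lik.site_rates(state)
    per_cell = lik.cell_loglik_values(lam_cam, rates, state.phi)
    if not np.isfinite(model.log_prior(state)):
        state.phi = max(state.phi, 0.5)
        state.sigma = min(max(state.sigma, 0.5), model.config.sigma_upper / 2)
        state.tau = max(state.tau, 0.5)
    ll = float(per_cell.sum())

    n_kept = (n_iter - n_burn) // thin
    out = np.empty((n_kept, pack(state).size))
    kept = 0
    acc_ct = {k: 0.0 for k in ("beta", "delta", "eps", "phi", "sigma", "tau")}
    prop_ct = {k: 0 for k in acc_ct}
    eps_prop_sites = 0

    for t in range(n_iter):
        adapting = t < n_burn
        if t == n_burn:
            beta_block.freeze()
            delta_block.freeze()

        # ---- joint regression-coefficient block
        cur = np.concatenate([state.beta_lambda, state.beta_gamma])
        prop = beta_block.propose(cur, rng)
        bl, bg = prop[:p], prop[p:]
        lam_prop = np.exp(lik.x_lambda_cam @ bl + model.k_cam @ state.delta)
        rates_prop = np.exp(d.x_gamma @ bg + state.eps) * d.effort
        per_cell_prop = lik.cell_loglik_values(lam_prop, rates_prop, state.phi)
        ll_prop = float(per_cell_prop.sum())
        dprior = -0.5 * model.config.beta_precision * (prop @ prop - cur @ cur)
        accept = np.log(rng.uniform()) < (ll_prop - ll) + dprior
        if accept:
            state.beta_lambda, state.beta_gamma = bl.copy(), bg.copy()
            lam_cam, rates, per_cell, ll = lam_prop, rates_prop, per_cell_prop, ll_prop
        if adapting:
            beta_block.adapt_scale(float(accept))
            beta_block.observe(np.concatenate([state.beta_lambda, state.beta_gamma]))
        else:
            prop_ct["beta"] += 1
            acc_ct["beta"] += int(accept)

        # ---- spatial basis coefficients
        m_prec = model.basis.prior_precision
        cur = state.delta
        prop = delta_block.propose(cur, rng)
        lam_prop = np.exp(lik.x_lambda_cam @ state.beta_lambda + model.k_cam @ prop)
        per_cell_prop = lik.cell_loglik_values(lam_prop, rates, state.phi)
        ll_prop = float(per_cell_prop.sum())
        dprior = -0.5 * state.tau * (prop @ (m_prec @ prop) - cur @ (m_prec @ cur))
        accept = np.log(rng.uniform()) < (ll_prop - ll) + dprior
        if accept:
            state.delta = prop.copy()
            lam_cam, per_cell, ll = lam_prop, per_cell_prop, ll_prop
        if adapting:
            delta_block.adapt_scale(float(accept))
            delta_block.observe(state.delta)
        else:
            prop_ct["delta"] += 1
            acc_ct["delta"] += int(accept)

        # ---- site errors, per-cell Metropolis
        step = eps_scale.scale * rng.standard_normal(state.eps.size)
        eps_prop = state.eps + step
        rates_prop = rates * np.exp(step)
        per_cell_prop = lik.cell_loglik_values(lam_cam, rates_prop, state.phi)
        s2 = state.sigma**2
        dprior_site = -(eps_prop**2 - state.eps**2) / (2 * s2)
        dprior_cell = np.bincount(
            lik.site_to_cam, weights=dprior_site, minlength=lik.n_cam
        )
        log_u = np.log(rng.uniform(size=lik.n_cam))
        acc_cells = log_u < (per_cell_prop - per_cell) + dprior_cell
        acc_sites = acc_cells[lik.site_to_cam]
        if np.any(acc_sites):
            state.eps = np.where(acc_sites, eps_prop, state.eps)
            rates = np.where(acc_sites, rates_prop, rates)
            per_cell = np.where(acc_cells, per_cell_prop, per_cell)
            ll = float(per_cell.sum())
        frac = float(np.mean(acc_cells))
        if adapting:
            eps_scale.update(frac)
        else:
            prop_ct["eps"] += 1
            acc_ct["eps"] += frac

        # ---- phi (NegBin dispersion)
        prop_phi = state.phi + phi_scale.scale * rng.standard_normal()
        if prop_phi > 0:
            per_cell_prop = lik.cell_loglik_values(lam_cam, rates, prop_phi)
            ll_prop = float(per_cell_prop.sum())
            dprior = _gamma_diff(prop_phi, state.phi, model.config.phi_shape,
                                 model.config.phi_rate)
            accept = np.log(rng.uniform()) < (ll_prop - ll) + dprior
        else:
            accept = False
        if accept:
            state.phi = float(prop_phi)
            per_cell, ll = per_cell_prop, ll_prop
        if adapting:
            phi_scale.update(float(accept))
        else:
            prop_ct["phi"] += 1
            acc_ct["phi"] += int(accept)

        # ---- sigma (site-error SD); likelihood-free given eps
        prop_sigma = state.sigma + sigma_scale.scale * rng.standard_normal()
        if 0.0 < prop_sigma < model.config.sigma_upper:
            n_eps = state.eps.size
            ete = state.eps @ state.eps
            dprior = (
                -n_eps * (np.log(prop_sigma) - np.log(state.sigma))
                - 0.5 * ete * (1 / prop_sigma**2 - 1 / state.sigma**2)
            )
            accept = np.log(rng.uniform()) < dprior
        else:
            accept = False
        if accept:
            state.sigma = float(prop_sigma)
        if adapting:
            sigma_scale.update(float(accept))
        else:
            prop_ct["sigma"] += 1
            acc_ct["sigma"] += int(accept)

        # ---- tau (RSR precision); likelihood-free given delta
        prop_tau = state.tau + tau_scale.scale * rng.standard_normal()
        if prop_tau > 0:
            quad = state.delta @ (m_prec @ state.delta)
            rank = state.delta.size
            dprior = (
                0.5 * rank * (np.log(prop_tau) - np.log(state.tau))
                - 0.5 * quad * (prop_tau - state.tau)
                + _gamma_diff(prop_tau, state.tau, model.config.tau_shape,
                              model.config.tau_rate)
            )
            accept = np.log(rng.uniform()) < dprior
        else:
            accept = False
        if accept:
            state.tau = float(prop_tau)
        if adapting:
            tau_scale.update(float(accept))
        else:
            prop_ct["tau"] += 1
            acc_ct["tau"] += int(accept)

        if t >= n_burn and (t - n_burn) % thin == 0 and kept < n_kept:
            out[kept] = pack(state)
            kept += 1

    acc = {k: acc_ct[k] / max(prop_ct[k], 1) for k in acc_ct}
    return out, acc


def _gamma_diff(new: float, old: float, shape: float, rate: float) -> float:
    return (shape - 1.0) * (np.log(new) - np.log(old)) - rate * (new - old)


# ---------------------------------------------------------------------------
# posterior predictive check
# ---------------------------------------------------------------------------

def posterior_predictive_pvalue(
    fitted: SpatialAbundanceModel,
    seed: int | None = None,
    discrepancy=None,
    max_draws: int = 200,
    y_obs: np.ndarray | None = None,
) -> float:
    """Bayesian p-value from posterior-predictive replicates.

    For each retained draw, a replicate data set is simulated from the model
    (latent N per occupied cell, then Poisson counts), and the default
    chi-square-type discrepancy D = sum (y - E[y])^2 / E[y] with
    E[y_i] = lambda_j[i] gamma_i d_i is compared between the replicate and
    the observed counts; ties count toward the replicate (``>=``).  Values
    near 0 or 1 flag misfit.
    """
    samples = fitted.samples_
    model = fitted.model_
    lik = model.likelihood
    flat = samples.stacked()
    if flat.shape[0] == 0:
        raise ValueError("no retained draws")
    rng = np.random.default_rng(seed)
    idx = (
        np.arange(flat.shape[0])
        if flat.shape[0] <= max_draws
        else rng.choice(flat.shape[0], size=max_draws, replace=False)
    )
    y_obs = lik.y if y_obs is None else np.asarray(y_obs, dtype=float)
    exceed = 0
    for i in idx:
        state = fitted.state_from_draw(flat[i])
        lam_cam = np.exp(
            lik.x_lambda_cam @ state.beta_lambda + fitted.model_.k_cam @ state.delta
        )
        rates = lik.site_rates(state)
        ey = lam_cam[lik.site_to_cam] * rates
        if discrepancy is None:
            d_obs = float(np.sum((y_obs - ey) ** 2 / ey))
        else:
            d_obs = float(discrepancy(y_obs, ey))
        n_lat = rng.poisson(rng.gamma(state.phi, lam_cam / state.phi))
        y_rep = rng.poisson(n_lat[lik.site_to_cam] * rates)
        if discrepancy is None:
            d_rep = float(np.sum((y_rep - ey) ** 2 / ey))
        else:
            d_rep = float(discrepancy(y_rep, ey))
        exceed += int(d_rep >= d_obs)
    return exceed / len(idx)
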