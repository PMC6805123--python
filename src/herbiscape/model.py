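"""The hierarchical spatial abundance model.

Counts from camera site i nested in grid cell j follow

    y_i | N_j[i] ~ Poisson(N_j[i] * gamma_i * d_i)
    N_j          ~ NegBin(mean lambda_j, dispersion phi)
    log lambda_j = x_lambda_j' beta_lambda + omega_j
    log gamma_i  = x_gamma_i' beta_gamma + eps_i,   eps_i ~ Normal(0, sigma^2)

with omega = K delta a Restricted Spatial Regression (RSR) random effect:
K holds the leading Moran eigenvectors of the adjacency operator projected
orthogonal to the fixed-effect design, so the spatial effect cannot absorb
covariate signal.  The latent abundance N_j is marginalised out by a finite
sum up to ``n_max`` individuals per cell ("integrated likelihood"), which
removes the discrete latent block from the sampler entirely.

Because the Poisson terms of all sites in a cell enter the integrated sum
only through the sufficient statistics

    Y_j = sum_i y_i,   R_j = sum_i gamma_i d_i,   C_j = sum_i y_i log(gamma_i d_i)

the total likelihood is evaluated as a single (n_max+1) x (#occupied cells)
matrix log-sum-exp, which is what makes full MCMC on a laptop feasible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import gammaln, logsumexp

__all__ = [
    "DesignMatrices",
    "RSRBasis",
    "ModelConfig",
    "ModelState",
    "AbundanceData",
    "IntegratedLikelihood",
    "build_design_matrix",
    "build_rsr_basis",
    "negbin_logpmf",
    "cell_integrated_loglik",
    "total_log_posterior",
]


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrices:
    """Fixed-effect design for both model scales.

    ``x_lambda`` is G x P (landscape scale, first column an intercept),
    ``x_gamma`` is S x Q (site scale, first column an intercept); quadratic
    columns are element-wise squares of their standardized parents and are
    recorded in ``quadratic_of``.
    """

    x_lambda: np.ndarray
    x_gamma: np.ndarray
    lambda_names: list[str]
    gamma_names: list[str]
    effort: np.ndarray
    cell_index: np.ndarray
    quadratic_of: dict[str, str] = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.x_lambda.shape[0]

    @property
    def n_sites(self) -> int:
        return self.x_gamma.shape[0]


def build_design_matrix(
    covariates: pd.DataFrame,
    quadratic_names: tuple[str, ...] | list[str] = (),
    intercept: bool = True,
) -> tuple[np.ndarray, list[str], dict[str, str]]:
    """Assemble a design matrix from standardized covariates.

    Appends one squared column per name in ``quadratic_names`` and prepends
    an intercept.  Returns (matrix, column names, quadratic parent map).
    """
    for name in quadratic_names:
        if name not in covariates.columns:
            raise KeyError(f"quadratic term requested for missing covariate {name!r}")
    cols: list[np.ndarray] = []
    names: list[str] = []
    if intercept:
        cols.append(np.ones(len(covariates)))
        names.append("intercept")
    for name in covariates.columns:
        cols.append(covariates[name].to_numpy(dtype=float))
        names.append(str(name))
    quad_of: dict[str, str] = {}
    for name in quadratic_names:
        z = covariates[name].to_numpy(dtype=float)
        qname = f"{name}^2"
        cols.append(z * z)
        names.append(qname)
        quad_of[qname] = str(name)
    return np.column_stack(cols), names, quad_of


# ---------------------------------------------------------------------------
# RSR basis
# ---------------------------------------------------------------------------

@dataclass
class RSRBasis:
    """Reduced-rank Moran eigenbasis orthogonal to the fixed-effect design.

    ``k`` (G x q) holds the top-q eigenvectors of the Moran operator
    P_perp A P_perp; ``prior_precision`` is K'QK, the ICAR precision
    restricted to the basis (symmetric positive definite).
    """

    k: np.ndarray
    eigenvalues: np.ndarray
    prior_precision: np.ndarray

    @property
    def rank(self) -> int:
        return self.k.shape[1]

    @property
    def logdet_prior_precision(self) -> float:
        sign, logdet = np.linalg.slogdet(self.prior_precision)
        if sign <= 0:
            raise np.linalg.LinAlgError("K'QK is not positive definite")
        return float(logdet)


def default_basis_rank(n_cells: int, n_positive: int) -> int:
    """Default number of Moran eigenvectors: 10% of cells, capped by the
    number of positive eigenvalues."""
    return min(int(np.ceil(0.1 * n_cells)), n_positive)


def build_rsr_basis(
    x_lambda: np.ndarray,
    adjacency: sp.spmatrix | np.ndarray,
    icar_precision: sp.spmatrix | np.ndarray,
    rank: int | None = None,
) -> RSRBasis:
    """Eigendecompose the Moran operator P_perp A P_perp.

    P_perp = I - X (X'X)^-1 X' projects orthogonal to the fixed-effect
    columns; the leading eigenvectors of the projected adjacency carry
    smooth spatial structure that cannot be explained by the covariates.
    """
    x = np.asarray(x_lambda, dtype=float)
    g = x.shape[0]
    a = np.asarray(
        adjacency.toarray() if sp.issparse(adjacency) else adjacency, dtype=float
    )
    xtx = x.T @ x
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("X'X is singular; drop collinear columns") from err
    p_perp = np.eye(g) - x @ xtx_inv @ x.T
    moran_op = p_perp @ a @ p_perp
    moran_op = 0.5 * (moran_op + moran_op.T)
    eigvals, eigvecs = np.linalg.eigh(moran_op)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    n_positive = int(np.sum(eigvals > 1e-10))
    if rank is None:
        rank = default_basis_rank(g, n_positive)
    if rank > n_positive:
        raise ValueError(
            f"requested rank {rank} exceeds the {n_positive} positive Moran eigenvalues"
        )
    if rank < 1:
        raise ValueError("basis rank must be at least 1")
    k = eigvecs[:, :rank]
    # re-project to pin K'X at numerical zero; leaves the eigenvectors
    # unchanged up to ~1e-12 because they already live in range(P_perp)
    k = p_perp @ k
    k /= np.linalg.norm(k, axis=0, keepdims=True)
    q_mat = np.asarray(
        icar_precision.toarray() if sp.issparse(icar_precision) else icar_precision,
        dtype=float,
    )
    kqk = k.T @ q_mat @ k
    kqk = 0.5 * (kqk + kqk.T)
    return RSRBasis(k=k, eigenvalues=eigvals[:rank], prior_precision=kqk)


# ---------------------------------------------------------------------------
# NegBin pmf and the integrated likelihood
# ---------------------------------------------------------------------------

def negbin_logpmf(n, lam, phi):
    """Negative Binomial log pmf in mean/dispersion form.

    P(N) = Gamma(N+phi) / (Gamma(phi) N!) * (phi/(phi+lam))^phi
           * (lam/(phi+lam))^N,  mean lam, variance lam + lam^2/phi.
    Broadcasts over arrays.
    """
    n = np.asarray(n)
    lam = np.asarray(lam, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(lam <= 0) or np.any(phi <= 0):
        raise ValueError("lam and phi must be positive")
    if np.any(n < 0):
        raise ValueError("N must be a non-negative integer")
    return (
        gammaln(n + phi)
        - gammaln(phi)
        - gammaln(n + 1)
        + phi * (np.log(phi) - np.log(phi + lam))
        + n * (np.log(lam) - np.log(phi + lam))
    )


def cell_integrated_loglik(
    y: np.ndarray,
    rate: np.ndarray,
    lam: float,
    phi: float,
    n_max: int = 100,
) -> float:
    """Log-likelihood of one cell with the latent abundance summed out.

    ``y`` are the counts of the cameras in the cell and ``rate`` their
    per-individual Poisson rates gamma_i * d_i (same length).  Returns

        log sum_{N=0}^{n_max} NegBin(N | lam, phi) prod_i Poisson(y_i | N rate_i)

    computed in log space.  A cell without cameras carries no data and
    contributes exactly 0.
    """
    y = np.asarray(y, dtype=float)
    rate = np.asarray(rate, dtype=float)
    if y.size != rate.size:
        raise ValueError("y and rate must have equal length")
    if y.size == 0:
        return 0.0
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if np.any(rate <= 0):
        raise ValueError("rates must be positive")
    n = np.arange(n_max + 1)
    y_tot = y.sum()
    r_tot = rate.sum()
    c = float(y @ np.log(rate) - gammaln(y + 1).sum())
    log_n = np.full(n_max + 1, -np.inf)
    log_n[1:] = np.log(n[1:])
    site_term = np.where(
        (n == 0) & (y_tot > 0), -np.inf, y_tot * np.where(n == 0, 0.0, log_n) - n * r_tot
    )
    return float(logsumexp(negbin_logpmf(n, lam, phi) + site_term) + c)


# ---------------------------------------------------------------------------
# configuration, state, data
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Priors and structural settings.

    ``beta_precision`` is the precision of the diffuse Normal prior on all
    regression coefficients (1e-3, i.e. SD ~ 31.6).  ``sigma_upper`` bounds
    the Uniform prior on the site-error SD.  tau (RSR precision) and phi
    (NegBin dispersion) carry Gamma(shape, rate) priors.  ``n_max`` truncates
    the marginalisation over latent abundance.
    """

    n_max: int = 100
    basis_rank: int | None = None
    adjacency_rule: str = "rook"
    beta_precision: float = 1e-3
    sigma_upper: float = 100.0
    tau_shape: float = 0.1
    tau_rate: float = 0.1
    phi_shape: float = 0.1
    phi_rate: float = 0.1

    def validate(self) -> None:
        if self.n_max < 1:
            raise ValueError("n_max must be >= 1")
        for name in ("beta_precision", "sigma_upper", "tau_shape", "tau_rate",
                     "phi_shape", "phi_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ModelState:
    """All model unknowns; omega = K delta is derived, not stored."""

    beta_lambda: np.ndarray
    beta_gamma: np.ndarray
    eps: np.ndarray
    delta: np.ndarray
    tau: float = 1.0
    phi: float = 1.0
    sigma: float = 1.0

    def copy(self) -> "ModelState":
        return replace(
            self,
            beta_lambda=self.beta_lambda.copy(),
            beta_gamma=self.beta_gamma.copy(),
            eps=self.eps.copy(),
            delta=self.delta.copy(),
        )

    def in_support(self, config: ModelConfig) -> bool:
        return (
            self.tau > 0
            and self.phi > 0
            and 0.0 < self.sigma < config.sigma_upper
        )


@dataclass
class AbundanceData:
    """Model-ready data bundle: designs, counts, effort and nesting."""

    design: DesignMatrices
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.size != self.design.n_sites:
            raise ValueError("count vector length must match the site design")
        if np.any(self.y < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.design.effort < 0):
            raise ValueError("effort must be non-negative")
        j = np.asarray(self.design.cell_index)
        if np.any(j < 0) or np.any(j >= self.design.n_cells):
            raise ValueError("site references a missing cell")


class IntegratedLikelihood:
    """Vectorised integrated likelihood over all occupied cells.

    Precomputes the cell bookkeeping so a full likelihood evaluation is a
    single (n_max+1) x C matrix log-sum-exp, C the number of occupied cells.
    """

    def __init__(self, data: AbundanceData, n_max: int = 100):
        self.data = data
        self.n_max = int(n_max)
        j = np.asarray(data.design.cell_index)
        self.cam_cells, self.site_to_cam = np.unique(j, return_inverse=True)
        self.n_cam = self.cam_cells.size
        self.y = data.y
        self.y_cell = np.bincount(self.site_to_cam, weights=self.y, minlength=self.n_cam)
        self.lgamma_y = float(gammaln(self.y + 1).sum())
        n = np.arange(self.n_max + 1)
        self._n = n[:, None].astype(float)
        self._gammaln_n1 = gammaln(n + 1)[:, None]
        log_n = np.zeros(self.n_max + 1)
        log_n[1:] = np.log(n[1:])
        # N=0 row: y log N is -inf unless the cell total is zero
        self._ylogn = np.outer(log_n, self.y_cell)
        self._ylogn[0, :] = np.where(self.y_cell > 0, -np.inf, 0.0)
        self._lg_cell = np.bincount(
            self.site_to_cam, weights=gammaln(self.y + 1), minlength=self.n_cam
        )
        self.x_lambda_cam = data.design.x_lambda[self.cam_cells]

    def site_rates(self, state: ModelState) -> np.ndarray:
        d = self.data.design
        return np.exp(d.x_gamma @ state.beta_gamma + state.eps) * d.effort

    def loglik(self, state: ModelState, basis_k_cam: np.ndarray | None = None,
               omega_cam: np.ndarray | None = None) -> tuple[float, np.ndarray]:
        """Total and per-cell integrated log-likelihood at ``state``.

        ``omega_cam`` (spatial effect restricted to occupied cells) may be
        passed directly; otherwise it is ``basis_k_cam @ delta`` or zero.
        """
        if omega_cam is None:
            if basis_k_cam is not None:
                omega_cam = basis_k_cam @ state.delta
            else:
                omega_cam = 0.0
        lam_cam = np.exp(self.x_lambda_cam @ state.beta_lambda + omega_cam)
        rates = self.site_rates(state)
        per_cell = self.cell_loglik_values(lam_cam, rates, state.phi)
        return float(per_cell.sum()), per_cell

    def cell_loglik_values(
        self, lam_cam: np.ndarray, rates: np.ndarray, phi: float
    ) -> np.ndarray:
        """The log-sum-exp over latent N for every occupied cell."""
        r_cell = np.bincount(self.site_to_cam, weights=rates, minlength=self.n_cam)
        with np.errstate(divide="ignore", invalid="ignore"):
            ylogr = np.where(self.y > 0, self.y * np.log(rates), 0.0)
        c_cell = np.bincount(self.site_to_cam, weights=ylogr, minlength=self.n_cam)
        lg_cell = self._lg_cell
        n = self._n
        log_ratio = np.log(lam_cam) - np.log(phi + lam_cam)
        nb = (
            gammaln(n + phi)
            - gammaln(phi)
            - self._gammaln_n1
            + phi * (np.log(phi) - np.log(phi + lam_cam))[None, :]
            + n * log_ratio[None, :]
        )
        site = self._ylogn - n * r_cell[None, :]
        return _logsumexp0(nb + site) + c_cell - lg_cell


@dataclass
class SpatialModel:
    """Data + structure + priors, exposing the joint log-posterior."""

    data: AbundanceData
    basis: RSRBasis
    config: ModelConfig

    def __post_init__(self) -> None:
        self.config.validate()
        self.likelihood = IntegratedLikelihood(self.data, self.config.n_max)
        self.k_cam = self.basis.k[self.likelihood.cam_cells]
        self._logdet_kqk = self.basis.logdet_prior_precision

    # -- prior pieces -------------------------------------------------------
    def log_prior(self, state: ModelState) -> float:
        cfg = self.config
        if not state.in_support(cfg):
            return -np.inf
        prec = cfg.beta_precision
        beta = np.concatenate([state.beta_lambda, state.beta_gamma])
        lp = 0.5 * beta.size * (np.log(prec) - np.log(2 * np.pi)) - 0.5 * prec * (
            beta @ beta
        )
        s2 = state.sigma**2
        n_eps = state.eps.size
        lp += (
            -0.5 * n_eps * np.log(2 * np.pi * s2)
            - 0.5 * (state.eps @ state.eps) / s2
            - np.log(cfg.sigma_upper)
        )
        m = self.basis.prior_precision
        q = state.delta.size
        lp += (
            0.5 * q * np.log(state.tau)
            + 0.5 * self._logdet_kqk
            - 0.5 * q * np.log(2 * np.pi)
            - 0.5 * state.tau * (state.delta @ (m @ state.delta))
        )
        lp += _gamma_logpdf(state.tau, cfg.tau_shape, cfg.tau_rate)
        lp += _gamma_logpdf(state.phi, cfg.phi_shape, cfg.phi_rate)
        return float(lp)

    def log_posterior(self, state: ModelState) -> float:
        lp = self.log_prior(state)
        if not np.isfinite(lp):
            return -np.inf
        ll, _ = self.likelihood.loglik(state, basis_k_cam=self.k_cam)
        return lp + ll

    # -- per-cell pieces used by the cellwise eps update --------------------
    def cell_logliks(self, state: ModelState) -> np.ndarray:
        _, per_cell = self.likelihood.loglik(state, basis_k_cam=self.k_cam)
        return per_cell

    def lambda_full(self, state: ModelState) -> np.ndarray:
        """lambda over the full grid, spatial effect included."""
        return np.exp(
            self.data.design.x_lambda @ state.beta_lambda + self.basis.k @ state.delta
        )


def _logsumexp0(x: np.ndarray) -> np.ndarray:
    """log sum exp over axis 0, tolerant of all -inf columns; kept local
    because it sits on the sampler's hottest path."""
    m = x.max(axis=0)
    safe = np.where(np.isfinite(m), m, 0.0)
    out = safe + np.log(np.exp(x - safe).sum(axis=0))
    return np.where(np.isfinite(m), out, -np.inf)


def _gamma_logpdf(x: float, shape: float, rate: float) -> float:
    return (
        shape * np.log(rate)
        - gammaln(shape)
        + (shape - 1.0) * np.log(x)
        - rate * x
    )


def total_log_posterior(
    state: ModelState,
    data: AbundanceData,
    basis: RSRBasis,
    config: ModelConfig,
) -> float:
    """Joint log-posterior of the full model (integrated likelihood + priors).

    Out-of-support states return -inf rather than raising, so a sampler can
    simply reject them.
    """
    return SpatialModel(data=data, basis=basis, config=config).log_posterior(state)
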