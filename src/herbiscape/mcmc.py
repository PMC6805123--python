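"""Metropolis-Hastings machinery, chain containers and convergence checks.

Two step methods are provided, mirroring common practice for this model
class: component-wise random-walk Metropolis for scalar parameters (with
Robbins-Monro scale adaptation toward a target acceptance rate) and
adaptive-covariance Metropolis for parameter blocks (empirical covariance
learned during burn-in, frozen afterwards so the post-burn-in kernel is a
valid fixed Metropolis kernel).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AdaptiveScale",
    "AdaptiveCovProposal",
    "PosteriorSamples",
    "run_mcmc",
    "gelman_rubin",
    "summarize_posterior",
]


class AdaptiveScale:
    """Robbins-Monro adaptation of a log proposal scale toward a target
    acceptance rate; call :meth:`update` only during burn-in."""

    def __init__(self, scale: float = 0.5, target: float = 0.35, rate: float = 0.66):
        self.log_scale = np.log(scale)
        self.target = target
        self.rate = rate
        self._t = 0

    @property
    def scale(self) -> float:
        return float(np.exp(self.log_scale))

    def update(self, accepted: float) -> None:
        self._t += 1
        step = self._t ** (-self.rate)
        self.log_scale += step * (accepted - self.target)


class AdaptiveCovProposal:
    """Haario-style adaptive multivariate normal proposal.

    Maintains a running mean/covariance of the chain for one block; the
    proposal is N(0, s * (Cov + eps I)) with s itself adapted toward a
    target acceptance rate.  ``freeze()`` stops all adaptation.
    """

    def __init__(self, dim: int, scale: float | None = None, target: float = 0.25):
        self.dim = dim
        self.mean = np.zeros(dim)
        self.m2 = np.zeros((dim, dim))
        self.count = 0
        self.chol: np.ndarray | None = None
        init = scale if scale is not None else 0.1 / np.sqrt(dim)
        self.tuner = AdaptiveScale(scale=init, target=target)
        self.frozen = False
        self._warm = 10 * dim

    def observe(self, x: np.ndarray) -> None:
        if self.frozen:
            return
        self.count += 1
        delta = x - self.mean
        self.mean += delta / self.count
        self.m2 += np.outer(delta, x - self.mean)
        if self.count > self._warm and self.count % 50 == 0:
            cov = self.m2 / (self.count - 1)
            cov = (2.38**2 / self.dim) * cov + 1e-10 * np.eye(self.dim)
            try:
                self.chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                self.chol = None

    def propose(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        s = self.tuner.scale
        z = rng.standard_normal(self.dim)
        if self.chol is not None:
            return x + s * (self.chol @ z)
        return x + s * z

    def adapt_scale(self, accepted: float) -> None:
        if not self.frozen:
            self.tuner.update(accepted)

    def freeze(self) -> None:
        self.frozen = True


# ---------------------------------------------------------------------------
# samples container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSamples:
    """Thinned post-burn-in draws from one or more chains.

    ``draws`` has shape (n_chains, n_kept, n_params); ``names`` labels the
    last axis.  ``acceptance`` maps block name to its post-adaptation
    acceptance rate (averaged over chains).
    """

    draws: np.ndarray
    names: list[str]
    n_iter: int
    n_burn: int
    thin: int
    seed: int | None = None
    acceptance: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.draws.ndim != 3:
            raise ValueError("draws must be (n_chains, n_kept, n_params)")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_kept(self) -> int:
        return self.draws.shape[1]

    def index_of(self, name: str) -> int:
        return self.names.index(name)

    def get(self, name: str) -> np.ndarray:
        """Draws of one parameter, shape (n_chains, n_kept)."""
        return self.draws[:, :, self.index_of(name)]

    def stacked(self, name: str | None = None) -> np.ndarray:
        """All chains concatenated: (n_chains*n_kept,) or (..., n_params)."""
        flat = self.draws.reshape(-1, self.draws.shape[2])
        if name is None:
            return flat
        return flat[:, self.index_of(name)]

    def select(self, prefix: str) -> list[str]:
        return [n for n in self.names if n == prefix or n.startswith(prefix + "[")]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.stacked(), columns=self.names)
        frame.insert(0, "chain", np.repeat(np.arange(self.n_chains), self.n_kept))
        frame.insert(1, "draw", np.tile(np.arange(self.n_kept), self.n_chains))
        return frame


# ---------------------------------------------------------------------------
# generic vector sampler (used for unit-test posteriors and small targets)
# ---------------------------------------------------------------------------

def run_mcmc(
    log_posterior: Callable[[np.ndarray], float],
    x0: np.ndarray,
    n_iter: int,
    n_burn: int,
    thin: int = 1,
    n_chains: int = 1,
    seed: int | None = None,
    names: Sequence[str] | None = None,
    blocked: bool = True,
) -> PosteriorSamples:
    """Sample an arbitrary log-density with adaptive Metropolis.

    ``blocked=True`` uses one adaptive-covariance block over all components;
    otherwise each component gets its own adapted random-walk scale.
    Deterministic for a fixed seed.  A NaN from ``log_posterior`` aborts
    (out-of-support states must return -inf instead).
    """
    if n_burn >= n_iter:
        raise ValueError("n_burn must be smaller than n_iter")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    dim = x0.size
    names = list(names) if names is not None else [f"x{i}" for i in range(dim)]
    n_kept = (n_iter - n_burn) // thin
    draws = np.empty((n_chains, n_kept, dim))
    ss = np.random.SeedSequence(seed)
    acc_after: list[float] = []
    for c, child in enumerate(ss.spawn(n_chains)):
        rng = np.random.default_rng(child)
        x = x0 + 0.1 * rng.standard_normal(dim)
        lp = _checked(log_posterior, x)
        if not np.isfinite(lp):
            x = x0.copy()
            lp = _checked(log_posterior, x)
        block = AdaptiveCovProposal(dim) if blocked else None
        scales = [AdaptiveScale(0.5) for _ in range(dim)] if not blocked else None
        kept = 0
        n_acc = 0
        n_prop = 0
        for t in range(n_iter):
            adapting = t < n_burn
            if blocked:
                prop = block.propose(x, rng)
                lp_prop = _checked(log_posterior, prop)
                accept = np.log(rng.uniform()) < lp_prop - lp
                if accept:
                    x, lp = prop, lp_prop
                if adapting:
                    block.adapt_scale(float(accept))
                    block.observe(x)
                else:
                    block.freeze()
                    n_prop += 1
                    n_acc += int(accept)
            else:
                for i in range(dim):
                    prop = x.copy()
                    prop[i] += scales[i].scale * rng.standard_normal()
                    lp_prop = _checked(log_posterior, prop)
                    accept = np.log(rng.uniform()) < lp_prop - lp
                    if accept:
                        x, lp = prop, lp_prop
                    if adapting:
                        scales[i].update(float(accept))
                    else:
                        n_prop += 1
                        n_acc += int(accept)
            if t >= n_burn and (t - n_burn) % thin == 0 and kept < n_kept:
                draws[c, kept] = x
                kept += 1
        acc_after.append(n_acc / max(n_prop, 1))
    return PosteriorSamples(
        draws=draws,
        names=names,
        n_iter=n_iter,
        n_burn=n_burn,
        thin=thin,
        seed=seed,
        acceptance={"all": float(np.mean(acc_after))},
    )


def _checked(f: Callable[[np.ndarray], float], x: np.ndarray) -> float:
    lp = float(f(x))
    if np.isnan(lp):
        raise FloatingPointError(
            "log-posterior returned NaN (out-of-support states must return -inf)"
        )
    return lp


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def gelman_rubin(samples: PosteriorSamples | np.ndarray) -> pd.Series | float:
    """Classic Gelman-Rubin potential scale reduction factor.

    For draws x_{c,t} (m chains of n draws): W the mean within-chain
    variance, B/n the variance of the chain means, and

        R-hat = sqrt( ((n-1)/n * W + B/n) / W ).

    Given a :class:`PosteriorSamples` returns a Series per parameter;
    given a plain (m, n) array returns a float.
    """
    if isinstance(samples, PosteriorSamples):
        vals = {
            name: _psrf(samples.get(name)) for name in samples.names
        }
        return pd.Series(vals, name="r_hat")
    return _psrf(np.asarray(samples, dtype=float))


def _psrf(chains: np.ndarray) -> float:
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need at least two chains of draws")
    m, n = chains.shape
    if n < 10:
        raise ValueError("need at least 10 draws per chain")
    w = chains.var(axis=1, ddof=1).mean()
    b_over_n = chains.mean(axis=1).var(ddof=1)
    if w == 0.0:
        return 1.0 if b_over_n == 0.0 else np.inf
    v_hat = (n - 1) / n * w + b_over_n
    return float(np.sqrt(v_hat / w))


def summarize_posterior(
    samples: PosteriorSamples,
    levels: tuple[float, float] = (0.025, 0.975),
    names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-parameter posterior mean, SD, quantile CI and a flag that is true
    iff the credibility interval excludes zero."""
    if samples.n_kept == 0:
        raise ValueError("no stored draws to summarize")
    lo, hi = levels
    rows = []
    for name in (names if names is not None else samples.names):
        x = samples.stacked(name)
        qlo, qhi = np.quantile(x, [lo, hi])
        rows.append(
            {
                "parameter": name,
                "mean": float(x.mean()),
                "sd": float(x.std(ddof=0)),
                f"q{lo}": float(qlo),
                f"q{hi}": float(qhi),
                "differs_from_zero": bool(qlo > 0 or qhi < 0),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
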