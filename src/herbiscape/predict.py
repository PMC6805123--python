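"""Posterior landscape products: density surfaces, spatial-effect maps,
covariate effect curves and ranked-density curves.

All products are deterministic functions of the stored draws.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mcmc import PosteriorSamples

__all__ = [
    "predict_lambda_surface",
    "extract_spatial_effects",
    "effect_curve",
    "ranked_density_curve",
]


def _draw_matrix(samples: PosteriorSamples, names: list[str]) -> np.ndarray:
    idx = [samples.index_of(n) for n in names]
    return samples.stacked()[:, idx]


def predict_lambda_surface(
    samples: PosteriorSamples,
    x_lambda: np.ndarray,
    lambda_names: list[str],
    k: np.ndarray | None = None,
    include_sre: bool = True,
    levels: tuple[float, float] = (0.025, 0.975),
) -> pd.DataFrame:
    """Per-cell posterior summary of lambda (expected individuals per cell).

    Per draw, lambda_j = exp(x_j' beta + (K delta)_j); the spatial effect is
    dropped when ``include_sre`` is false.  Returns a DataFrame with cell
    index, posterior mean and quantile CI.
    """
    beta_names = [f"beta_lambda[{n}]" for n in lambda_names]
    beta = _draw_matrix(samples, beta_names)  # (draws, P)
    if x_lambda.shape[1] != beta.shape[1]:
        raise ValueError("design does not match the fitted coefficient draws")
    log_lam = beta @ x_lambda.T  # (draws, G)
    if include_sre:
        if k is None:
            raise ValueError("spatial basis K required when include_sre=True")
        delta_names = samples.select("delta")
        delta = _draw_matrix(samples, delta_names)
        if k.shape[1] != delta.shape[1]:
            raise ValueError("basis rank does not match the stored delta draws")
        log_lam = log_lam + delta @ k.T
    lam = np.exp(log_lam)
    lo, hi = levels
    qlo, qhi = np.quantile(lam, [lo, hi], axis=0)
    return pd.DataFrame(
        {
            "cell": np.arange(x_lambda.shape[0]),
            "mean": lam.mean(axis=0),
            f"q{lo}": qlo,
            f"q{hi}": qhi,
        }
    )


def extract_spatial_effects(
    samples: PosteriorSamples,
    k: np.ndarray,
    levels: tuple[float, float] = (0.025, 0.975),
) -> pd.DataFrame:
    """Posterior summary of the spatial random effect omega = K delta per
    cell (log-scale deviations: unexplained hot/cold spots)."""
    delta = _draw_matrix(samples, samples.select("delta"))
    if k.shape[1] != delta.shape[1]:
        raise ValueError("basis rank does not match the stored delta draws")
    omega = delta @ k.T
    lo, hi = levels
    qlo, qhi = np.quantile(omega, [lo, hi], axis=0)
    return pd.DataFrame(
        {
            "cell": np.arange(k.shape[0]),
            "mean": omega.mean(axis=0),
            f"q{lo}": qlo,
            f"q{hi}": qhi,
        }
    )


def effect_curve(
    samples: PosteriorSamples,
    covariate: str,
    values: np.ndarray,
    names: list[str],
    quadratic_of: dict[str, str],
    scale: str = "lambda",
    levels: tuple[float, float] = (0.025, 0.975),
) -> pd.DataFrame:
    """Response curve for one covariate with all others held at 0.

    ``names`` are the design column names of the chosen scale ("lambda" or
    "gamma") and ``quadratic_of`` maps quadratic columns to their parents;
    the quadratic twin of the varied covariate tracks value^2.  Values are
    on the standardized covariate scale; the response is on the natural
    (exponentiated) scale, intercept included.
    """
    if scale not in ("lambda", "gamma"):
        raise ValueError("scale must be 'lambda' or 'gamma'")
    if covariate not in names:
        raise KeyError(f"unknown covariate {covariate!r}")
    values = np.asarray(values, dtype=float)
    design = np.zeros((values.size, len(names)))
    for col, name in enumerate(names):
        if name == "intercept":
            design[:, col] = 1.0
        elif name == covariate:
            design[:, col] = values
        elif quadratic_of.get(name) == covariate:
            design[:, col] = values**2
    beta = _draw_matrix(samples, [f"beta_{scale}[{n}]" for n in names])
    resp = np.exp(beta @ design.T)  # (draws, n_values)
    lo, hi = levels
    qlo, qhi = np.quantile(resp, [lo, hi], axis=0)
    return pd.DataFrame(
        {
            "value": values,
            "mean": resp.mean(axis=0),
            f"q{lo}": qlo,
            f"q{hi}": qhi,
        }
    )


def ranked_density_curve(surface: np.ndarray | pd.Series) -> pd.DataFrame:
    """Cell values sorted descending (ties keep stable cell order), as used
    to compare how density concentrates across the landscape."""
    values = np.asarray(surface, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("empty surface")
    order = np.argsort(-values, kind="stable")
    return pd.DataFrame(
        {"rank": np.arange(1, values.size + 1), "cell": order, "value": values[order]}
    )
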