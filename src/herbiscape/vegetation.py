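"""Linking herbivory regimes to browsing outcomes on regeneration plots.

Plot records are long-format: one row per plot x sapling species with
counts in two height classes (<30 cm, >=30 cm) and the number of browsed
individuals in the >=30 cm class.  The browsing intensity index is the
proportion of browsed individuals among all >=30 cm saplings of a plot;
the recruitment shift of a focal species is the difference of its
proportional share between the >=30 cm and <30 cm classes.  Both are
modelled by ordinary least squares with two interacting factors,
herbivory regime (cluster) and reserve status.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = [
    "browsing_intensity",
    "recruitment_shift",
    "fit_herbiscape_lm",
    "FOCAL_SPECIES",
]

# Contrasting focal species: carpinus (browsing-tolerant) vs acer
# (browsing-sensitive); any species present in the records may be used.
FOCAL_SPECIES = ("carpinus", "acer")

_REQUIRED = ("plot_id", "species", "count_lt30", "count_ge30", "browsed_ge30")


def _check(plots: pd.DataFrame) -> None:
    for col in _REQUIRED:
        if col not in plots.columns:
            raise ValueError(f"plot records lack column {col!r}")
    if (plots[["count_lt30", "count_ge30", "browsed_ge30"]] < 0).any().any():
        raise ValueError("counts must be non-negative")
    if (plots["browsed_ge30"] > plots["count_ge30"]).any():
        raise ValueError("browsed saplings exceed the >=30 cm count")


def browsing_intensity(plots: pd.DataFrame) -> pd.Series:
    """Per-plot proportion of browsed saplings in the >=30 cm class.

    Plots with no >=30 cm saplings have no defined intensity and return
    NaN (they are dropped from downstream model fits).
    """
    _check(plots)
    grouped = plots.groupby("plot_id")[["count_ge30", "browsed_ge30"]].sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        out = grouped["browsed_ge30"] / grouped["count_ge30"]
    out[grouped["count_ge30"] == 0] = np.nan
    out.name = "browsing_intensity"
    return out


def recruitment_shift(plots: pd.DataFrame, species: str) -> pd.Series:
    """Per-plot share_{>=30}(species) - share_{<30}(species), in [-1, 1].

    Shares are over all species within each height class; a plot with an
    empty class returns NaN.  Positive values mean the species is better
    represented in the taller (herbivory-filtered) class.
    """
    _check(plots)
    totals = plots.groupby("plot_id")[["count_lt30", "count_ge30"]].sum()
    focal = (
        plots[plots["species"] == species]
        .groupby("plot_id")[["count_lt30", "count_ge30"]]
        .sum()
        .reindex(totals.index, fill_value=0)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        share_lo = focal["count_lt30"] / totals["count_lt30"]
        share_hi = focal["count_ge30"] / totals["count_ge30"]
    out = share_hi - share_lo
    out[(totals["count_lt30"] == 0) | (totals["count_ge30"] == 0)] = np.nan
    out.name = f"recruitment_shift_{species}"
    return out


def fit_herbiscape_lm(
    response: pd.Series,
    cluster: pd.Series,
    reserve: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """OLS with full cluster x reserve interaction on plot-level responses.

    Inputs share the plot index; plots with a missing response are
    excluded.  Returns (coefficient table, per-combination predicted means
    with standard errors; combinations without data are flagged
    unavailable).
    """
    data = pd.DataFrame(
        {"response": response, "cluster": cluster, "reserve": reserve}
    ).dropna(subset=["response"])
    if len(data) == 0:
        raise ValueError("no plots with a defined response")
    # single-level factors reduce gracefully to an intercept-only model
    terms = [
        f"C({name})"
        for name in ("cluster", "reserve")
        if data[name].nunique() > 1
    ]
    formula = "response ~ " + (" * ".join(terms) if terms else "1")
    model = smf.ols(formula, data=data).fit()
    coefs = pd.DataFrame(
        {
            "coef": model.params,
            "se": model.bse,
            "t": model.tvalues,
            "p": model.pvalues,
        }
    )
    observed = set(map(tuple, data[["cluster", "reserve"]].drop_duplicates().values))
    rows = []
    for c, r in itertools.product(
        sorted(data["cluster"].unique()), sorted(data["reserve"].unique())
    ):
        if (c, r) in observed:
            pred = model.get_prediction(
                pd.DataFrame({"cluster": [c], "reserve": [r]})
            )
            rows.append(
                {
                    "cluster": c,
                    "reserve": r,
                    "mean": float(pred.predicted_mean[0]),
                    "se": float(pred.se_mean[0]),
                    "available": True,
                }
            )
        else:
            rows.append(
                {"cluster": c, "reserve": r, "mean": np.nan, "se": np.nan,
                 "available": False}
            )
    return coefs, pd.DataFrame(rows)
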