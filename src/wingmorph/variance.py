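"""Variance decomposition on the link and data scales.

For a binary trait modelled with a logit link, the phenotypic variance on
the latent (link) scale is the sum of the fixed-effect variance
V_F = beta^2 V_x, the additive-genetic term, the cage variance V_C, the
latent residual V_R (fixed to 1), and the distribution-specific variance of
the logit, pi^2/3.  For the random-slope model the additive-genetic
variance averaged over the covariate distribution (the *marginalized*
additive variance) is

    V_A,M = V_A,I + V_A,S V_x + mu^2 V_A,S + 2 mu C_A,IS

with mu, V_x the mean and variance of the centred covariate, and the part
exclusively attributable to slope variation is V_S = V_A,S V_x + mu^2 V_A,S.
Conditional on a covariate value x the additive variance is

    V_A(x) = V_A,I + 2 x C_A,IS + x^2 V_A,S.

Data-scale (observation-scale) variants multiply the link-scale components
by the squared derivative of the inverse link (the delta method) and use
the Bernoulli observation variance P(1 - P) in the total.

All quantities are computed per posterior draw and then summarized, so the
reported proportions are posterior medians of ratios, not ratios of
medians.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .animal_model import PosteriorSamples, hpd_interval

__all__ = [
    "CovariateMoments",
    "covariate_moments",
    "marginalized_additive_variance",
    "slope_exclusive_variance",
    "link_scale_proportions",
    "data_scale_proportions",
    "conditional_decomposition",
    "summarize_components",
    "DISTRIBUTION_VARIANCE",
]

#: distribution-specific variance of the logit link
DISTRIBUTION_VARIANCE = np.pi ** 2 / 3.0


@dataclass(frozen=True)
class CovariateMoments:
    """Mean and variance of the centred covariate over phenotyped records."""

    mu: float
    V_x: float

    def __post_init__(self) -> None:
        if self.V_x < 0:
            raise ValueError("V_x must be nonnegative")


def covariate_moments(
    data: pd.DataFrame,
    centre: float = 6.5,
    covariate: str = "nymphal_density",
    response: str = "y",
) -> CovariateMoments:
    """Moments of the centred covariate over phenotyped individuals.

    Accepts either a phenotype table (rows with missing response are
    excluded) or any frame with the covariate column.
    """
    df = data
    if response in df.columns:
        df = df.loc[df[response].notna()]
    if df.empty:
        raise ValueError("no records")
    x = df[covariate].to_numpy(dtype=float) - centre
    v = float(np.var(x))
    if v == 0:
        warnings.warn("constant covariate: V_x = 0")
    return CovariateMoments(mu=float(np.mean(x)), V_x=v)


def marginalized_additive_variance(V_A_I, V_A_S, C_A_IS, moments: CovariateMoments):
    """V_A,M = V_A,I + V_A,S V_x + mu^2 V_A,S + 2 mu C_A,IS (per draw)."""
    return (
        np.asarray(V_A_I)
        + np.asarray(V_A_S) * moments.V_x
        + moments.mu ** 2 * np.asarray(V_A_S)
        + 2.0 * moments.mu * np.asarray(C_A_IS)
    )


def slope_exclusive_variance(V_A_S, moments: CovariateMoments):
    """V_S = V_A,S V_x + mu^2 V_A,S (per draw)."""
    return np.asarray(V_A_S) * (moments.V_x + moments.mu ** 2)


def _component_frame(samples: PosteriorSamples, moments: CovariateMoments,
                     mode: str) -> pd.DataFrame:
    """Per-draw link-scale variance components for either model."""
    df = samples.to_dataframe()
    if mode == "basic":
        if "V_A" not in df:
            raise ValueError("samples are not from a basic (intercept) model")
        additive = df["V_A"].to_numpy()
        extra = {}
    elif mode == "random_slope":
        needed = {"V_A_I", "V_A_S", "C_A_IS"}
        if not needed.issubset(df.columns):
            raise ValueError("samples are not from a random-slope model")
        additive = marginalized_additive_variance(
            df["V_A_I"], df["V_A_S"], df["C_A_IS"], moments
        )
        extra = {
            "V_A_I": df["V_A_I"].to_numpy(),
            "V_A_S": df["V_A_S"].to_numpy(),
            "C_A_IS": df["C_A_IS"].to_numpy(),
            "V_S": slope_exclusive_variance(df["V_A_S"], moments),
        }
    else:
        raise ValueError(f"unknown mode {mode!r}")
    v_r = float(samples.meta.get("v_r", 1.0))
    out = pd.DataFrame(
        {
            "V_F": df["beta"].to_numpy() ** 2 * moments.V_x,
            "V_A_total": np.asarray(additive, dtype=float),
            "V_C": df["V_C"].to_numpy(),
            "V_R": np.full(len(df), v_r),
            "V_dist": np.full(len(df), DISTRIBUTION_VARIANCE),
        }
    )
    for k, v in extra.items():
        out[k] = v
    return out


def link_scale_proportions(
    samples: PosteriorSamples,
    moments: CovariateMoments,
    mode: str = "random_slope",
) -> pd.DataFrame:
    """Per-draw link-scale proportions of total phenotypic variance.

    The total is V_F + V_A + V_C + V_R + pi^2/3, where the additive term is
    V_A for the basic model and the marginalized V_A,M for the random-slope
    model.  The five ``prop_*`` columns sum to one per draw.  For the
    random-slope model the raw slope-variance ratio (``prop_slope_raw``,
    V_A,S / total) and the slope-exclusive ratio (``prop_slope_exclusive``,
    V_S / total) are also reported; they are *not* part of the unit sum.
    """
    comp = _component_frame(samples, moments, mode)
    total = (
        comp["V_F"] + comp["V_A_total"] + comp["V_C"] + comp["V_R"] + comp["V_dist"]
    )
    out = pd.DataFrame(
        {
            "prop_fixed": comp["V_F"] / total,
            "prop_additive": comp["V_A_total"] / total,
            "prop_cage": comp["V_C"] / total,
            "prop_residual": comp["V_R"] / total,
            "prop_distribution": comp["V_dist"] / total,
        }
    )
    if mode == "random_slope":
        out["prop_additive_intercept"] = comp["V_A_I"] / total
        out["prop_slope_raw"] = comp["V_A_S"] / total
        out["prop_slope_exclusive"] = comp["V_S"] / total
    out.attrs["total"] = total.to_numpy()
    out.attrs["components"] = comp
    return out


def data_scale_proportions(
    samples: PosteriorSamples,
    moments: CovariateMoments,
    P: float,
    mode: str = "random_slope",
) -> pd.DataFrame:
    """Observation-scale proportions using the delta method at logit(P).

    Each link-scale variance component is multiplied by the squared
    derivative of the inverse logit evaluated at logit(P), i.e. (P(1-P))^2,
    and the Bernoulli observation variance P(1-P) replaces the link-scale
    residual-plus-distribution terms in the total.
    """
    if not (0.0 < P < 1.0):
        raise ValueError("P must be strictly between 0 and 1")
    comp = _component_frame(samples, moments, mode)
    f = (P * (1.0 - P)) ** 2
    obs = P * (1.0 - P)
    total = f * (comp["V_F"] + comp["V_A_total"] + comp["V_C"] + comp["V_R"]) + obs
    out = pd.DataFrame(
        {
            "prop_fixed": f * comp["V_F"] / total,
            "prop_additive": f * comp["V_A_total"] / total,
            "prop_cage": f * comp["V_C"] / total,
            "prop_residual": f * comp["V_R"] / total,
            "prop_observation": obs / total,
        }
    )
    if mode == "random_slope":
        out["prop_slope_raw"] = f * comp["V_A_S"] / total
    out.attrs["total"] = total.to_numpy()
    return out


def conditional_decomposition(
    samples: PosteriorSamples,
    moments: Optional[CovariateMoments] = None,
    grid: Optional[Sequence[float]] = None,
    centre: float = 6.5,
    data_scale: bool = False,
    P: Optional[float] = None,
    observed_range: Optional[tuple] = None,
) -> pd.DataFrame:
    """Additive-genetic variance and its proportion along the density grid.

    ``grid`` holds raw densities (default 1..12); internally they are
    centred.  Link scale: proportion = V_A(x) / (V_A(x) + V_C + V_R +
    pi^2/3).  Data scale: components are multiplied by the squared logistic
    density at the fitted linear predictor alpha + beta x (per draw) and
    the observation variance P(1-P) -- with P the average proportion of
    long-winged individuals -- enters the total in place of the link-scale
    distribution variance.

    Returns one row per grid density with posterior median, SD and 95% HPD
    of the conditional proportion, plus the median conditional V_A(x).
    """
    df = samples.to_dataframe()
    for col in ("V_A_I", "V_A_S", "C_A_IS"):
        if col not in df:
            raise ValueError("conditional decomposition needs random-slope samples")
    if grid is None:
        grid = np.arange(1.0, 13.0)
    grid = np.asarray(grid, dtype=float)
    if observed_range is not None:
        lo, hi = observed_range
        if grid.min() < lo or grid.max() > hi:
            warnings.warn("grid extends outside the observed density range")
    if data_scale and P is None:
        raise ValueError("data-scale variant requires the average proportion P")

    x = grid - centre
    vai = df["V_A_I"].to_numpy()[:, None]
    vas = df["V_A_S"].to_numpy()[:, None]
    cis = df["C_A_IS"].to_numpy()[:, None]
    vc = df["V_C"].to_numpy()[:, None]
    v_r = float(samples.meta.get("v_r", 1.0))

    va_x = vai + 2.0 * x[None, :] * cis + x[None, :] ** 2 * vas  # (draws, grid)
    if data_scale:
        alpha = df["alpha"].to_numpy()[:, None]
        beta = df["beta"].to_numpy()[:, None]
        p_x = 1.0 / (1.0 + np.exp(-(alpha + beta * x[None, :])))
        fac = (p_x * (1.0 - p_x)) ** 2
        obs = P * (1.0 - P)
        prop = fac * va_x / (fac * (va_x + vc + v_r) + obs)
    else:
        prop = va_x / (va_x + vc + v_r + DISTRIBUTION_VARIANCE)

    rows = []
    for j, d in enumerate(grid):
        lo, hi = hpd_interval(prop[:, j])
        rows.append(
            {
                "density": d,
                "V_A_conditional": float(np.median(va_x[:, j])),
                "prop_median": float(np.median(prop[:, j])),
                "prop_sd": float(np.std(prop[:, j], ddof=1)),
                "prop_hpd_low": lo,
                "prop_hpd_high": hi,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["scale"] = "data" if data_scale else "link"
    return out


def summarize_components(per_draw: pd.DataFrame, prob: float = 0.95) -> pd.DataFrame:
    """Median/SD/HPD summary of per-draw proportions (Table-2 shape)."""
    rows = []
    for col in per_draw.columns:
        v = per_draw[col].to_numpy()
        lo, hi = hpd_interval(v, prob)
        rows.append(
            {
                "component": col,
                "median": float(np.median(v)),
                "sd": float(np.std(v, ddof=1)),
                "hpd_low": lo,
                "hpd_high": hi,
            }
        )
    return pd.DataFrame(rows).set_index("component")
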