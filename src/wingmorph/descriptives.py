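"""Pre-model descriptive analyses of the breeding-design data.

Density-class sample-size tables, wing-morph percentages, the sex-bias
chi-square test, the between-sex correlation of morph proportions across
density classes, and pooled binomial GLMs relating wing morph to the
alternative density measures (nymphal, hatchling, embryo) or to cage-wise
survival.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "density_class_table",
    "morph_proportion",
    "sex_bias_chisq",
    "proportions_correlation",
    "pooled_density_glm",
    "GlmFit",
]


def density_class_table(
    data: pd.DataFrame, classes: Tuple[int, int] = (1, 12)
) -> pd.DataFrame:
    """Per-density-class counts of sexes, morphs, families and cages.

    Rows cover every class in ``classes`` (zero-filled where empty); extra
    classes present in the data are appended with a warning.  Only
    phenotyped individuals (non-missing ``y``) are counted.
    """
    lo, hi = classes
    wanted = list(range(lo, hi + 1))
    df = data.loc[data["y"].notna()].copy()
    if df.empty:
        return pd.DataFrame(
            0,
            index=pd.Index(wanted, name="nymphal_density"),
            columns=["females", "males", "total", "long_winged",
                     "short_winged", "families", "cages"],
        )
    dens = df["nymphal_density"].astype(int)
    extra = sorted(set(dens.unique()) - set(wanted))
    if extra:
        warnings.warn(f"densities outside {lo}-{hi} present: {extra}")
    index = pd.Index(wanted + extra, name="nymphal_density")
    fam = df["sire"].astype(str) + "/" + df["dam"].astype(str)
    g = df.assign(_d=dens, _fam=fam).groupby("_d")
    tab = pd.DataFrame(
        {
            "females": g.apply(lambda s: int((s["sex"] == "F").sum()), include_groups=False),
            "males": g.apply(lambda s: int((s["sex"] == "M").sum()), include_groups=False),
            "total": g.size(),
            "long_winged": g.apply(lambda s: int((s["y"] == 1).sum()), include_groups=False),
            "short_winged": g.apply(lambda s: int((s["y"] == 0).sum()), include_groups=False),
            "families": g.apply(lambda s: s["_fam"].nunique(), include_groups=False),
            "cages": g.apply(lambda s: s["cage_id"].nunique(), include_groups=False),
        }
    )
    return tab.reindex(index, fill_value=0).astype(int)


def morph_proportion(n_long: int, n_total: int) -> dict:
    """Percentages of each morph, rounded half-up to one decimal.

    Full-precision fractions are returned alongside the display values.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_long <= n_total):
        raise ValueError("n_long must be between 0 and n_total")

    def pct(count: int) -> float:
        exact = Decimal(100) * Decimal(count) / Decimal(n_total)
        return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))

    p_long = n_long / n_total
    return {
        "pct_long_winged": pct(n_long),
        "pct_short_winged": pct(n_total - n_long),
        "frac_long_winged": p_long,
        "frac_short_winged": 1.0 - p_long,
    }


def sex_bias_chisq(table, correction: bool = False) -> Tuple[float, int, float]:
    """Pearson chi-square on a 2x2 sex-by-morph table (no Yates by default).

    Returns (chi2, df, p).
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (obs < 0).any():
        raise ValueError("counts must be nonnegative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero margin")
    chi2, p, dof, _ = stats.chi2_contingency(obs, correction=correction)
    return float(chi2), int(dof), float(p)


def proportions_correlation(props_a, props_b) -> dict:
    """Pearson correlation of per-class proportions with its t test.

    t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.
    """
    a = np.asarray(props_a, dtype=float)
    b = np.asarray(props_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in a proportions vector")
    r, _ = stats.pearsonr(a, b)
    n = len(a)
    df = n - 2
    if abs(r) >= 1.0:
        t = np.inf * np.sign(r)
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df)
    return {"r": float(r), "t": float(t), "df": df, "p": float(p)}


@dataclass
class GlmFit:
    """Binomial-logit GLM of wing morph on one density/survival measure."""

    measure: str
    subset: str
    intercept: float
    slope: float
    n: int
    separation: bool = False

    def predict(self, x) -> np.ndarray:
        eta = self.intercept + self.slope * np.asarray(x, dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))


def _survival_per_cage(data: pd.DataFrame) -> pd.Series:
    g = data.groupby("cage_id")["survived"]
    return g.mean()


def pooled_density_glm(
    data: pd.DataFrame, measure: str = "nymphal", subset: str = "all"
) -> GlmFit:
    """ML logistic regression of morph on a density measure, pooled data.

    ``measure`` is one of nymphal / hatchling / embryo / survival (cage-wise
    proportion surviving); ``subset='never_split'`` keeps only cages that
    were neither split nor created by splitting (excludes source and
    receiving cages).  Fitting is at the individual level, which for
    grouped binomial data is equivalent to fitting pooled per-class counts.
    """
    columns = {
        "nymphal": "nymphal_density",
        "hatchling": "hatchling_density",
        "embryo": "embryo_density",
        "survival": None,
    }
    if measure not in columns:
        raise ValueError(f"unknown measure {measure!r}")
    if subset not in ("all", "never_split"):
        raise ValueError(f"unknown subset {subset!r}")

    df = data.loc[data["y"].notna()].copy()
    if subset == "never_split":
        df = df.loc[df["cage_role"] == "unsplit"]
    if measure == "survival":
        surv = _survival_per_cage(data)
        df["_x"] = df["cage_id"].map(surv)
    else:
        df["_x"] = df[columns[measure]]
    df = df.loc[df["_x"].notna()]
    x = df["_x"].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError(f"measure {measure!r} has fewer than 2 distinct values")

    separation = False
    if len(np.unique(y)) == 2:
        lo1, hi1 = x[y == 1].min(), x[y == 1].max()
        lo0, hi0 = x[y == 0].min(), x[y == 0].max()
        if lo1 > hi0 or hi1 < lo0:
            separation = True
            warnings.warn(
                f"complete separation for measure {measure!r}; "
                "ML estimates diverge"
            )
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    return GlmFit(
        measure=measure,
        subset=subset,
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        n=len(y),
        separation=separation,
    )
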