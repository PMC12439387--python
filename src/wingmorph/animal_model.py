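"""Bayesian binary animal models: random-intercept and random-slope (G x E).

The phenotypic model for a binary wing morph y_i is

    y_i ~ Bernoulli(p_i)
    logit(p_i) = alpha + beta x_i + c_i + a_i + e_i                (basic)
    logit(p_i) = alpha + (beta + a_{i,2}) x_i + c_i + a_{i,1} + e_i  (slope)

with cage effects c ~ N(0, V_C), breeding values linked to the pedigree
relatedness matrix A (a ~ N(0, V_A A), or bivariate MVN(0, G (x) A) with
G = [[V_A_I, C_A_IS], [C_A_IS, V_A_S]]), and a latent individual residual
e ~ N(0, V_R) with V_R fixed to 1.  The density covariate x is centred
(default at 6.5).  Priors: improper flat on fixed effects; half-Student-t
(3 df, scale auto-adjusted to the link-scale response dispersion, floored
at 2.5) on each standard deviation, realized through the Huang-Wand
hierarchy so all conditionals stay conjugate.

Sampling is by Polya-Gamma-augmented blocked Gibbs (see ``_gibbs``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from . import _gibbs
from .pedigree import RelatednessMatrix

__all__ = [
    "PriorSpec",
    "ModelSpec",
    "MCMCConfig",
    "PosteriorSamples",
    "fit_animal_model",
    "fit_logit_liability",
    "posterior_summary",
    "convergence_diagnostics",
    "hpd_interval",
]


@dataclass(frozen=True)
class PriorSpec:
    """Priors for the sampler (fixed effects are always improper flat).

    ``sd_scale=None`` auto-adjusts the half-t scale to the standard
    deviation of the link-scale working response, floored at ``sd_floor``.
    """

    sd_df: float = 3.0
    sd_scale: Optional[float] = None
    sd_floor: float = 2.5

    def resolve_scale(self, y: np.ndarray) -> float:
        if self.sd_scale is not None:
            if self.sd_scale <= 0:
                raise ValueError("sd_scale must be positive")
            return float(self.sd_scale)
        # working response on the logit scale
        w = np.log((y + 0.5) / (1.5 - y))
        return float(max(self.sd_floor, np.std(w)))


@dataclass(frozen=True)
class ModelSpec:
    """Which columns to model and which random terms to include."""

    response: str = "y"
    covariate: str = "nymphal_density"
    centre: float = 6.5
    random_slope: bool = False
    priors: PriorSpec = field(default_factory=PriorSpec)


@dataclass(frozen=True)
class MCMCConfig:
    """Chain lengths.  ``preset("paper")`` reproduces the published protocol."""

    n_chains: int = 2
    warmup: int = 2000
    sampling_iterations: int = 4000
    thin: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chains", "warmup", "sampling_iterations", "thin"):
            if getattr(self, name) < 1 and name != "warmup":
                raise ValueError(f"{name} must be positive")
        if self.warmup < 0:
            raise ValueError("warmup must be nonnegative")
        if self.thin > self.sampling_iterations:
            raise ValueError("thin must not exceed sampling_iterations")

    @classmethod
    def preset(cls, name: str, seed: int = 0) -> "MCMCConfig":
        if name == "paper":
            return cls(n_chains=2, warmup=50_000,
                       sampling_iterations=120_000, thin=70, seed=seed)
        if name == "desk":
            return cls(seed=seed)
        if name == "fast":
            return cls(n_chains=2, warmup=400,
                       sampling_iterations=800, thin=2, seed=seed)
        raise ValueError(f"unknown preset {name!r}")


@dataclass
class PosteriorSamples:
    """Per-chain, per-draw posterior values keyed by parameter name."""

    draws: Dict[str, np.ndarray]  # each (n_chains, n_draws)
    meta: dict = field(default_factory=dict)

    @property
    def parameters(self) -> List[str]:
        return list(self.draws)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def pooled(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def to_dataframe(self) -> pd.DataFrame:
        """Pooled draws, one row per draw, one column per parameter."""
        return pd.DataFrame({k: self.pooled(k) for k in self.draws})


# ---------------------------------------------------------------------------
# relatedness precision
# ---------------------------------------------------------------------------

def _ainv_csr(A: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Invert A blockwise over its connected components.

    Returns (indptr, indices, data) for the *off-diagonal* entries of A^-1
    plus the diagonal as a separate vector.  Family-structured pedigrees
    give small blocks, so this is cheap and keeps the precision sparse.
    """
    n = A.shape[0]
    eig_min = np.linalg.eigvalsh(A).min() if n <= 4000 else None
    if eig_min is not None and eig_min < -1e-8:
        raise ValueError("relatedness matrix is not positive semi-definite")
    adj = sparse.csr_matrix(np.abs(A) > 1e-12)
    n_comp, labels = connected_components(adj, directed=False)
    rows: List[np.ndarray] = []
    cols: List[np.ndarray] = []
    vals: List[np.ndarray] = []
    diag = np.empty(n)
    for comp in range(n_comp):
        idx = np.flatnonzero(labels == comp)
        block = A[np.ix_(idx, idx)]
        binv = np.linalg.inv(block)
        diag[idx] = np.diag(binv)
        np.fill_diagonal(binv, 0.0)
        r, cidx = np.nonzero(np.abs(binv) > 1e-12)
        rows.append(idx[r])
        cols.append(idx[cidx])
        vals.append(binv[r, cidx])
    coo = sparse.coo_matrix(
        (np.concatenate(vals) if vals else np.empty(0),
         (np.concatenate(rows) if rows else np.empty(0, dtype=int),
          np.concatenate(cols) if cols else np.empty(0, dtype=int))),
        shape=(n, n),
    ).tocsr()
    return (
        coo.indptr.astype(np.int64),
        coo.indices.astype(np.int64),
        coo.data.astype(np.float64),
        diag,
    )


def _check_separation(y: np.ndarray, x: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        warnings.warn("response is constant; the prior alone regularizes")
        return
    lo1, hi0 = x[y == 1].min(), x[y == 0].max()
    if lo1 > hi0 or x[y == 1].max() < x[y == 0].min():
        warnings.warn(
            "complete separation: the covariate perfectly predicts the "
            "response; coefficients are identified only through the prior"
        )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_logit_liability(
    y: np.ndarray,
    X: np.ndarray,
    fixed_names: Sequence[str],
    cage_codes: np.ndarray,
    A: np.ndarray,
    slope_covariate: Optional[np.ndarray],
    mcmc: MCMCConfig,
    priors: PriorSpec = PriorSpec(),
    v_r: float = 1.0,
    freeze_slope: bool = False,
    slope_fixed_col: Optional[int] = None,
) -> PosteriorSamples:
    """Low-level fit on prepared arrays (rows of ``A`` match rows of ``y``).

    ``slope_covariate=None`` fits the basic (random-intercept) model;
    ``freeze_slope=True`` runs the random-slope machinery with the slope
    variance pinned at zero (used to verify that the slope model nests the
    basic one).
    """
    y = np.asarray(y, dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    n = y.shape[0]
    if X.shape[0] != n or A.shape != (n, n):
        raise ValueError("inconsistent shapes between y, X and A")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("response must be binary 0/1")

    cages, cage_idx = np.unique(cage_codes, return_inverse=True)
    indptr, indices, data, diag = _ainv_csr(A)
    scale = priors.resolve_scale(y)

    if slope_covariate is None:
        mode = _gibbs.MODE_INTERCEPT
        zcov = np.zeros(n)
        slope_col = -1
    else:
        zcov = np.asarray(slope_covariate, dtype=np.float64)
        mode = _gibbs.MODE_SLOPE_FROZEN if freeze_slope else _gibbs.MODE_SLOPE
        if np.ptp(zcov) == 0:
            warnings.warn("slope covariate is constant; V_A_S is unidentified")
        if slope_fixed_col is not None:
            slope_col = slope_fixed_col
        else:  # auto-detect the fixed-effect column carrying the covariate
            slope_col = -1
            for j in range(X.shape[1]):
                if np.array_equal(X[:, j], zcov):
                    slope_col = j
                    break

    n_iter = mcmc.warmup + mcmc.sampling_iterations
    chain_seeds = np.random.SeedSequence(mcmc.seed).generate_state(
        mcmc.n_chains
    ) % (2**31 - 1)

    chains = []
    for ch in range(mcmc.n_chains):
        draws = _gibbs.run_chain(
            int(chain_seeds[ch]),
            y,
            X,
            cage_idx.astype(np.int64),
            int(len(cages)),
            zcov,
            int(mode),
            indptr,
            indices,
            data,
            diag,
            float(scale),
            float(v_r),
            int(mcmc.warmup),
            int(n_iter),
            int(mcmc.thin),
            int(slope_col),
        )
        chains.append(draws)
    stacked = np.stack(chains)  # (chains, kept, npar)

    p = X.shape[1]
    names = list(fixed_names) + ["V_C", "V_A_I", "V_A_S", "C_A_IS"]
    out: Dict[str, np.ndarray] = {
        nm: stacked[:, :, j] for j, nm in enumerate(names)
    }
    if mode != _gibbs.MODE_SLOPE:
        out.pop("V_A_S")
        out.pop("C_A_IS")
        out["V_A"] = out.pop("V_A_I")
    meta = {
        "mode": {0: "intercept", 1: "slope", 2: "slope_frozen"}[mode],
        "prior_scale": scale,
        "prior_df": priors.sd_df,
        "v_r": v_r,
        "mcmc": mcmc,
        "n_obs": n,
        "n_cages": int(len(cages)),
        "seed": mcmc.seed,
    }
    return PosteriorSamples(draws=out, meta=meta)


def fit_animal_model(
    data: pd.DataFrame,
    A: RelatednessMatrix,
    spec: ModelSpec = ModelSpec(),
    mcmc: MCMCConfig = MCMCConfig(),
) -> PosteriorSamples:
    """Fit the basic or random-slope animal model to a phenotype table.

    ``data`` must contain the response, covariate, ``cage_id`` and ``id``
    columns; ``A`` must cover every phenotyped individual (extra ids are
    dropped, order is aligned automatically).
    """
    df = data.loc[data[spec.response].notna()].copy()
    if df.empty:
        raise ValueError("no phenotyped individuals")
    y = df[spec.response].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("non-binary response")
    xraw = df[spec.covariate].to_numpy(dtype=float)
    if np.isnan(xraw).any():
        raise ValueError("covariate contains missing values")
    if np.ptp(xraw) == 0:
        raise ValueError("covariate is constant")
    x = xraw - spec.centre

    ids = df["id"].astype(str).tolist()
    missing = set(ids) - set(map(str, A.ids))
    if missing:
        raise ValueError(
            f"relatedness matrix does not cover {len(missing)} phenotyped "
            f"individuals (e.g. {sorted(missing)[:3]})"
        )
    Asub = A.reorder(ids).A

    _check_separation(y, x)
    X = np.column_stack([np.ones(len(y)), x])
    samples = fit_logit_liability(
        y=y,
        X=X,
        fixed_names=["alpha", "beta"],
        cage_codes=df["cage_id"].to_numpy(),
        A=Asub,
        slope_covariate=x if spec.random_slope else None,
        mcmc=mcmc,
        priors=spec.priors,
    )
    samples.meta["spec"] = spec
    samples.meta["covariate_centred_mean"] = float(x.mean())
    samples.meta["covariate_centred_var"] = float(x.var())
    return samples


# ---------------------------------------------------------------------------
# summaries and diagnostics
# ---------------------------------------------------------------------------

def hpd_interval(draws: np.ndarray, prob: float = 0.95) -> Tuple[float, float]:
    """Shortest interval containing ``prob`` of the pooled draws."""
    x = np.sort(np.asarray(draws).reshape(-1))
    n = len(x)
    if n == 0:
        raise ValueError("empty draws")
    k = max(1, int(np.ceil(prob * n)))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + k])


def posterior_summary(
    samples: PosteriorSamples, prob: float = 0.95, min_draws: int = 100
) -> pd.DataFrame:
    """Median, SD and HPD interval per parameter over pooled chains."""
    total = samples.n_chains * samples.n_draws
    if total == 0:
        raise ValueError("empty posterior samples")
    if total < min_draws:
        raise ValueError(
            f"need at least {min_draws} draws for a summary, got {total}"
        )
    rows = []
    for name in samples.parameters:
        pooled = samples.pooled(name)
        lo, hi = hpd_interval(pooled, prob)
        rows.append(
            {
                "parameter": name,
                "median": float(np.median(pooled)),
                "sd": float(np.std(pooled, ddof=1)) if total > 1 else 0.0,
                "hpd_low": lo,
                "hpd_high": hi,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def convergence_diagnostics(
    samples: PosteriorSamples,
    rhat_max: float = 1.01,
    ess_min: float = 400.0,
) -> pd.DataFrame:
    """Rank-normalized split R-hat and bulk ESS per parameter.

    With a single chain R-hat is undefined and flagged as NaN.
    """
    import arviz as az

    rows = []
    single = samples.n_chains < 2
    if single:
        warnings.warn("single chain: R-hat undefined")
    for name in samples.parameters:
        arr = samples.draws[name]
        rhat = float(az.rhat(arr)) if not single else float("nan")
        ess = float(az.ess(arr))
        rows.append(
            {
                "parameter": name,
                "rhat": rhat,
                "ess": ess,
                "converged": (np.isnan(rhat) or rhat <= rhat_max)
                and ess >= ess_min,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
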