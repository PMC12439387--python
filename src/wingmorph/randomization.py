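"""Randomization-based significance test for the G x E random-slope variance.

Posterior distributions of variance components are bounded away from zero
even under a true null, so credible intervals alone cannot establish the
significance of the random-slope (G x E) variance.  Instead, the observed
random-slope model is compared against a set of null fits in which the
density vector is permuted: each null model keeps the *real* density as a
fixed effect and the pedigree random intercept, while the *permuted*
density enters both as an additional fixed effect and as the random-slope
covariate.  With 19 permutations, the real data being the 20th arrangement,
a real posterior exceeding all nulls corresponds to a 95% (19/20)
confidence statement.

The comparison statistic is the posterior median of the random-slope
variance (a mean option is provided); the verdict is "significant" when
the real statistic strictly exceeds every null statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd

from .animal_model import MCMCConfig, PosteriorSamples, PriorSpec, fit_logit_liability
from .pedigree import RelatednessMatrix

__all__ = ["NullTestResult", "randomization_null_test", "permute_densities"]


@dataclass
class NullTestResult:
    """Real-fit summary, null-fit summaries and the significance verdict."""

    real_statistic: float
    null_statistics: List[float]
    significant: bool
    statistic: str
    n_rand: int
    seed: int
    real_samples: PosteriorSamples = field(repr=False, default=None)
    null_samples: List[PosteriorSamples] = field(repr=False, default_factory=list)

    @property
    def exceedance_rank(self) -> int:
        """Number of null statistics strictly below the real one."""
        return int(sum(s < self.real_statistic for s in self.null_statistics))

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "real": self.real_statistic,
            "null": list(self.null_statistics),
            "significant": bool(self.significant),
            "n_rand": self.n_rand,
            "seed": self.seed,
        }


def permute_densities(
    x: np.ndarray,
    rng: np.random.Generator,
    cage_codes: Optional[np.ndarray] = None,
    max_tries: int = 100,
) -> np.ndarray:
    """Permutation of the density vector, redrawn if identical to the input.

    ``cage_codes`` switches to cage-blocked permutation: cages keep their
    membership and cage-level densities are shuffled between cages, so each
    individual receives the density of its cage's new label.
    """
    x = np.asarray(x, dtype=float)
    for _ in range(max_tries):
        if cage_codes is None:
            perm = rng.permutation(x)
        else:
            cages, inv = np.unique(cage_codes, return_inverse=True)
            cage_x = np.empty(len(cages))
            for k in range(len(cages)):
                cage_x[k] = x[inv == k][0]
            perm = rng.permutation(cage_x)[inv]
        if not np.array_equal(perm, x):
            return perm
    return perm  # constant vector: permutation cannot differ


def _stat(samples: PosteriorSamples, statistic: str) -> float:
    draws = samples.pooled("V_A_S")
    if statistic == "median":
        return float(np.median(draws))
    if statistic == "mean":
        return float(np.mean(draws))
    raise ValueError(f"unknown statistic {statistic!r}")


def randomization_null_test(
    data: pd.DataFrame,
    A: RelatednessMatrix,
    mcmc: MCMCConfig,
    n_rand: int = 19,
    seed: int = 0,
    statistic: str = "median",
    permute: str = "individual",
    centre: float = 6.5,
    covariate: str = "nymphal_density",
    response: str = "y",
    priors: PriorSpec = PriorSpec(),
    keep_samples: bool = True,
    null_mcmc: Optional[MCMCConfig] = None,
) -> NullTestResult:
    """Fit the real random-slope model and ``n_rand`` permutation nulls.

    All randomness (permutations and every MCMC chain) derives from
    ``seed``, so results are bit-reproducible.  ``null_mcmc`` optionally
    runs the permutation fits at different (typically cheaper) settings
    than the real fit: Monte-Carlo noise in a null median only raises the
    maximum the real statistic must beat, so economizing there is
    conservative, whereas the real fit's median should be estimated well.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be at least 1")
    if permute not in ("individual", "cage"):
        raise ValueError("permute must be 'individual' or 'cage'")

    df = data.loc[data[response].notna()]
    y = df[response].to_numpy(dtype=float)
    x = df[covariate].to_numpy(dtype=float) - centre
    cage_codes = df["cage_id"].to_numpy()
    ids = df["id"].astype(str).tolist()
    Asub = A.reorder(ids).A

    ss = np.random.SeedSequence(seed)
    perm_rng = np.random.default_rng(ss.spawn(1)[0])
    fit_seeds = ss.generate_state(n_rand + 1) % (2**31 - 1)

    # real fit: intercept + real density fixed effect, real-density slope
    X_real = np.column_stack([np.ones(len(y)), x])
    real = fit_logit_liability(
        y, X_real, ["alpha", "beta"], cage_codes, Asub,
        slope_covariate=x,
        mcmc=MCMCConfig(
            n_chains=mcmc.n_chains, warmup=mcmc.warmup,
            sampling_iterations=mcmc.sampling_iterations, thin=mcmc.thin,
            seed=int(fit_seeds[0]),
        ),
        priors=priors,
    )
    real_stat = _stat(real, statistic)

    if null_mcmc is None:
        null_mcmc = mcmc
    null_stats: List[float] = []
    null_samples: List[PosteriorSamples] = []
    for r in range(n_rand):
        xp = permute_densities(
            x, perm_rng, cage_codes if permute == "cage" else None
        )
        # real density stays as fixed effect; permuted density enters as an
        # extra fixed effect and as the random-slope covariate
        X_null = np.column_stack([np.ones(len(y)), x, xp])
        null = fit_logit_liability(
            y, X_null, ["alpha", "beta", "beta_perm"], cage_codes, Asub,
            slope_covariate=xp,
            mcmc=MCMCConfig(
                n_chains=null_mcmc.n_chains, warmup=null_mcmc.warmup,
                sampling_iterations=null_mcmc.sampling_iterations,
                thin=null_mcmc.thin,
                seed=int(fit_seeds[r + 1]),
            ),
            priors=priors,
        )
        null_stats.append(_stat(null, statistic))
        if keep_samples:
            null_samples.append(null)

    return NullTestResult(
        real_statistic=real_stat,
        null_statistics=null_stats,
        significant=bool(real_stat > max(null_stats)),
        statistic=statistic,
        n_rand=n_rand,
        seed=seed,
        real_samples=real if keep_samples else None,
        null_samples=null_samples,
    )
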