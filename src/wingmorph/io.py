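"""File readers and writers: phenotype/pedigree CSVs, posterior draws,
variance tables and null-test results.

One CSV dialect throughout: comma-separated, UTF-8, header required,
"." decimal.  Posterior draws round-trip through a CSV of one row per draw
plus a JSON metadata sidecar carrying the seed and sampler settings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .animal_model import MCMCConfig, PosteriorSamples
from .randomization import NullTestResult
from .simulate import PHENOTYPE_COLUMNS, SimulationConfig

__all__ = [
    "RunConfig",
    "read_phenotypes",
    "write_phenotypes",
    "write_posterior",
    "read_posterior",
    "write_results",
    "write_nulltest",
]

REQUIRED_COLUMNS = ["id", "sire", "dam", "cage_id", "nymphal_density", "y"]


@dataclass
class RunConfig:
    """Top-level pipeline configuration (seed + per-stage settings)."""

    seed: int = 0
    out_dir: str = "wingmorph_out"
    model: str = "slope"  # or "intercept"
    mcmc_preset: Optional[str] = None
    n_chains: int = 2
    warmup: int = 2000
    sampling_iterations: int = 4000
    thin: int = 2
    n_rand: int = 19
    permute: str = "individual"
    statistic: str = "median"
    centre: float = 6.5
    simulation: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: raw[k] for k in raw if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def mcmc(self, seed: Optional[int] = None) -> MCMCConfig:
        s = self.seed if seed is None else seed
        if self.mcmc_preset:
            return MCMCConfig.preset(self.mcmc_preset, seed=s)
        return MCMCConfig(
            n_chains=self.n_chains,
            warmup=self.warmup,
            sampling_iterations=self.sampling_iterations,
            thin=self.thin,
            seed=s,
        )

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(seed=self.seed, **self.simulation)

    def digest(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir", None)  # output location is not part of identity
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype CSV, validating columns and the binary response.

    Rows with a missing response are kept (they are non-phenotyped
    individuals such as pre-adult deaths); any non-missing response value
    other than 0/1 is an error.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file missing column(s): {missing}")
    y = df["y"]
    bad = y.dropna()[~y.dropna().isin((0, 1))]
    if len(bad):
        raise ValueError(
            f"non-binary response: values {sorted(bad.unique())[:5]} in 'y'"
        )
    return df


def write_phenotypes(data: pd.DataFrame, path) -> None:
    cols = [c for c in PHENOTYPE_COLUMNS if c in data.columns]
    cols += [c for c in data.columns if c not in cols]
    data[cols].to_csv(path, index=False)


def write_posterior(samples: PosteriorSamples, path, meta_path=None) -> None:
    """Posterior draws as CSV (row per draw) + JSON metadata sidecar."""
    path = Path(path)
    df = samples.to_dataframe()
    df.insert(0, "chain", np.repeat(np.arange(samples.n_chains), samples.n_draws))
    df.insert(1, "draw", np.tile(np.arange(samples.n_draws), samples.n_chains))
    df.to_csv(path, index=False)
    meta_path = Path(meta_path) if meta_path else path.with_suffix(".meta.json")
    meta = {}
    for k, v in samples.meta.items():
        if isinstance(v, MCMCConfig):
            meta[k] = asdict(v)
        elif isinstance(v, (str, int, float, bool, list, dict, type(None))):
            meta[k] = v
        else:
            meta[k] = repr(v)
    with open(meta_path, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1)


def read_posterior(path, meta_path=None) -> PosteriorSamples:
    path = Path(path)
    df = pd.read_csv(path)
    chains = sorted(df["chain"].unique())
    params = [c for c in df.columns if c not in ("chain", "draw")]
    draws = {}
    for p in params:
        draws[p] = np.stack(
            [df.loc[df["chain"] == ch, p].to_numpy() for ch in chains]
        )
    meta_path = Path(meta_path) if meta_path else path.with_suffix(".meta.json")
    meta = {}
    if meta_path.exists():
        with open(meta_path, "r", encoding="utf-8") as fh:
            meta = json.load(fh)
    return PosteriorSamples(draws=draws, meta=meta)


def write_results(results, path, format: str = "csv"):
    """Serialize a result table/dict; reading back reproduces the values.

    DataFrames go to CSV (or JSON ``orient="table"``); dictionaries go to
    JSON.  Returns the path written.
    """
    path = Path(path)
    if format not in ("csv", "json"):
        raise ValueError("format must be 'csv' or 'json'")
    if isinstance(results, pd.DataFrame):
        if format == "csv":
            results.to_csv(path)
        else:
            results.to_json(path, orient="table", double_precision=15)
    elif isinstance(results, dict):
        if format == "csv":
            pd.DataFrame([results]).to_csv(path, index=False)
        else:
            with open(path, "w", encoding="utf-8") as fh:
                json.dump(results, fh, indent=1)
    else:
        raise TypeError(f"cannot serialize {type(results).__name__}")
    return path


def write_nulltest(result: NullTestResult, path) -> None:
    """Null-test verdict with real + null summaries as JSON."""
    payload = result.to_dict()
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
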