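import numpy as np
import pandas as pd
import pytest

from wingmorph.pedigree import PedigreeRecord, build_pedigree, relatedness_matrix
from wingmorph.simulate import SimulationConfig, pedigree_from_data, simulate_dataset


@pytest.fixture(scope="session")
def two_gen_pedigree():
    """2 sires x 2 dams x 3 offspring: full sibs, half sibs, unrelated."""
    records = [PedigreeRecord(f"S{i}") for i in (1, 2)]
    records += [PedigreeRecord(f"D{i}") for i in (1, 2, 3, 4)]
    k = 0
    for s, dams in (("S1", ("D1", "D2")), ("S2", ("D3", "D4"))):
        for d in dams:
            for _ in range(3):
                k += 1
                records.append(PedigreeRecord(f"O{k}", sire=s, dam=d))
    return build_pedigree(records)


@pytest.fixture(scope="session")
def small_dataset():
    """Small simulated breeding design (~500 phenotyped) with pedigree/A."""
    cfg = SimulationConfig(n_sires=10, seed=424241)
    data = simulate_dataset(cfg)
    ped = pedigree_from_data(data)
    ids = data.loc[data["y"].notna(), "id"].astype(str).tolist()
    A = relatedness_matrix(ped, subset=ids)
    return data, ped, A, cfg


@pytest.fixture(scope="session")
def medium_dataset():
    """Mid-size design (~1500 phenotyped) for fitting tests."""
    cfg = SimulationConfig(n_sires=28, seed=777)
    data = simulate_dataset(cfg)
    ped = pedigree_from_data(data)
    ids = data.loc[data["y"].notna(), "id"].astype(str).tolist()
    A = relatedness_matrix(ped, subset=ids)
    return data, ped, A, cfg
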