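import numpy as np
import pandas as pd
import pytest

from clockforge.datatypes import MethylationDataset
from clockforge.synthetic import SimulationConfig, generate_dataset


def make_dataset(beta: np.ndarray, ages, sexes=None, tissues=None, groups=None,
                 species=None, probe_meta=None) -> MethylationDataset:
    """Hand-build a small dataset: beta is probes x samples."""
    beta = np.asarray(beta, dtype=float)
    p, n = beta.shape
    sample_ids = [f"s{i}" for i in range(n)]
    probe_ids = [f"cg{j}" for j in range(p)]
    samples = pd.DataFrame(
        {
            "age": np.asarray(ages, dtype=float),
            "sex": list(sexes) if sexes is not None else (["F", "M"] * n)[:n],
            "tissue": list(tissues) if tissues is not None else ["blood"] * n,
            "group": list(groups) if groups is not None else ["sex_naive"] * n,
            "species": list(species) if species is not None else ["vole"] * n,
        },
        index=pd.Index(sample_ids),
    )
    probes = pd.DataFrame(
        {
            "chromosome": ["chr1"] * p,
            "position": np.arange(1, p + 1) * 100,
            "gene": [""] * p,
            "tss_distance": [0] * p,
            "island": [False] * p,
            "chromatin_state": ["NA"] * p,
        },
        index=pd.Index(probe_ids),
    )
    if probe_meta:
        for key, values in probe_meta.items():
            probes[key] = values
    return MethylationDataset(
        beta=pd.DataFrame(beta, index=probe_ids, columns=sample_ids),
        samples=samples,
        probes=probes,
    )


@pytest.fixture(scope="session")
def benchmark():
    """The cross-module benchmark: 200 samples, 2000 CpGs, 100 age CpGs."""
    return generate_dataset(SimulationConfig(seed=5))


@pytest.fixture(scope="session")
def noiseless_linear_ds():
    """60 samples, one CpG tracking age exactly: beta = 0.1 + 0.5 * age_frac."""
    rng = np.random.default_rng(4)
    ages = rng.uniform(0.0, 1.31, 60)
    beta = (0.1 + 0.5 * ages / 1.31)[None, :]
    return make_dataset(beta, ages)
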