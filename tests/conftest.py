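"""Shared simulated fixtures for the test suite.

Session-scoped so the simulator runs once per configuration; tests must not
mutate fixture objects in place (use ``take_sites``/``take_samples`` copies).
"""

import numpy as np
import pytest

import paracline as pc


@pytest.fixture(scope="session")
def ds_default():
    """Default two-transect dataset: 200 genes, ~1000 SNPs, 100 samples."""
    return pc.simulate_dataset(pc.SimConfig(seed=0))


@pytest.fixture(scope="session")
def filtered_gm(ds_default):
    gm = pc.drop_sex_chromosomes(ds_default.gm)
    return pc.filter_sites(gm, ds_default.samples)


@pytest.fixture(scope="session")
def null_onetransect():
    """One-transect null dataset: no cline, no genetic effect, complete calls."""
    cfg = pc.SimConfig(
        seed=11,
        n_transects=1,
        n_genes=400,
        h2=0.0,
        sex_effect=0.0,
        clinal_fraction=0.0,
        missing_rate=0.0,
    )
    ds = pc.simulate_dataset(cfg)
    f = ds.gm.allele_frequencies()
    gm = ds.gm.take_sites((f > 0) & (f < 1))
    return ds, gm


def env_per_sample(ds, transect=None):
    """Mean-annual-temperature vector aligned with the sample table."""
    env_by_pop = ds.pops.set_index("population")["env"]
    samples = ds.samples
    if transect is not None:
        samples = samples[samples["transect"] == transect]
    return samples["population"].map(env_by_pop).to_numpy(dtype=float)


def intercept_sex(samples) -> np.ndarray:
    return np.column_stack(
        [np.ones(len(samples)), (samples["sex"] == "M").to_numpy(dtype=float)]
    )
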