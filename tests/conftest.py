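import numpy as np
import pandas as pd
import pytest

from icmeth import score, simulate


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_config():
    return simulate.default_config(
        seed=7,
        n_participants=300,
        n_cpgs=400,
        n_causal_cpgs=8,
        n_celltype_cpgs=60,
        n_genes=300,
        n_ic_genes=20,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_scored(small_cohort):
    return score.score_cohort(small_cohort)


@pytest.fixture(scope="session")
def small_ic(small_scored):
    return small_scored.table["overall_ic"]


@pytest.fixture(scope="session")
def small_methylome(small_cohort, small_ic, small_config):
    return simulate.simulate_methylome(small_cohort, small_ic, small_config)


def make_complete_cohort(n=50, seed=0):
    """A small fully observed instrument table with realistic ranges."""
    r = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "age": r.uniform(20, 100, n),
            "sex": np.where(r.random(n) < 0.5, "male", "female"),
            "mmse": r.uniform(10, 30, n),
            "sppb": r.uniform(0, 12, n),
            "phq9": r.uniform(0, 27, n),
            "vision": r.uniform(0, 3, n),
            "hearing": r.uniform(0, 2, n),
            "grip": r.uniform(10, 60, n),
        },
        index=[f"P{i:04d}" for i in range(n)],
    )
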