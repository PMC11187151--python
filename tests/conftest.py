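import numpy as np
import pytest
from hypothesis import settings

import msipanel as mp

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_cohort() -> mp.CohortData:
    """Small paired cohort shared by read-only tests."""
    cfg = mp.SimulationConfig(
        seed=3,
        n_paired_patients=20,
        n_unmatched_tumors=0,
        frac_dmmr=0.5,
        n_loci=40,
        n_informative=4,
        families_per_locus=40.0,
    )
    return mp.simulate_cohort(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_dna(rng: np.random.Generator, n: int, p_n: float = 0.0) -> str:
    if p_n > 0:
        p = [(1 - p_n) / 4] * 4 + [p_n]
        return "".join(rng.choice(list("ACGTN"), size=n, p=p))
    return "".join(rng.choice(list("ACGT"), size=n))
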