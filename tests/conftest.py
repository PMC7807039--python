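import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True)
settings.load_profile("default")

from binodex import (
    BinormalMixture,
    NormalComponent,
    build_histogram,
    generate_cohort,
    preprocess,
)
from binodex.synthetic import CohortSpec

# Fitted components reported for the 54-59-year PSA stratum; used throughout
# as the canonical worked example.
MU1, SIGMA1 = -0.124, 0.643
MU2, SIGMA2 = 1.033, 0.766
PR = 0.198


@pytest.fixture
def neg():
    return NormalComponent(MU1, SIGMA1)


@pytest.fixture
def pos():
    return NormalComponent(MU2, SIGMA2)


@pytest.fixture
def printed_mix(neg, pos):
    return BinormalMixture(neg=neg, pos=pos, pr=PR)


def make_cohort_spec(pr: float, seed: int, n: int, band: str = "50-59", mu1: float = MU1) -> CohortSpec:
    """Single-band cohort at the worked-example components."""
    return CohortSpec(
        n=n,
        pr={band: pr},
        neg_mu_by_age={band: mu1},
        neg_sigma=SIGMA1,
        pos=NormalComponent(MU2, SIGMA2),
        age_distribution={band: 1.0},
        seed=seed,
    )


def cohort_histogram(pr: float, seed: int, n: int):
    """Histogram of one simulated cohort, through the standard preprocessing."""
    table = generate_cohort(make_cohort_spec(pr, seed, n))
    return build_histogram(preprocess(table["value"].to_numpy()))


def spawn_seeds(s: int, k: int = 2) -> list[int]:
    """k independent child seeds (< 2**31) derived from one master seed."""
    return [int(c.generate_state(1)[0] % 2**31) for c in np.random.SeedSequence(s).spawn(k)]
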