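import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nnnfit as nf

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref_table():
    """Packaged reference triplet/covariate parameter table."""
    return nf.reference_table()


@pytest.fixture(scope="session")
def independent_seqs():
    """Packaged 49 circular 12-mers with independent triplet count vectors."""
    return nf.reference_independent_sequences()


@pytest.fixture(scope="session")
def sim_truth():
    return nf.generate_truth(seed=1)


@pytest.fixture(scope="session")
def sim_experiments(sim_truth):
    """112 synthetic experiments matching the canonical design shape."""
    return nf.generate_experiments(sim_truth, n=112, seed=1)


@pytest.fixture(scope="session")
def sim_fit(sim_experiments):
    return nf.svd_fit(nf.build_design(sim_experiments))


def random_circular(rng: np.random.Generator, length: int) -> nf.NucleotideSequence:
    return nf.NucleotideSequence(
        "".join(rng.choice(list("ACGU"), size=length)), topology="circular"
    )
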