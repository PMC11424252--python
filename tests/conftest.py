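import numpy as np
import pytest

from tcatrace.tca import TCAParams, TracerSpec, simulate


@pytest.fixture(scope="session")
def acetate_first_turn():
    """Fully enriched acetate tracer, single turn, no other entry routes."""
    params = TCAParams(
        pdh_fraction=0.0,
        pc_fraction=0.0,
        anaplerosis_unlabelled=0.0,
        turnover=1.0,
        reductive_fraction=0.0,
        n_turns=1,
    )
    return simulate(TracerSpec("acetate_12_13C2", enrichment=1.0), params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240814)


def random_mid(rng: np.random.Generator, n_carbons: int) -> np.ndarray:
    return rng.dirichlet(np.ones(n_carbons + 1))
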