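import numpy as np
import pytest
from hypothesis import settings

from pirna_soma import synthetic_data as sim

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def catalog():
    """One toy reference catalog shared across the suite."""
    return sim.build_toy_references(seed=123)


@pytest.fixture(scope="session")
def small_control(catalog):
    """A modest control library plus its truth manifest."""
    cfg = sim.SimConfig(seed=123, n_reads=10_000)
    reads, manifest = sim.simulate_library(cfg, "control", catalog, seed=777)
    return cfg, reads, manifest


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), n))
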