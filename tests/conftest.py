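import numpy as np
import pytest

from cmapoly.lattice import LatticeSpec
from cmapoly.rng import Pcg32
from cmapoly.state import RunConfig, build_initial


@pytest.fixture
def spec8():
    return LatticeSpec(8)


@pytest.fixture
def rng():
    return Pcg32(12345)


@pytest.fixture
def dilute_small():
    """A small mobile polymer+solvent system."""
    return build_initial(RunConfig(N=4, n_chains=3, L=8, seed=1))


@pytest.fixture
def melt_small():
    """A small melt (phi = 1) that the engine can unfreeze."""
    from cmapoly.state import build_disordered

    return build_disordered(RunConfig(N=8, n_chains=32, L=16, seed=2))


def random_saw_chain(N: int, spec: LatticeSpec, seed: int):
    """A random valid in-box chain (pivot-sampled, translated)."""
    from cmapoly.fixtures import sample_saw_chains
    from cmapoly.state import Chain

    conf = sample_saw_chains(N, 1, seed)[0]
    rng = np.random.default_rng(seed)
    ab = (conf + rng.integers(0, spec.edge, size=2)) % spec.edge
    beads = np.column_stack([ab, np.zeros(N, dtype=np.int64)])
    return Chain(0, beads.astype(np.int32))
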