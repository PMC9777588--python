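import numpy as np
import pytest

from chainthermo import (
    DrivenChain,
    GeneratorSpec,
    counterexample_chain,
    cycle_chain,
    db2_chain,
    energy_family,
    random_chain,
)


@pytest.fixture
def db2():
    """Two-state, two-step chain with detailed balance and p0 = p1."""
    return db2_chain()


@pytest.fixture
def counterexample3():
    """The three-state Crooks counterexample at (a, b, c) = (0.5, 0.2, 0.3)."""
    return counterexample_chain()


@pytest.fixture
def cycle3():
    """Deterministic 3-cycle: irreducible, periodic, non-reversible."""
    return cycle_chain(3, 2)


@pytest.fixture
def flat_chain():
    """A chain whose reference distributions (hence energies) all coincide."""
    M = np.array([[0.9, 0.2], [0.1, 0.8]])
    chain = DrivenChain(
        states=(0, 1),
        p0=np.array([2.0 / 3.0, 1.0 / 3.0]),
        matrices=(M, M),
        beta=1.0,
    )
    return chain, energy_family(chain)


def make_random_chain(seed, mode="generic", equilibrated=False, min_states=2,
                      max_states=4, max_steps=3):
    """A small random chain with size drawn reproducibly from the seed."""
    rng = np.random.default_rng(seed)
    spec = GeneratorSpec(
        n_states=int(rng.integers(min_states, max_states + 1)),
        n_steps=int(rng.integers(1, max_steps + 1)),
        seed=int(rng.integers(2**31)),
        mode=mode,
        equilibrated=equilibrated,
    )
    return random_chain(spec)
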