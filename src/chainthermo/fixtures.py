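"""Reference chains and seeded random-chain generators.

Three small chains anchor the test surface:

* the three-state two-point counterexample chain, where the initial
  distribution is *not* stationary for the first matrix and the Crooks
  relation fails at every work value even though detailed balance holds;
* ``db2``, a minimal two-state, two-step chain with detailed balance and
  ``p_0 = p_1``, on which every fluctuation identity holds and every number
  is checkable by hand;
* a cyclic permutation chain, irreducible but maximally non-reversible.

The generators produce reproducible random chains in three classes: generic
(strictly positive entries, hence irreducible), detailed-balance (Metropolis
matrices against random targets, hence reversible), and permutation
(periodic, deterministic dynamics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain import DrivenChain, stationary_distribution
from .decision import named_proposal, policy_transition_matrix
from .thermo import EnergyFamily, energy_family

__all__ = [
    "GeneratorSpec",
    "counterexample_chain",
    "db2_chain",
    "cycle_chain",
    "random_chain",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters for the seeded random-chain generator.

    ``mode`` selects the chain class (``generic`` | ``detailed_balance`` |
    ``permutation``); ``floor`` is the minimum entry in generic matrices
    (positivity implies irreducibility); ``equilibrated`` sets ``p0`` to the
    stationary distribution of the first matrix, satisfying the Crooks
    hypothesis by construction.
    """

    n_states: int = 3
    n_steps: int = 2
    seed: int = 0
    mode: str = "generic"
    floor: float = 1e-3
    equilibrated: bool = False

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise ValueError("need at least 2 states")
        if self.n_steps < 1:
            raise ValueError("need at least 1 step")
        if self.mode not in ("generic", "detailed_balance", "permutation"):
            raise ValueError(f"unknown generator mode {self.mode!r}")
        if not 0 <= self.floor * self.n_states < 1:
            raise ValueError("floor too large for the number of states")


def counterexample_chain(
    a: float = 0.5, b: float = 0.2, c: float = 0.3
) -> tuple[DrivenChain, EnergyFamily]:
    """The three-state chain on which the Crooks relation fails everywhere.

    States {A, B, C}, one step, beta = 1, initial distribution ``(a, b, c)``
    and a transition matrix with constant rows ``(a), (c), (b)`` — it has
    strictly positive entries and satisfies detailed balance with respect to
    its stationary distribution ``p_1 = (a, c, b)``.  The energies are
    ``E_0 = (log 1/a, log 1/b, log 1/c)`` and ``E_1`` with the B and C
    values swapped, so the work atoms are ``w_A = 0``, ``w_B = log(b/c) < 0``
    and ``w_C = log(c/b) > 0``.  Because ``p_0 != p_1``, the reversed process
    does no work at all (point mass at 0) and the forward/backward ratio is
    undefined at ``w_B, w_C`` and wrong at ``w_A``.

    Requires ``a, b, c > 0``, ``b < c`` and ``a + b + c = 1``.
    """
    if not (a > 0 and b > 0 and c > 0):
        raise ValueError("requires a, b, c > 0")
    if abs(a + b + c - 1.0) > 1e-12:
        raise ValueError("requires a + b + c = 1")
    if not b < c:
        raise ValueError("requires b < c (strict), so that w_B < 0 < w_C")
    p0 = np.array([a, b, c])
    p1 = np.array([a, c, b])
    M1 = np.column_stack([p1, p1, p1])  # every column is (a, c, b)
    chain = DrivenChain(states=("A", "B", "C"), p0=p0, matrices=(M1,), beta=1.0)
    energies = np.vstack([-np.log(p0), -np.log(p1)])
    family = EnergyFamily(
        states=chain.states,
        beta=1.0,
        energies=energies,
        gauges=np.zeros(2),
        references=np.vstack([p0, p1]),
    )
    return chain, family


def db2_chain() -> tuple[DrivenChain, EnergyFamily]:
    """A minimal two-state, two-step chain with detailed balance and p0 = p1.

    ``p0 = (2/3, 1/3)`` is stationary for ``M1 = [[0.9, 0.2], [0.1, 0.8]]``;
    ``M2 = [[0.7, 0.3], [0.3, 0.7]]`` is symmetric with stationary
    ``(1/2, 1/2)``.  Both matrices satisfy detailed balance, so the chain is
    microscopically reversible and every fluctuation identity holds in its
    strongest form; all 8 trajectories can be enumerated by hand.
    """
    chain = DrivenChain(
        states=(0, 1),
        p0=np.array([2.0 / 3.0, 1.0 / 3.0]),
        matrices=(
            np.array([[0.9, 0.2], [0.1, 0.8]]),
            np.array([[0.7, 0.3], [0.3, 0.7]]),
        ),
        beta=1.0,
    )
    return chain, energy_family(chain)


def cycle_chain(n_states: int = 3, n_steps: int = 2) -> DrivenChain:
    """A deterministic cyclic permutation chain with uniform initial law.

    Irreducible but periodic and maximally non-reversible: the auxiliary
    reversed chain runs the cycle the other way, so detailed balance fails
    for any ``n_states >= 3``.
    """
    M = np.roll(np.eye(n_states), 1, axis=0)  # x -> x+1 (mod n)
    return DrivenChain(
        states=tuple(range(n_states)),
        p0=np.full(n_states, 1.0 / n_states),
        matrices=(M,) * n_steps,
        beta=1.0,
    )


def _random_positive(rng: np.random.Generator, n: int) -> np.ndarray:
    p = rng.dirichlet(np.ones(n))
    # keep entries off the boundary so energies stay finite and well scaled
    p = 0.9 * p + 0.1 / n
    return p / p.sum()


def random_chain(spec: GeneratorSpec) -> DrivenChain:
    """A reproducible random chain of the class requested by ``spec``."""
    rng = np.random.default_rng(spec.seed)
    S, N = spec.n_states, spec.n_steps
    matrices: list[np.ndarray] = []
    if spec.mode == "generic":
        for _ in range(N):
            raw = rng.random((S, S))
            raw /= raw.sum(axis=0, keepdims=True)
            matrices.append((1.0 - S * spec.floor) * raw + spec.floor)
    elif spec.mode == "detailed_balance":
        proposal = named_proposal("uniform", S)
        for _ in range(N):
            target = _random_positive(rng, S)
            matrices.append(policy_transition_matrix(target, proposal))
    else:  # permutation
        for _ in range(N):
            # a single random cycle, so the matrix is irreducible
            cycle = rng.permutation(S)
            M = np.zeros((S, S))
            for i, y in enumerate(cycle):
                M[cycle[(i + 1) % S], y] = 1.0
            matrices.append(M)
    if spec.equilibrated:
        p0 = stationary_distribution(matrices[0])
    else:
        p0 = _random_positive(rng, S)
    return DrivenChain(
        states=tuple(range(S)), p0=p0, matrices=tuple(matrices), beta=1.0
    )
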