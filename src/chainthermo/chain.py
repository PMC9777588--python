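"""Finite driven (time-inhomogeneous) Markov chains.

A driven chain is a process ``X = (X_0, ..., X_N)`` on a finite state space,
specified by an initial distribution ``p0`` and an ordered list of transition
matrices ``M_1, ..., M_N`` — one per step, so the dynamics may change over
time.  Throughout this package transition matrices are *column-stochastic*:
entry ``(x, y)`` of ``M_n`` is ``P(X_n = x | X_{n-1} = y)``, columns index the
source state and each column sums to one.  This orientation keeps matrix
action on distributions a plain matrix-vector product, ``p_next = M @ p``.

Stationarity here is a per-matrix notion: ``p`` is stationary for ``M_n`` if
``M_n p = p``.  For an irreducible matrix the stationary distribution is
unique and strictly positive, which is the property every thermodynamic
construction downstream (energies, time reversal, fluctuation identities)
relies on.  Aperiodic convergence is never needed, so periodic matrices such
as permutation cycles are perfectly valid inputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy.linalg import null_space
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

#: default tolerance for stochasticity (column sums, distribution sums)
TOL_STOCHASTIC = 1e-9
#: default tolerance for the stationary-distribution residual ||Mp - p||_inf
TOL_STATIONARY = 1e-10

__all__ = [
    "TOL_STOCHASTIC",
    "TOL_STATIONARY",
    "DrivenChain",
    "Trajectory",
    "TrajectoryEnsemble",
    "validate_chain",
    "is_irreducible",
    "stationary_distribution",
    "satisfies_detailed_balance",
    "reference_distributions",
    "trajectory_probability",
    "enumerate_trajectories",
    "sample_trajectories",
]


def _as_readonly(a: np.ndarray) -> np.ndarray:
    a = np.array(a, dtype=float)
    a.setflags(write=False)
    return a


@dataclass(frozen=True)
class DrivenChain:
    """A finite driven Markov chain ``(p0, M_1..M_N)`` at inverse temperature beta.

    Parameters
    ----------
    states
        Ordered, distinct state labels; length at least 2.
    p0
        Initial probability vector over ``states``.
    matrices
        Transition matrices in time order, column-stochastic in the
        ``(to, from)`` orientation.  At least one matrix is required: with no
        transitions, work and heat would be empty sums and none of the
        fluctuation identities has content.
    beta
        Inverse temperature (dimensionless trade-off parameter), > 0.
    """

    states: tuple
    p0: np.ndarray
    matrices: tuple
    beta: float = 1.0

    def __post_init__(self) -> None:
        states = tuple(self.states)
        if len(states) < 2:
            raise ValueError("a driven chain needs at least 2 states")
        if len(set(states)) != len(states):
            raise ValueError("state labels must be distinct")
        p0 = _as_readonly(self.p0)
        if p0.shape != (len(states),):
            raise ValueError(
                f"p0 has shape {p0.shape}, expected ({len(states)},)"
            )
        mats = tuple(_as_readonly(M) for M in self.matrices)
        if len(mats) == 0:
            raise ValueError("a driven chain needs at least one transition matrix")
        for i, M in enumerate(mats):
            if M.shape != (len(states), len(states)):
                raise ValueError(
                    f"matrix {i + 1} has shape {M.shape}, expected square over "
                    f"{len(states)} states"
                )
        if not self.beta > 0:
            raise ValueError("beta must be positive")
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "p0", p0)
        object.__setattr__(self, "matrices", mats)
        object.__setattr__(self, "beta", float(self.beta))

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_steps(self) -> int:
        """Number of transitions N (trajectories have N+1 points)."""
        return len(self.matrices)

    def index(self, label) -> int:
        try:
            return self.states.index(label)
        except ValueError:
            raise KeyError(f"unknown state label {label!r}") from None


@dataclass(frozen=True)
class Trajectory:
    """A realization ``x = (x_0, ..., x_N)`` given as a tuple of state labels."""

    states_sequence: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "states_sequence", tuple(self.states_sequence))

    def __len__(self) -> int:
        return len(self.states_sequence)

    def reversed(self) -> "Trajectory":
        """The reversal ``x^R = (x_N, ..., x_0)``."""
        return Trajectory(self.states_sequence[::-1])

    def indices(self, states: Sequence) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(states)}
        try:
            return np.array([lookup[s] for s in self.states_sequence], dtype=np.intp)
        except KeyError as err:
            raise KeyError(f"unknown state label {err.args[0]!r}") from None


def as_trajectory(x) -> Trajectory:
    return x if isinstance(x, Trajectory) else Trajectory(tuple(x))


@dataclass(frozen=True)
class TrajectoryEnsemble:
    """A collection of trajectories with exact probabilities or sample weights.

    ``paths`` is an integer array of shape ``(n_trajectories, N+1)`` holding
    state indices; ``weights`` are exact probabilities for enumerated
    ensembles and ``1/n`` for sampled ones.  ``provenance`` records how the
    ensemble was produced (``{"kind": "enumerated"}`` or
    ``{"kind": "sampled", "n": ..., "seed": ...}``).
    """

    states: tuple
    paths: np.ndarray
    weights: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.paths.shape[0]

    def __iter__(self) -> Iterator[tuple]:
        for row, w in zip(self.paths, self.weights):
            yield Trajectory(tuple(self.states[i] for i in row)), float(w)


def validate_chain(chain: DrivenChain, tol: float = TOL_STOCHASTIC) -> list:
    """Check the chain's probabilistic invariants; return a list of violations.

    Reports rather than raises, so callers can surface all defects at once.
    An empty list means the chain is a valid driven Markov chain at
    tolerance ``tol``.
    """
    diagnostics: list[str] = []
    if np.any(chain.p0 < -tol):
        bad = int(np.argmin(chain.p0))
        diagnostics.append(
            f"p0 has a negative entry at state {chain.states[bad]!r}: "
            f"{chain.p0[bad]:.3g}"
        )
    total = float(chain.p0.sum())
    if abs(total - 1.0) > tol:
        diagnostics.append(f"p0 sums to {total:.12g}, expected 1")
    for n, M in enumerate(chain.matrices, start=1):
        if np.any(M < -tol):
            x, y = np.unravel_index(int(np.argmin(M)), M.shape)
            diagnostics.append(
                f"matrix M{n} entry ({chain.states[x]!r}, {chain.states[y]!r}) "
                f"is negative: {M[x, y]:.3g}"
            )
        colsums = M.sum(axis=0)
        off = np.abs(colsums - 1.0)
        if np.any(off > tol):
            y = int(np.argmax(off))
            diagnostics.append(
                f"matrix M{n} column {chain.states[y]!r} sums to "
                f"{colsums[y]:.12g}, expected 1"
            )
    if not chain.beta > 0:
        diagnostics.append(f"beta is {chain.beta}, expected > 0")
    return diagnostics


def is_irreducible(M: np.ndarray) -> bool:
    """True iff the transition graph of ``M`` is strongly connected.

    For finite matrices, irreducibility (some power of ``M`` connects every
    ordered pair of states) is equivalent to strong connectivity of the
    directed graph with an edge ``y -> x`` whenever ``M[x, y] > 0``.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {M.shape}")
    n_comp, _ = connected_components(
        csr_matrix(M > 0), directed=True, connection="strong"
    )
    return n_comp == 1


def stationary_distribution(M: np.ndarray, tol: float = TOL_STATIONARY) -> np.ndarray:
    """The unique stationary distribution of an irreducible column-stochastic M.

    Solved as the one-dimensional null space of ``M - I`` (SVD-based),
    normalized to sum to one, then cross-checked by the residual
    ``||Mp - p||_inf <= tol``.  Irreducibility guarantees uniqueness and
    strict positivity; reducible input is refused because without uniqueness
    every downstream thermodynamic definition becomes ambiguous.
    """
    M = np.asarray(M, dtype=float)
    if not is_irreducible(M):
        raise ValueError(
            "matrix is reducible: the stationary distribution is not unique"
        )
    # rcond well above machine eps: the zero singular value of M - I can sit
    # a few ulps high; the residual check below guards against false positives
    ns = null_space(M - np.eye(M.shape[0]), rcond=1e-10)
    if ns.shape[1] != 1:
        # cannot happen for an irreducible stochastic matrix unless the
        # numerics went badly wrong
        raise ValueError(
            f"null space of M - I has dimension {ns.shape[1]}, expected 1"
        )
    p = ns[:, 0]
    p = p / p.sum()
    residual = float(np.max(np.abs(M @ p - p)))
    if residual > tol:
        raise ValueError(
            f"stationary solve residual {residual:.3g} exceeds tolerance {tol:.3g}"
        )
    if np.any(p <= 0):
        raise ValueError("stationary distribution has non-positive entries")
    return p


def satisfies_detailed_balance(
    M: np.ndarray, p: np.ndarray, tol: float = TOL_STOCHASTIC
) -> bool:
    """True iff ``M[y, x] p[x] == M[x, y] p[y]`` for all state pairs.

    Detailed balance says the probability flow matrix ``F[x, y] = M[x, y] p[y]``
    is symmetric; it upgrades a stationary distribution to an equilibrium one.
    """
    M = np.asarray(M, dtype=float)
    p = np.asarray(p, dtype=float)
    if M.shape != (p.size, p.size):
        raise ValueError(
            f"dimension mismatch: matrix {M.shape} vs distribution ({p.size},)"
        )
    flow = M * p[np.newaxis, :]
    return bool(np.max(np.abs(flow - flow.T)) <= tol)


def reference_distributions(
    chain: DrivenChain, tol: float = TOL_STATIONARY
) -> np.ndarray:
    """The per-step reference distributions ``p_0, p_1, ..., p_N``.

    ``p_0`` is the chain's initial distribution; ``p_n`` for ``n >= 1`` is the
    unique stationary distribution of ``M_n``.  Shape ``(N+1, n_states)``.
    """
    refs = np.empty((chain.n_steps + 1, chain.n_states))
    refs[0] = chain.p0
    for n, M in enumerate(chain.matrices, start=1):
        refs[n] = stationary_distribution(M, tol=tol)
    return refs


def trajectory_probability(chain: DrivenChain, x) -> float:
    """``P(X = x) = p0(x_0) * prod_n M_n(x_n, x_{n-1})``."""
    x = as_trajectory(x)
    if len(x) != chain.n_steps + 1:
        raise ValueError(
            f"trajectory has {len(x)} points, chain expects {chain.n_steps + 1}"
        )
    idx = x.indices(chain.states)
    prob = float(chain.p0[idx[0]])
    for n, M in enumerate(chain.matrices, start=1):
        prob *= float(M[idx[n], idx[n - 1]])
    return prob


def enumerate_trajectories(
    chain: DrivenChain, cap: int = 10**6
) -> TrajectoryEnsemble:
    """All ``|S|^(N+1)`` trajectories with their exact probabilities.

    Refuses when the trajectory count exceeds ``cap`` (the error message
    states the required count so callers can fall back to sampling).
    """
    count = chain.n_states ** (chain.n_steps + 1)
    if count > cap:
        raise ValueError(
            f"enumeration needs {count} trajectories, exceeding cap={cap}; "
            "use sample_trajectories instead"
        )
    paths = np.array(
        list(itertools.product(range(chain.n_states), repeat=chain.n_steps + 1)),
        dtype=np.intp,
    )
    probs = chain.p0[paths[:, 0]].copy()
    for n, M in enumerate(chain.matrices, start=1):
        probs *= M[paths[:, n], paths[:, n - 1]]
    return TrajectoryEnsemble(
        states=chain.states,
        paths=paths,
        weights=probs,
        provenance={"kind": "enumerated"},
    )


def sample_trajectories(
    chain: DrivenChain, n: int, seed: int
) -> TrajectoryEnsemble:
    """Draw ``n`` independent trajectories; reproducible for a given seed."""
    if n < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    S = chain.n_states
    paths = np.empty((n, chain.n_steps + 1), dtype=np.intp)
    cum0 = np.cumsum(chain.p0)
    paths[:, 0] = np.minimum(np.searchsorted(cum0, rng.random(n), side="right"), S - 1)
    for step, M in enumerate(chain.matrices, start=1):
        cum = np.cumsum(M, axis=0)  # (S, S): cumulative within each source column
        prev = paths[:, step - 1]
        u = rng.random(n)
        paths[:, step] = np.minimum((u[np.newaxis, :] >= cum[:, prev]).sum(axis=0), S - 1)
    return TrajectoryEnsemble(
        states=chain.states,
        paths=paths,
        weights=np.full(n, 1.0 / n),
        provenance={"kind": "sampled", "n": int(n), "seed": int(seed)},
    )
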