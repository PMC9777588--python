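"""Energies, free energies, and per-trajectory work and heat.

Every strictly positive distribution ``p`` determines an energy function up
to an additive constant (the gauge): ``E(x) = -(1/beta) log p(x) + c``, with
partition function ``Z = sum_x exp(-beta E(x))`` and free energy
``F = -(1/beta) log Z``.  A *family of energies* of a driven chain assigns
one such function to each reference distribution ``p_n`` (the initial
distribution for n=0, the stationary distribution of ``M_n`` for n>=1).

Along a realization ``x = (x_0..x_N)`` the work is the energy change due to
the external switch of the energy function at the currently occupied state,

    W(x) = sum_{n=0}^{N-1} E_{n+1}(x_n) - E_n(x_n),

while the heat is the energy change due to internal state transitions under
a fixed energy function,

    Q(x) = sum_{n=1}^{N} E_n(x_n) - E_n(x_{n-1}).

Work shifts by exactly ``c_N - c_0`` under a gauge change; heat and the
dissipated work ``W - deltaF`` are gauge-invariant.  The first law
``W + Q = E_N(x_N) - E_0(x_0)`` holds identically, term by term.

The default *zero-gauge* convention sets ``E_n = -(1/beta) log p_n`` exactly,
which makes every ``Z_n = 1``, every ``F_n = 0`` and ``deltaF = 0``.  All the
identities checked in this package are gauge-covariant, so this convention
loses no generality while removing an arbitrary constant from every oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .chain import (
    TOL_STATIONARY,
    DrivenChain,
    as_trajectory,
    reference_distributions,
)

__all__ = [
    "EnergyFamily",
    "FreeEnergySummary",
    "energy_of",
    "energy_family",
    "validate_family",
    "free_energy_summary",
    "work",
    "heat",
    "dissipated_work",
    "first_law_residual",
]


@dataclass(frozen=True)
class EnergyFamily:
    """Per-step energy functions ``E_0..E_N`` over a fixed state order.

    ``energies`` has shape ``(N+1, n_states)``; row ``n`` is ``E_n`` in units
    of ``1/beta``.  ``gauges`` records the offsets relative to the zero-gauge
    convention.  ``references``, when present, caches the distributions the
    energies were derived from (used by consistency checks).
    """

    states: tuple
    beta: float
    energies: np.ndarray
    gauges: np.ndarray
    references: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        energies = np.array(self.energies, dtype=float)
        if energies.ndim != 2 or energies.shape[1] != len(self.states):
            raise ValueError(
                f"energies shape {energies.shape} does not match "
                f"{len(self.states)} states"
            )
        gauges = np.array(self.gauges, dtype=float)
        if gauges.shape != (energies.shape[0],):
            raise ValueError("need one gauge constant per energy function")
        if not np.all(np.isfinite(gauges)):
            raise ValueError("gauge constants must be finite")
        if not self.beta > 0:
            raise ValueError("beta must be positive")
        energies.setflags(write=False)
        gauges.setflags(write=False)
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "beta", float(self.beta))
        object.__setattr__(self, "energies", energies)
        object.__setattr__(self, "gauges", gauges)
        if self.references is not None:
            refs = np.array(self.references, dtype=float)
            refs.setflags(write=False)
            object.__setattr__(self, "references", refs)

    @property
    def n_steps(self) -> int:
        return self.energies.shape[0] - 1

    def with_gauges(self, gauges) -> "EnergyFamily":
        """The same family re-gauged: ``E_n -> E_n - c_n^old + c_n^new``."""
        gauges = np.asarray(gauges, dtype=float)
        shift = gauges - self.gauges
        return EnergyFamily(
            states=self.states,
            beta=self.beta,
            energies=self.energies + shift[:, np.newaxis],
            gauges=gauges,
            references=self.references,
        )


@dataclass(frozen=True)
class FreeEnergySummary:
    """Partition functions ``Z_n``, free energies ``F_n``, and ``deltaF = F_N - F_0``."""

    partition_values: np.ndarray
    free_energies: np.ndarray
    delta_F: float


def energy_of(p, beta: float, gauge: float = 0.0) -> np.ndarray:
    """The energy function of a strictly positive distribution.

    ``E(x) = -(1/beta) log p(x) + gauge``; with ``gauge=0`` the induced
    partition function is exactly 1 and the free energy 0.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0):
        raise ValueError(
            "energy_of requires strictly positive probabilities: an energy "
            "function exists only for distributions with non-zero entries"
        )
    if not beta > 0:
        raise ValueError("beta must be positive")
    return -np.log(p) / beta + gauge


def energy_family(chain: DrivenChain, gauges=None) -> EnergyFamily:
    """The energy family of a chain from its reference distributions.

    ``E_n = -(1/beta) log p_n + c_n`` with ``p_0`` the initial distribution
    and ``p_n`` the stationary distribution of ``M_n``.  Requires ``p0``
    strictly positive and every matrix irreducible, which guarantees each
    ``p_n`` exists, is unique, and is strictly positive.
    """
    if np.any(chain.p0 <= 0):
        raise ValueError("p0 must be strictly positive to define E_0")
    refs = reference_distributions(chain)
    if gauges is None:
        gauges = np.zeros(chain.n_steps + 1)
    gauges = np.asarray(gauges, dtype=float)
    if gauges.shape != (chain.n_steps + 1,):
        raise ValueError(
            f"need {chain.n_steps + 1} gauge constants, got {gauges.shape}"
        )
    energies = -np.log(refs) / chain.beta + gauges[:, np.newaxis]
    return EnergyFamily(
        states=chain.states,
        beta=chain.beta,
        energies=energies,
        gauges=gauges,
        references=refs,
    )


def validate_family(
    family: EnergyFamily, chain: DrivenChain, tol: float = TOL_STATIONARY
) -> list:
    """Check that each ``E_n`` is an energy function of the chain's ``p_n``.

    Normalizing ``exp(-beta E_n)`` must recover the reference distribution;
    returns a list of violations (empty when the family is consistent).
    """
    diagnostics: list[str] = []
    if family.states != chain.states:
        return [
            f"state order mismatch: family {family.states} vs chain {chain.states}"
        ]
    if abs(family.beta - chain.beta) > 0:
        diagnostics.append(
            f"beta mismatch: family {family.beta} vs chain {chain.beta}"
        )
    if family.n_steps != chain.n_steps:
        return diagnostics + [
            f"family has {family.n_steps} steps, chain has {chain.n_steps}"
        ]
    refs = reference_distributions(chain)
    for n in range(family.n_steps + 1):
        logw = -family.beta * family.energies[n]
        induced = np.exp(logw - logsumexp(logw))
        err = float(np.max(np.abs(induced - refs[n])))
        if err > max(tol, 1e-12):
            diagnostics.append(
                f"E_{n} is not an energy function of p_{n}: max deviation {err:.3g}"
            )
    return diagnostics


def free_energy_summary(family: EnergyFamily) -> FreeEnergySummary:
    """``Z_n = sum_x exp(-beta E_n(x))``, ``F_n = -(1/beta) log Z_n``, ``deltaF``.

    Evaluated in the log domain so large ``beta`` or large gauge offsets do
    not overflow.
    """
    logZ = logsumexp(-family.beta * family.energies, axis=1)
    F = -logZ / family.beta
    return FreeEnergySummary(
        partition_values=np.exp(logZ),
        free_energies=F,
        delta_F=float(F[-1] - F[0]),
    )


def delta_F(family: EnergyFamily) -> float:
    """Free energy difference ``F_N - F_0`` of a family."""
    return free_energy_summary(family).delta_F


def _indices(family: EnergyFamily, x) -> np.ndarray:
    x = as_trajectory(x)
    if len(x) != family.n_steps + 1:
        raise ValueError(
            f"trajectory has {len(x)} points, family expects {family.n_steps + 1}"
        )
    return x.indices(family.states)


def work(x, family: EnergyFamily) -> float:
    """``W(x) = sum_{n=0}^{N-1} E_{n+1}(x_n) - E_n(x_n)``.

    The driving signal: energy injected by switching the energy function
    while the system sits at ``x_n``.  Gauge-covariant — re-gauging shifts
    the value by exactly ``c_N - c_0``.
    """
    idx = _indices(family, x)
    steps = np.arange(family.n_steps)
    return float(
        np.sum(family.energies[steps + 1, idx[:-1]] - family.energies[steps, idx[:-1]])
    )


def heat(x, family: EnergyFamily) -> float:
    """``Q(x) = sum_{n=1}^{N} E_n(x_n) - E_n(x_{n-1})``; gauge-invariant."""
    idx = _indices(family, x)
    steps = np.arange(1, family.n_steps + 1)
    return float(
        np.sum(family.energies[steps, idx[1:]] - family.energies[steps, idx[:-1]])
    )


def dissipated_work(x, family: EnergyFamily) -> float:
    """``W^d(x) = W(x) - deltaF``; gauge-invariant."""
    return work(x, family) - free_energy_summary(family).delta_F


def first_law_residual(x, family: EnergyFamily) -> float:
    """``W(x) + Q(x) - (E_N(x_N) - E_0(x_0))`` — zero up to roundoff, always."""
    idx = _indices(family, x)
    boundary = float(family.energies[-1, idx[-1]] - family.energies[0, idx[0]])
    return work(x, family) + heat(x, family) - boundary
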