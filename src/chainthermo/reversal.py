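"""Time reversal, the auxiliary reversed chain, and microscopic reversibility.

Two reversed processes matter here.  The *time reversal* of a driven chain X
starts from ``p_N`` (the stationary distribution of the last matrix) and runs
the original matrices in reversed order, ``(M_N, ..., M_1)``.  The *auxiliary
reversed chain* Y also starts from ``p_N`` but uses the detailed-balance
conjugates

    Mhat_{n+1}[x, y] = p_{N-n}(x) / p_{N-n}(y) * M_{N-n}[y, x],

which are automatically column-stochastic because each ``p_n`` is stationary
for ``M_n``.  Y is the chain against which the trajectory-ratio identity
``P(X = x) = P(Y = x^R) e^{beta (W - deltaF)}`` holds unconditionally; it
coincides with the time reversal exactly when every matrix satisfies
detailed balance (then X is called *microscopically reversible*).

Energies reverse by re-use, not by recomputation: since ``Mhat_n`` has
stationary distribution ``p_{N-(n-1)}``, the reversed family is
``Ehat_n = E_{N-(n-1)}`` for ``n >= 1`` with ``Ehat_0 = Ehat_1 (= E_N)``.
Under this choice the works of a trajectory and its reversal are tied by

    W_Y(x^R) = -W_X(x) + E_1(x_0) - E_0(x_0) + k,

where k collects gauge offsets and vanishes for the re-used energies.  The
residual term ``E_1(x_0) - E_0(x_0)`` is the protocol asymmetry of the
discrete-time setting: it is constant (and absorbable into k) precisely when
``p_0`` is stationary for ``M_1``, which is when work becomes odd under time
reversal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain import (
    DrivenChain,
    enumerate_trajectories,
    reference_distributions,
    satisfies_detailed_balance,
    stationary_distribution,
)
from .thermo import EnergyFamily, work

__all__ = [
    "ReversalPair",
    "auxiliary_reverse_chain",
    "time_reversal",
    "is_microscopically_reversible",
    "reversal_energy_family",
    "work_reversal_constant",
    "reversal_pair",
    "verify_work_reversal",
]

_TOL_CONSTRUCT = 1e-12


@dataclass(frozen=True)
class ReversalPair:
    """A forward chain/family and its reversed counterpart.

    ``kind`` is ``"auxiliary"`` (the detailed-balance conjugate construction)
    or ``"time_reversal"`` (matrices literally reversed); ``k`` is the
    work-reversal constant tying the two work functionals together.
    """

    forward_chain: DrivenChain
    forward_family: EnergyFamily
    backward_chain: DrivenChain
    backward_family: EnergyFamily
    kind: str
    k: float


def auxiliary_reverse_chain(chain: DrivenChain) -> DrivenChain:
    """The reversed chain Y with conjugated matrices.

    Requires a strictly positive ``p0`` and irreducible matrices (so every
    reference distribution exists and is strictly positive).  Column
    stochasticity of each conjugate is verified on construction; ``Mhat_n``
    has stationary distribution ``p_{N-(n-1)}``.
    """
    if np.any(chain.p0 <= 0):
        raise ValueError("auxiliary reversal requires strictly positive p0")
    refs = reference_distributions(chain)  # raises on reducible matrices
    N = chain.n_steps
    reversed_mats = []
    for n in range(1, N + 1):
        p = refs[N - n + 1]
        M = chain.matrices[N - n]  # M_{N-n+1}
        Mhat = (p[:, np.newaxis] / p[np.newaxis, :]) * M.T
        colsums = Mhat.sum(axis=0)
        if np.max(np.abs(colsums - 1.0)) > _TOL_CONSTRUCT:
            raise ValueError(
                f"conjugated matrix {n} failed column-stochasticity "
                f"(max deviation {np.max(np.abs(colsums - 1.0)):.3g}); "
                "the stationary solve is inconsistent"
            )
        reversed_mats.append(Mhat)
    return DrivenChain(
        states=chain.states,
        p0=refs[N],
        matrices=tuple(reversed_mats),
        beta=chain.beta,
    )


def time_reversal(chain: DrivenChain) -> DrivenChain:
    """The time reversal: initial ``p_N``, matrices ``(M_N, ..., M_1)``."""
    pN = stationary_distribution(chain.matrices[-1])
    return DrivenChain(
        states=chain.states,
        p0=pN,
        matrices=tuple(chain.matrices[::-1]),
        beta=chain.beta,
    )


def is_microscopically_reversible(chain: DrivenChain, tol: float = 1e-10) -> bool:
    """True iff every matrix satisfies detailed balance w.r.t. its stationary law.

    Two equivalent criteria are computed and required to agree: (a) detailed
    balance of each ``M_n`` with respect to ``p_n``, and (b) entrywise
    coincidence of the auxiliary reversed chain with the time reversal.  A
    disagreement beyond ``tol`` indicates a solver problem, not a property of
    the chain, and raises.
    """
    refs = reference_distributions(chain)
    by_balance = all(
        satisfies_detailed_balance(M, refs[n], tol)
        for n, M in enumerate(chain.matrices, start=1)
    )
    aux = auxiliary_reverse_chain(chain)
    rev = time_reversal(chain)
    gap = max(
        float(np.max(np.abs(A - B)))
        for A, B in zip(aux.matrices, rev.matrices)
    )
    by_coincidence = gap <= tol
    if by_balance != by_coincidence:
        raise RuntimeError(
            "detailed-balance and chain-coincidence criteria disagree "
            f"(matrix gap {gap:.3g}); tighten tolerances or check the input"
        )
    return by_balance


def reversal_energy_family(family: EnergyFamily) -> EnergyFamily:
    """Energies of the reversed chain by re-use: ``Ehat_n = E_{N-(n-1)}``, ``Ehat_0 = Ehat_1``.

    Valid for the auxiliary chain (and, under detailed balance, the time
    reversal) because ``Mhat_n`` has stationary distribution ``p_{N-(n-1)}``.
    """
    N = family.n_steps
    order = [N] + [N - (n - 1) for n in range(1, N + 1)]  # Ehat_0 = Ehat_1 = E_N
    refs = None
    if family.references is not None:
        refs = family.references[order]
    return EnergyFamily(
        states=family.states,
        beta=family.beta,
        energies=family.energies[order],
        gauges=family.gauges[order],
        references=refs,
    )


def work_reversal_constant(
    family: EnergyFamily, rev_family: EnergyFamily, tol: float = 1e-10
) -> float:
    """The constant ``k = (Ehat_N - E_1) - (Ehat_0 - E_N)``.

    Both parenthesized differences pair two energy functions of the same
    distribution, so each is constant across states; that constancy is
    verified (within ``tol``) rather than assumed, to catch inconsistent
    user-supplied families.  With re-used (reversed) energies ``k = 0``.
    """
    d1 = rev_family.energies[-1] - family.energies[1]
    d2 = rev_family.energies[0] - family.energies[-1]
    for name, d in (("Ehat_N - E_1", d1), ("Ehat_0 - E_N", d2)):
        if float(np.max(d) - np.min(d)) > tol:
            raise ValueError(
                f"{name} varies across states by {np.max(d) - np.min(d):.3g}; "
                "the reversed family is not consistent with the forward one"
            )
    return float(d1.mean() - d2.mean())


def reversal_pair(
    chain: DrivenChain,
    family: EnergyFamily,
    kind: str = "auxiliary",
) -> ReversalPair:
    """Bundle a chain/family with its reversed counterpart and constant k."""
    if kind == "auxiliary":
        backward = auxiliary_reverse_chain(chain)
    elif kind == "time_reversal":
        backward = time_reversal(chain)
    else:
        raise ValueError(f"unknown reversal kind {kind!r}")
    rev_family = reversal_energy_family(family)
    k = work_reversal_constant(family, rev_family)
    return ReversalPair(
        forward_chain=chain,
        forward_family=family,
        backward_chain=backward,
        backward_family=rev_family,
        kind=kind,
        k=k,
    )


def verify_work_reversal(pair: ReversalPair, cap: int = 10**6) -> float:
    """Max violation of ``W_Y(x^R) = -W_X(x) + E_1(x_0) - E_0(x_0) + k``.

    Enumerates every trajectory of the forward chain and evaluates both work
    functionals; the identity is unconditional for consistent families, so
    the returned maximum should be zero up to roundoff.  When ``p_0 = p_1``
    the residual term ``E_1(x_0) - E_0(x_0)`` is itself constant and the
    relation collapses to plain work-oddness up to a constant.
    """
    ens = enumerate_trajectories(pair.forward_chain, cap=cap)
    fam = pair.forward_family
    e10 = fam.energies[1] - fam.energies[0]
    worst = 0.0
    for x, _w in ens:
        wx = work(x, fam)
        wy = work(x.reversed(), pair.backward_family)
        resid = wy + wx - float(e10[x.indices(fam.states)[0]]) - pair.k
        worst = max(worst, abs(resid))
    return worst
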