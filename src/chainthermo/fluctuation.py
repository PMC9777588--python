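"""Fluctuation theorems by exact enumeration and Monte Carlo.

For a finite driven chain every expectation is a finite sum, so Jarzynski's
equality

    < exp(-beta (W - deltaF)) > = 1

and the per-trajectory ratio identity

    P(X = x) = P(Y = x^R) exp(beta (W(x) - deltaF))

(with Y the auxiliary reversed chain) can be checked *exactly*, not just
statistically.  The work distribution has finite support; pairing its atoms
with those of the reversed process yields the Crooks relation

    P_F(W = w) / P_B(W = -w + k) = exp(beta (w - deltaF)),

which in this discrete-time symmetric-work formulation additionally
requires the initial distribution to be stationary for the first matrix
(``p_0 = p_1``).  When that hypothesis fails the report is still produced —
the breakdown (undefined ratios, wrong values) is a first-class result, not
an error.  The second law ``deltaF <= <W>`` follows from Jarzynski by
Jensen's inequality and is exposed as the nonnegative gap ``<W> - deltaF``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chain import (
    DrivenChain,
    TrajectoryEnsemble,
    enumerate_trajectories,
    is_irreducible,
    reference_distributions,
    sample_trajectories,
    as_trajectory,
    trajectory_probability,
)
from .reversal import (
    is_microscopically_reversible,
    reversal_energy_family,
    reversal_pair,
    time_reversal,
)
from .thermo import (
    EnergyFamily,
    dissipated_work,
    free_energy_summary,
)

__all__ = [
    "WorkDistribution",
    "CrooksReport",
    "jarzynski_exact",
    "jarzynski_mc",
    "trajectory_ratio_check",
    "hysteresis",
    "work_distribution",
    "crooks_report",
    "second_law_gap",
]

#: work values closer than this are treated as the same atom of the
#: (discrete) work distribution — float noise must not split atoms
TOL_GROUP = 1e-9


def _check_hypotheses(chain: DrivenChain) -> None:
    """The standing hypotheses: strictly positive p0, irreducible matrices."""
    if np.any(chain.p0 <= 0):
        raise ValueError(
            "hypothesis violated: p0 must have strictly positive entries"
        )
    for n, M in enumerate(chain.matrices, start=1):
        if not is_irreducible(M):
            raise ValueError(f"hypothesis violated: M{n} is reducible")


def _ensemble_works(ens: TrajectoryEnsemble, family: EnergyFamily) -> np.ndarray:
    """Vectorized work values for every path in an ensemble."""
    E = family.energies
    paths = ens.paths
    W = np.zeros(paths.shape[0])
    for n in range(family.n_steps):
        W += E[n + 1, paths[:, n]] - E[n, paths[:, n]]
    return W


@dataclass(frozen=True)
class WorkDistribution:
    """A finite-support work distribution: sorted atoms with probabilities."""

    support: np.ndarray
    probabilities: np.ndarray
    provenance: dict = field(default_factory=dict)

    def probability_of(self, w: float, tol: float = TOL_GROUP) -> float:
        """P(W = w), matching the atom within ``tol`` (0 if no atom there)."""
        hits = np.abs(self.support - w) <= tol
        return float(self.probabilities[hits].sum())


@dataclass(frozen=True)
class CrooksReport:
    """Atom-by-atom comparison of forward and backward work distributions.

    ``table`` has one row per forward support point: the work value, both
    probabilities, the observed ratio (NaN where the backward atom is
    missing), the predicted ratio ``exp(beta (w - deltaF))``, and whether the
    ratio is defined.  ``holds`` is True iff every atom is defined and the
    worst relative error is within tolerance; ``p0_equals_p1`` records
    whether the theorem's extra hypothesis was met in the first place.
    """

    table: pd.DataFrame
    k: float
    delta_F: float
    p0_equals_p1: bool
    holds: bool
    max_relative_error: float

    def to_json_dict(self) -> dict:
        rows = []
        for rec in self.table.to_dict(orient="records"):
            rec["defined"] = bool(rec["defined"])
            rows.append({k: (v if isinstance(v, bool) else float(v))
                         for k, v in rec.items()})
        return {
            "k": float(self.k),
            "delta_F": float(self.delta_F),
            "p0_equals_p1": bool(self.p0_equals_p1),
            "holds": bool(self.holds),
            "max_relative_error": float(self.max_relative_error),
            "rows": rows,
        }


def _group_atoms(
    values: np.ndarray, weights: np.ndarray, tol_group: float
) -> tuple[np.ndarray, np.ndarray]:
    """Single-linkage grouping of float values into atoms of a discrete law."""
    order = np.argsort(values)
    v, w = values[order], weights[order]
    breaks = np.nonzero(np.diff(v) > tol_group)[0] + 1
    groups = np.split(np.arange(v.size), breaks)
    support = np.array([v[g] @ w[g] / w[g].sum() if w[g].sum() > 0 else v[g].mean()
                        for g in groups])
    probs = np.array([w[g].sum() for g in groups])
    keep = probs > 0
    return support[keep], probs[keep]


def work_distribution(
    chain: DrivenChain,
    family: EnergyFamily,
    cap: int = 10**6,
    tol_group: float = TOL_GROUP,
) -> WorkDistribution:
    """The exact work distribution by full trajectory enumeration."""
    ens = enumerate_trajectories(chain, cap=cap)
    W = _ensemble_works(ens, family)
    support, probs = _group_atoms(W, ens.weights, tol_group)
    return WorkDistribution(
        support=support,
        probabilities=probs,
        provenance={"kind": "exact", "n_trajectories": len(ens)},
    )


def jarzynski_exact(
    chain: DrivenChain, family: EnergyFamily, cap: int = 10**6
) -> float:
    """``sum_x P(x) exp(-beta (W(x) - deltaF))`` over the full enumeration.

    Equals 1 (to roundoff) for every chain satisfying the hypotheses —
    strictly positive ``p0`` and irreducible matrices — under any gauge.
    """
    _check_hypotheses(chain)
    ens = enumerate_trajectories(chain, cap=cap)
    W = _ensemble_works(ens, family)
    dF = free_energy_summary(family).delta_F
    return float(np.sum(ens.weights * np.exp(-family.beta * (W - dF))))


def jarzynski_mc(
    chain: DrivenChain,
    family: EnergyFamily,
    n: int,
    seed: int,
) -> tuple[float, float]:
    """Monte Carlo estimate and standard error of the Jarzynski expectation.

    An explicitly separate estimator — never silently substituted for the
    exact sum.  Reproducible for a fixed seed.
    """
    if n < 2:
        raise ValueError("need at least 2 samples for a standard error")
    _check_hypotheses(chain)
    ens = sample_trajectories(chain, n=n, seed=seed)
    W = _ensemble_works(ens, family)
    dF = free_energy_summary(family).delta_F
    vals = np.exp(-family.beta * (W - dF))
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(n))


def trajectory_ratio_check(
    chain: DrivenChain, family: EnergyFamily, cap: int = 10**6
) -> float:
    """Max relative violation of the per-trajectory ratio identity.

    For every x with ``P(X = x) > 0`` the auxiliary chain Y satisfies
    ``P(X = x) = P(Y = x^R) exp(beta (W - deltaF))``, and conditionally
    ``P(x_1..x_N | x_0) = P(Y follows reversal | Y_0 = x_N) exp(-beta Q)``.
    Both forms are compared in the log domain; a trajectory with positive
    forward but zero backward probability is a genuine violation and yields
    ``inf``.  Under valid inputs the return value is ~1e-15.
    """
    _check_hypotheses(chain)
    pair = reversal_pair(chain, family, kind="auxiliary")
    ens = enumerate_trajectories(chain, cap=cap)
    dF = free_energy_summary(family).delta_F
    beta = family.beta
    E = family.energies
    worst = 0.0
    for x, px in ens:
        if px <= 0:
            continue
        idx = x.indices(chain.states)
        py = trajectory_probability(pair.backward_chain, x.reversed())
        W = float(np.sum(E[np.arange(family.n_steps) + 1, idx[:-1]]
                         - E[np.arange(family.n_steps), idx[:-1]]))
        Q = float(np.sum(E[np.arange(1, family.n_steps + 1), idx[1:]]
                         - E[np.arange(1, family.n_steps + 1), idx[:-1]]))
        if py <= 0:
            return float("inf")
        # unconditional form, Eq-(14) style
        rel = abs(np.expm1(np.log(py) + beta * (W - dF) - np.log(px)))
        worst = max(worst, rel)
        # conditional form with heat
        px_cond = px / chain.p0[idx[0]]
        py_cond = py / pair.backward_chain.p0[idx[-1]]
        rel_c = abs(np.expm1(np.log(py_cond) - beta * Q - np.log(px_cond)))
        worst = max(worst, rel_c)
    return worst


def hysteresis(chain: DrivenChain, family: EnergyFamily, x) -> float:
    """``beta * W^d(x)``: the log-ratio of forward to time-reversed probability.

    Requires microscopic reversibility (detailed balance of every matrix),
    so that the reversed process is the genuine time reversal; the value is
    cross-checked against ``log P(X = x) - log P(Y = x^R)`` whenever both
    probabilities are positive.  A zero value means the trajectory is as
    likely forward as backward — no hysteresis.
    """
    if not is_microscopically_reversible(chain):
        raise ValueError(
            "chain is not microscopically reversible (detailed balance "
            "fails); use trajectory_ratio_check with the auxiliary chain "
            "instead"
        )
    x = as_trajectory(x)
    value = chain.beta * dissipated_work(x, family)
    Y = time_reversal(chain)
    px = trajectory_probability(chain, x)
    py = trajectory_probability(Y, x.reversed())
    if px > 0 and py > 0:
        log_ratio = float(np.log(px) - np.log(py))
        if abs(log_ratio - value) > 1e-10 * max(1.0, abs(value)):
            raise RuntimeError(
                f"hysteresis routes disagree: beta*Wd={value:.12g} vs "
                f"log-ratio={log_ratio:.12g}"
            )
    elif (px > 0) != (py > 0):
        raise ValueError(
            "one-sided zero probability: the log-ratio form of hysteresis "
            "is undefined for this trajectory"
        )
    return value


def crooks_report(
    chain: DrivenChain,
    family: EnergyFamily,
    cap: int = 10**6,
    tol_group: float = TOL_GROUP,
    tol: float = 1e-9,
) -> CrooksReport:
    """Atom-by-atom check of the Crooks relation.

    Under detailed balance the backward process is the time reversal and
    ``k`` carries only gauge offsets (zero for re-used energies); otherwise
    the auxiliary chain is used.  When ``p_0 = p_1`` the residual protocol
    term is a constant absorbed into ``k`` and the relation is guaranteed;
    when it is not, the report is still produced so the breakdown can be
    examined — missing backward atoms are flagged undefined and ``holds``
    is False.
    """
    _check_hypotheses(chain)
    refs = reference_distributions(chain)
    p0_eq_p1 = bool(np.max(np.abs(refs[0] - refs[1])) <= 1e-9)
    db = is_microscopically_reversible(chain)
    kind = "time_reversal" if db else "auxiliary"
    pair = reversal_pair(chain, family, kind=kind)
    k = pair.k
    if p0_eq_p1:
        # E_1 - E_0 is constant across states; fold it into k
        c = family.energies[1] - family.energies[0]
        k += float(c.mean())
    fwd = work_distribution(chain, family, cap=cap, tol_group=tol_group)
    bwd = work_distribution(
        pair.backward_chain, pair.backward_family, cap=cap, tol_group=tol_group
    )
    dF = free_energy_summary(family).delta_F
    rows = []
    max_rel = 0.0
    all_defined = True
    for w, pf in zip(fwd.support, fwd.probabilities):
        pb = bwd.probability_of(-w + k, tol=tol_group)
        predicted = float(np.exp(family.beta * (w - dF)))
        defined = pb > 0
        observed = pf / pb if defined else float("nan")
        rel = abs(observed / predicted - 1.0) if defined else float("nan")
        if defined:
            max_rel = max(max_rel, rel)
        else:
            all_defined = False
        rows.append(
            {
                "work": float(w),
                "prob_forward": float(pf),
                "prob_backward": float(pb),
                "observed_ratio": observed,
                "predicted_ratio": predicted,
                "defined": defined,
            }
        )
    holds = bool(all_defined and max_rel <= tol)
    return CrooksReport(
        table=pd.DataFrame(rows),
        k=float(k),
        delta_F=dF,
        p0_equals_p1=p0_eq_p1,
        holds=holds,
        max_relative_error=max_rel if all_defined else float("inf"),
    )


def second_law_gap(
    chain: DrivenChain, family: EnergyFamily, cap: int = 10**6
) -> float:
    """``<W> - deltaF`` by exact enumeration; nonnegative by Jensen's inequality.

    In the decision-making reading this is the excess expected surprise over
    the free-energy bound; it is zero iff the work is almost surely equal to
    ``deltaF``.  Gauge-invariant.
    """
    _check_hypotheses(chain)
    ens = enumerate_trajectories(chain, cap=cap)
    W = _ensemble_works(ens, family)
    dF = free_energy_summary(family).delta_F
    return float(ens.weights @ W - dF)
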