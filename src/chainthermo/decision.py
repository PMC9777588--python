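"""Bounded-rational decision-making as driven-chain thermodynamics.

A decision-maker choosing among finitely many options under an
information-processing constraint maximizes entropy subject to an
expected-utility bound; the optimizer is the Boltzmann distribution
``p(x) = exp(beta U(x)) / Z`` with the utility acting as a negative energy,
``U = -E``.  Adaptation to a changing environment is modelled as a driven
chain: each environment contributes a transition matrix whose stationary
distribution is that environment's Boltzmann policy (built here by the
Metropolis rule), repeated for the number of steps the learner dwells
there.  The driving signal is the per-step surprise — the change in energy
at the currently occupied state when the environment switches — whose sum
along a trajectory is exactly the thermodynamic work, so Jarzynski bounds
the expected surprise and the Crooks/dissipated-work identities quantify
hysteresis between a schedule of environments and its reversal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import softmax

from .chain import DrivenChain, satisfies_detailed_balance, as_trajectory
from .fluctuation import (
    crooks_report,
    jarzynski_exact,
    jarzynski_mc,
    second_law_gap,
)
from .thermo import EnergyFamily, energy_family, work

__all__ = [
    "Environment",
    "AdaptationProtocol",
    "boltzmann_policy",
    "named_proposal",
    "policy_transition_matrix",
    "surprise_steps",
    "run_adaptation",
]


@dataclass(frozen=True)
class Environment:
    """One environmental condition: a utility per state and a dwell time.

    ``dwell`` is the number of transition steps the learner spends under
    this environment before the next switch.
    """

    utility: np.ndarray
    dwell: int = 1

    def __post_init__(self) -> None:
        u = np.array(self.utility, dtype=float)
        if not np.all(np.isfinite(u)):
            raise ValueError("utilities must be finite")
        u.setflags(write=False)
        object.__setattr__(self, "utility", u)
        if self.dwell < 1:
            raise ValueError("dwell must be at least 1 step")


@dataclass(frozen=True)
class AdaptationProtocol:
    """A schedule of environments for one learner on one state set.

    All environments share the state labels and the inverse temperature
    ``beta``.  ``proposal`` names the symmetric Metropolis proposal
    ("uniform" or "always_swap"); ``equilibrated`` starts the learner at the
    first environment's Boltzmann policy (so ``p_0 = p_1`` and the Crooks
    hypothesis holds by construction) — set it False to reproduce
    stationarity-failure scenarios.
    """

    states: tuple
    beta: float
    environments: tuple
    proposal: str = "uniform"
    seed: int = 0
    equilibrated: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "environments", tuple(self.environments))
        if len(self.environments) < 2:
            raise ValueError("an adaptation protocol needs at least 2 environments")
        for env in self.environments:
            if env.utility.shape != (len(self.states),):
                raise ValueError("every environment needs one utility per state")
        if not self.beta > 0:
            raise ValueError("beta must be positive")


def boltzmann_policy(U, beta: float) -> np.ndarray:
    """The max-entropy policy under an expected-utility constraint.

    ``p(x) = exp(beta U(x)) / sum_y exp(beta U(y))`` — evaluated in the log
    domain, strictly positive for finite utilities.
    """
    if not beta > 0:
        raise ValueError("beta must be positive")
    U = np.asarray(U, dtype=float)
    return softmax(beta * U)


def named_proposal(name: str, n_states: int) -> np.ndarray:
    """A symmetric, column-stochastic Metropolis proposal by name.

    ``"uniform"`` proposes every state with probability ``1/|S|`` (including
    staying); ``"always_swap"`` proposes each *other* state with probability
    ``1/(|S|-1)`` and never proposes staying.
    """
    if name == "uniform":
        return np.full((n_states, n_states), 1.0 / n_states)
    if name == "always_swap":
        P = np.full((n_states, n_states), 1.0 / (n_states - 1))
        np.fill_diagonal(P, 0.0)
        return P
    raise ValueError(f"unknown proposal {name!r}")


def policy_transition_matrix(p, proposal) -> np.ndarray:
    """A Metropolis matrix with prescribed stationary distribution ``p``.

    Off-diagonal entries are ``proposal[x, y] * min(1, p(x)/p(y))``; the
    diagonal absorbs the rejected mass.  The result is column-stochastic,
    satisfies detailed balance with respect to ``p`` (hence has it as a
    stationary distribution) — both verified on construction.  Only
    symmetric proposals are supported; any stochastic matrix with the right
    stationary distribution would do for the theory, and the Metropolis
    rule is the simplest constructive choice.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0):
        raise ValueError("the target policy must be strictly positive")
    proposal = np.asarray(proposal, dtype=float)
    if proposal.shape != (p.size, p.size):
        raise ValueError("proposal shape does not match the policy")
    if np.max(np.abs(proposal - proposal.T)) > 1e-12:
        raise ValueError(
            "proposal must be symmetric (the Hastings correction for "
            "asymmetric proposals is not supported)"
        )
    if np.any(proposal < 0) or np.max(np.abs(proposal.sum(axis=0) - 1.0)) > 1e-12:
        raise ValueError("proposal must be column-stochastic")
    accept = np.minimum(1.0, p[:, np.newaxis] / p[np.newaxis, :])
    M = proposal * accept
    np.fill_diagonal(M, 0.0)
    np.fill_diagonal(M, 1.0 - M.sum(axis=0))
    if not satisfies_detailed_balance(M, p, tol=1e-12):
        raise RuntimeError("Metropolis construction failed detailed balance")
    if np.max(np.abs(M @ p - p)) > 1e-12:
        raise RuntimeError("Metropolis construction failed stationarity")
    return M


def surprise_steps(x, family: EnergyFamily) -> np.ndarray:
    """The per-step driving signal ``w_n = E_{n+1}(x_n) - E_n(x_n)``.

    The surprise experienced when the environment switches while the
    decision-maker occupies ``x_n``; the steps sum exactly to the work.
    """
    x = as_trajectory(x)
    idx = x.indices(family.states)
    if idx.size != family.n_steps + 1:
        raise ValueError(
            f"trajectory has {idx.size} points, family expects {family.n_steps + 1}"
        )
    steps = np.arange(family.n_steps)
    return np.asarray(
        family.energies[steps + 1, idx[:-1]] - family.energies[steps, idx[:-1]]
    )


def run_adaptation(
    protocol: AdaptationProtocol,
    cap: int = 200_000,
    mc_samples: int = 100_000,
) -> tuple[DrivenChain, EnergyFamily, dict]:
    """Run an adaptation protocol and summarize its thermodynamics.

    Builds the driven chain whose step-``n`` matrix is the Metropolis matrix
    of the current environment's Boltzmann policy (each environment repeated
    ``dwell`` times).  With ``equilibrated=True`` the initial distribution is
    environment 1's policy, so the chain satisfies every fluctuation-theorem
    hypothesis by construction.  The summary reports the Jarzynski
    expectation, the second-law gap, and (when enumeration fits under
    ``cap``) the full Crooks report; otherwise it degrades to Monte Carlo
    with a notice.
    """
    beta = protocol.beta
    proposal = named_proposal(protocol.proposal, len(protocol.states))
    matrices: list[np.ndarray] = []
    policies = []
    for env in protocol.environments:
        pol = boltzmann_policy(env.utility, beta)
        policies.append(pol)
        M = policy_transition_matrix(pol, proposal)
        matrices.extend([M] * env.dwell)
    if protocol.equilibrated:
        p0 = policies[0]
    else:
        p0 = np.full(len(protocol.states), 1.0 / len(protocol.states))
    chain = DrivenChain(
        states=protocol.states, p0=p0, matrices=tuple(matrices), beta=beta
    )
    family = energy_family(chain)
    n_traj = chain.n_states ** (chain.n_steps + 1)
    summary: dict = {"n_trajectories": n_traj}
    if n_traj <= cap:
        summary["mode"] = "exact"
        summary["jarzynski"] = jarzynski_exact(chain, family, cap=cap)
        summary["second_law_gap"] = second_law_gap(chain, family, cap=cap)
        summary["crooks"] = crooks_report(chain, family, cap=cap)
    else:
        est, se = jarzynski_mc(chain, family, n=mc_samples, seed=protocol.seed)
        summary["mode"] = "mc"
        summary["jarzynski"] = est
        summary["jarzynski_se"] = se
        summary["notice"] = (
            f"{n_traj} trajectories exceed the enumeration cap {cap}; "
            "Jarzynski estimated by Monte Carlo, Crooks report omitted"
        )
    return chain, family, summary
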