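"""Plain-text serialization: chain/energy JSON, trajectory CSV, work tables.

Chain JSON schema::

    {"states": [...], "beta": number, "p0": [...],
     "matrices": [[[...]]], "convention": "to_from" | "from_to"}

Matrices are listed in time order.  The package convention is
``"to_from"`` (entry ``(x, y)`` = probability of moving *to* x *from* y,
column-stochastic); files written with ``"from_to"`` row-stochastic
matrices are transposed on load.  All readers validate what they load.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .chain import DrivenChain, Trajectory, validate_chain
from .thermo import EnergyFamily

__all__ = [
    "load_chain",
    "save_chain",
    "load_energy_family",
    "save_energy_family",
    "load_trajectory",
    "save_trajectory",
    "crooks_table_to_tsv",
]


def load_chain(path) -> DrivenChain:
    with open(path) as fh:
        doc = json.load(fh)
    convention = doc.get("convention", "to_from")
    if convention not in ("to_from", "from_to"):
        raise ValueError(f"unknown matrix convention {convention!r}")
    matrices = [np.asarray(M, dtype=float) for M in doc["matrices"]]
    if convention == "from_to":
        matrices = [M.T for M in matrices]
    chain = DrivenChain(
        states=tuple(doc["states"]),
        p0=np.asarray(doc["p0"], dtype=float),
        matrices=tuple(matrices),
        beta=float(doc.get("beta", 1.0)),
    )
    problems = validate_chain(chain)
    if problems:
        raise ValueError(
            f"{path}: invalid chain: " + "; ".join(problems)
        )
    return chain


def save_chain(chain: DrivenChain, path) -> None:
    doc = {
        "states": list(chain.states),
        "beta": chain.beta,
        "p0": chain.p0.tolist(),
        "matrices": [M.tolist() for M in chain.matrices],
        "convention": "to_from",
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def load_energy_family(path, states=None) -> EnergyFamily:
    """Load an energy family; ``states`` supplies labels when the file has none."""
    with open(path) as fh:
        doc = json.load(fh)
    energies = np.asarray(doc["energies"], dtype=float)
    file_states = doc.get("states")
    if file_states is not None:
        states = tuple(file_states)
    elif states is not None:
        states = tuple(states)
    else:
        states = tuple(range(energies.shape[1]))
    gauges = np.asarray(
        doc.get("gauges", np.zeros(energies.shape[0])), dtype=float
    )
    return EnergyFamily(
        states=states,
        beta=float(doc["beta"]),
        energies=energies,
        gauges=gauges,
    )


def save_energy_family(family: EnergyFamily, path) -> None:
    doc = {
        "states": list(family.states),
        "beta": family.beta,
        "energies": family.energies.tolist(),
        "gauges": family.gauges.tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def load_trajectory(path) -> Trajectory:
    """Read a trajectory CSV with columns ``step,state``, ordered by step."""
    df = pd.read_csv(path)
    missing = {"step", "state"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: trajectory CSV lacks columns {sorted(missing)}")
    df = df.sort_values("step")
    steps = df["step"].to_numpy()
    if not np.array_equal(steps, np.arange(len(steps))):
        raise ValueError(f"{path}: steps must be 0..N without gaps")
    return Trajectory(tuple(df["state"].tolist()))


def save_trajectory(x: Trajectory, path) -> None:
    pd.DataFrame(
        {"step": range(len(x)), "state": list(x.states_sequence)}
    ).to_csv(path, index=False)


def crooks_table_to_tsv(report, path) -> None:
    """Write a Crooks report's table as TSV (one row per forward work atom)."""
    report.table.to_csv(path, sep="\t", index=False)
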