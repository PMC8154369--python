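"""State and transition dipole moments of CI states; CT-partner selection.

Electronic dipoles follow μ_elec = −tr(γ·r) with γ the (transition) 1-RDM
and r the dipole-operator matrices in the orthonormal orbital basis; state
dipoles add the nuclear contribution Σ_A Z_A (R_A − O).  All dipoles are in
atomic units about the recorded gauge origin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .cisolve import CIState, transition_one_rdm
from .fcidump import IntegralSet
from .gmh import AdiabaticTwoState, GMHUndefinedError


@dataclass
class PropertyIntegrals:
    """One-electron dipole matrices (3, n, n) in a.u. plus the nuclear
    dipole contribution, referenced to ``gauge_origin`` (Å)."""

    dipole: np.ndarray
    nuclear_dipole: np.ndarray = field(default_factory=lambda: np.zeros(3))
    gauge_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.dipole = np.asarray(self.dipole, dtype=float)
        self.nuclear_dipole = np.asarray(self.nuclear_dipole, dtype=float)
        self.gauge_origin = np.asarray(self.gauge_origin, dtype=float)
        if self.dipole.ndim != 3 or self.dipole.shape[0] != 3:
            raise ValueError("dipole must have shape (3, n, n)")
        for k in range(3):
            if not np.allclose(self.dipole[k], self.dipole[k].T, atol=1e-10):
                raise ValueError(f"dipole component {k} is not symmetric")

    @property
    def n_orb(self) -> int:
        return self.dipole.shape[1]


def state_dipole(state: CIState, prop: PropertyIntegrals, ints=None) -> np.ndarray:
    """Total (electronic + nuclear) dipole 3-vector of one CI state (a.u.)."""
    rdm = transition_one_rdm(state, state, ints)
    mu_e = -np.einsum("kpq,qp->k", prop.dipole, rdm)
    return mu_e + prop.nuclear_dipole


def transition_dipole(
    bra: CIState, ket: CIState, prop: PropertyIntegrals, ints=None
) -> np.ndarray:
    """Transition dipole 3-vector between two CI states (a.u., no nuclear term)."""
    rdm = transition_one_rdm(bra, ket, ints)
    return -np.einsum("kpq,qp->k", prop.dipole, rdm)


def dipole_moments(
    states: list[CIState], prop: PropertyIntegrals, ints=None
) -> tuple[np.ndarray, np.ndarray]:
    """State dipoles (n_states, 3) and transition dipoles (n, n, 3)."""
    if prop.n_orb != states[0].space.n_orb:
        raise ValueError("property integrals and CI space dimension mismatch")
    mus = np.array([state_dipole(s, prop, ints) for s in states])
    n = len(states)
    trans = np.zeros((n, n, 3))
    for i in range(n):
        for j in range(i + 1, n):
            t = transition_dipole(states[i], states[j], prop, ints)
            trans[i, j] = t
            trans[j, i] = t
    return mus, trans


def make_adiabatic_pair(
    states: list[CIState],
    prop: PropertyIntegrals,
    i: int = 0,
    j: int = 1,
    ints=None,
    label: str = "",
) -> AdiabaticTwoState:
    """Package two CI states as GMH input (energies + dipole matrix)."""
    mu_i = state_dipole(states[i], prop, ints)
    mu_j = state_dipole(states[j], prop, ints)
    mu_t = transition_dipole(states[i], states[j], prop, ints)
    return AdiabaticTwoState(
        e_ground=states[i].energy,
        e_excited=states[j].energy,
        mu_ground=mu_i,
        mu_excited=mu_j,
        mu_transition=mu_t,
        gauge_origin=prop.gauge_origin,
        label=label,
    )


def select_ct_partner(
    states: list[CIState],
    prop: PropertyIntegrals,
    donor_acceptor_axis: np.ndarray,
    ints=None,
    tol: float = 1e-6,
) -> int:
    """Index of the excited state with the largest |transition dipole·axis|
    with the ground state; ties broken toward lower energy."""
    if len(states) < 2:
        raise ValueError("need at least two states to select a CT partner")
    axis = np.asarray(donor_acceptor_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    best, best_val = None, -1.0
    for j in range(1, len(states)):
        proj = abs(
            float(transition_dipole(states[0], states[j], prop, ints) @ axis)
        )
        if proj > best_val + 1e-12:
            best, best_val = j, proj
    if best is None or best_val < tol:
        raise GMHUndefinedError(
            "no CT state found: all projected transition dipoles vanish"
        )
    return best


# ---------------------------------------------------------------------------
# dipole-dump I/O: three one-electron dumps + a JSON sidecar
# ---------------------------------------------------------------------------


def write_property_integrals(prop: PropertyIntegrals, basename: str) -> None:
    n = prop.n_orb
    for axis, tag in enumerate("xyz"):
        lines = [f"&PROP NORB={n}, COMPONENT={tag},", "&END"]
        m = prop.dipole[axis]
        for i in range(n):
            for j in range(i + 1):
                if m[i, j] != 0.0:
                    lines.append(f"{m[i, j]:23.16E} {i + 1:4d} {j + 1:4d}    0    0")
        with open(f"{basename}.dip{tag}", "w") as fh:
            fh.write("\n".join(lines) + "\n")
    with open(f"{basename}.json", "w") as fh:
        json.dump(
            {
                "nuclear_dipole_au": prop.nuclear_dipole.tolist(),
                "gauge_origin_angstrom": prop.gauge_origin.tolist(),
                "n_orb": n,
            },
            fh,
            indent=1,
        )


def read_property_integrals(basename: str) -> PropertyIntegrals:
    with open(f"{basename}.json") as fh:
        meta = json.load(fh)
    n = int(meta["n_orb"])
    dip = np.zeros((3, n, n))
    for axis, tag in enumerate("xyz"):
        with open(f"{basename}.dip{tag}") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("&"):
                    continue
                parts = line.split()
                v = float(parts[0])
                i, j = int(parts[1]) - 1, int(parts[2]) - 1
                dip[axis, i, j] = v
                dip[axis, j, i] = v
    return PropertyIntegrals(
        dipole=dip,
        nuclear_dipole=np.asarray(meta["nuclear_dipole_au"]),
        gauge_origin=np.asarray(meta["gauge_origin_angstrom"]),
    )
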