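"""Two-state generalized Mulliken–Hush (GMH) diabatization.

The GMH method converts a pair of adiabatic states (ground + charge-transfer
excited state) into charge-localized diabatic states by requiring the
diabatic transition dipole to vanish.  All dipoles are first projected on
the direction of the adiabatic transition dipole; the 2×2 rotation that
diagonalizes the projected dipole matrix is then applied to the adiabatic
Hamiltonian, whose off-diagonal element is the electronic coupling

    H_AB = μ_AB ΔE_AB / sqrt((μ_AA − μ_BB)² + 4 μ_AB²)

For symmetric donor–acceptor pairs (μ_AA = μ_BB) this reduces to
H_AB = ΔE_AB / 2, i.e. half the adiabatic splitting.

Energies enter in hartree; couplings are reported in meV.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .units import hartree_to_mev

#: below this |μ_AA − μ_BB| (a.u.) the symmetric reduction is used, which
#: avoids catastrophic cancellation in the rotation-angle formula
SYMMETRIC_TOL = 1e-8


class GMHUndefinedError(ValueError):
    """Raised when the GMH transformation is not defined for the input."""


@dataclass(frozen=True)
class AdiabaticTwoState:
    """Energies and dipole matrix of a ground/CT adiabatic state pair.

    Dipoles are 3-vectors in atomic units; ``gauge_origin`` (Å) records the
    reference point of the dipole operator so that origin dependence of the
    inputs stays auditable (the GMH coupling itself is origin-invariant).
    """

    e_ground: float
    e_excited: float
    mu_ground: np.ndarray
    mu_excited: np.ndarray
    mu_transition: np.ndarray
    gauge_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    label: str = ""

    def __post_init__(self):
        for name in ("mu_ground", "mu_excited", "mu_transition", "gauge_origin"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,):
                raise ValueError(f"{name} must be a 3-vector, got shape {v.shape}")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} contains non-finite components")
            object.__setattr__(self, name, v)
        if self.e_excited < self.e_ground:
            raise ValueError(
                f"e_excited ({self.e_excited}) < e_ground ({self.e_ground})"
            )

    @property
    def delta_e(self) -> float:
        """Adiabatic energy gap ΔE_AB in hartree."""
        return self.e_excited - self.e_ground


@dataclass(frozen=True)
class GMHResult:
    """Diabatized two-state quantities.  Energies in meV, dipoles in a.u."""

    h_ab: float
    e_diab_a: float
    e_diab_b: float
    delta_mu_diab: float
    rotation_angle: float
    symmetric_case: bool
    label: str = ""


def project_dipoles(state: AdiabaticTwoState) -> tuple[float, float, float]:
    """Project the three dipole vectors on the transition-dipole direction.

    Returns the scalars (μ_AA, μ_BB, μ_AB) in a.u.; μ_AB equals
    |μ_transition| by construction.  A vanishing transition dipole means
    the pair has no charge-transfer character and GMH is undefined.
    """
    t = state.mu_transition
    norm = float(np.linalg.norm(t))
    if norm <= 0.0:
        raise GMHUndefinedError(
            "zero transition dipole: no CT character; GMH undefined"
        )
    u = t / norm
    return float(state.mu_ground @ u), float(state.mu_excited @ u), norm


def gmh_coupling(state: AdiabaticTwoState) -> GMHResult:
    """Diabatize one adiabatic pair and return the electronic coupling.

    The sign of H_AB is retained; curve building and decay fitting use the
    magnitude.  ``symmetric_case`` flags inputs with |μ_AA − μ_BB| below
    :data:`SYMMETRIC_TOL`, for which H_AB = ΔE_AB/2 exactly.
    """
    mu_aa, mu_bb, mu_ab = project_dipoles(state)
    de = state.delta_e
    dmu = mu_aa - mu_bb

    if abs(mu_ab) == 0.0 and abs(dmu) <= SYMMETRIC_TOL:
        raise GMHUndefinedError(
            "degenerate GMH transformation: both the transition dipole and "
            "the diabatic dipole difference vanish"
        )

    symmetric = abs(dmu) < SYMMETRIC_TOL
    if symmetric:
        h_ab_hartree = 0.5 * de
        delta_mu_diab = 2.0 * abs(mu_ab)
        angle = math.pi / 4.0
    else:
        denom = math.hypot(dmu, 2.0 * mu_ab)
        h_ab_hartree = mu_ab * de / denom
        delta_mu_diab = denom
        # rotation that diagonalizes the projected dipole matrix
        angle = 0.5 * math.atan2(2.0 * mu_ab, dmu)

    # diabatic site energies from rotating the adiabatic Hamiltonian
    c, s = math.cos(angle), math.sin(angle)
    e_g, e_x = state.e_ground, state.e_excited
    e_a = c * c * e_g + s * s * e_x
    e_b = s * s * e_g + c * c * e_x

    return GMHResult(
        h_ab=hartree_to_mev(h_ab_hartree),
        e_diab_a=hartree_to_mev(e_a),
        e_diab_b=hartree_to_mev(e_b),
        delta_mu_diab=delta_mu_diab,
        rotation_angle=angle,
        symmetric_case=symmetric,
        label=state.label,
    )


def build_coupling_curve(
    tagged_states: list[tuple[float, str, AdiabaticTwoState]],
) -> "pd.DataFrame":
    """Assemble a distance-resolved coupling curve from adiabatic pairs.

    ``tagged_states`` is a list of (distance in Å, spin label, state).
    Returns a DataFrame with columns (distance, h_ab, spin_label) sorted by
    ascending distance.  All rows must share one spin label; duplicate
    distances are rejected.
    """
    if not tagged_states:
        warnings.warn("empty input: returning empty coupling curve", stacklevel=2)
        return pd.DataFrame(columns=["distance", "h_ab", "spin_label"])

    labels = {lab for _, lab, _ in tagged_states}
    if len(labels) > 1:
        raise ValueError(f"mixed spin labels in one curve: {sorted(labels)}")

    dists = [d for d, _, _ in tagged_states]
    if len(set(dists)) != len(dists):
        dupes = sorted({d for d in dists if dists.count(d) > 1})
        raise ValueError(f"duplicate distances in curve: {dupes}")

    rows = [
        {"distance": d, "h_ab": gmh_coupling(st).h_ab, "spin_label": lab}
        for d, lab, st in tagged_states
    ]
    return (
        pd.DataFrame(rows).sort_values("distance", ignore_index=True)
    )


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

#: column schema for adiabatic-state tables: energies in hartree, dipole
#: components in a.u.
ADIABATIC_COLUMNS = [
    "label",
    "e_ground",
    "e_excited",
    "mu_gx", "mu_gy", "mu_gz",
    "mu_xx", "mu_xy", "mu_xz",
    "mu_tx", "mu_ty", "mu_tz",
]


def read_adiabatic_table(path) -> list[AdiabaticTwoState]:
    """Read a CSV table of adiabatic pairs (see :data:`ADIABATIC_COLUMNS`)."""
    df = pd.read_csv(path)
    missing = [c for c in ADIABATIC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"adiabatic table missing columns: {missing}")
    states = []
    for _, r in df.iterrows():
        states.append(
            AdiabaticTwoState(
                e_ground=float(r.e_ground),
                e_excited=float(r.e_excited),
                mu_ground=np.array([r.mu_gx, r.mu_gy, r.mu_gz]),
                mu_excited=np.array([r.mu_xx, r.mu_xy, r.mu_xz]),
                mu_transition=np.array([r.mu_tx, r.mu_ty, r.mu_tz]),
                label=str(r.label),
            )
        )
    return states


def write_gmh_results(results: list[GMHResult], path) -> None:
    """Write GMH results as JSON records; energies in meV, dipoles in a.u."""
    payload = {
        "units": {"h_ab": "meV", "e_diab": "meV", "delta_mu_diab": "a.u.",
                  "rotation_angle": "rad"},
        "results": [vars(r) for r in results],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
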