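"""Synthetic model systems with known reference behaviour.

This module generates every input the rest of the package consumes:
collinear H₂···H₂⁺ dimer geometries, AO integrals for them, Hubbard/Hückel
dimer integral sets with closed-form couplings, and random two-state
diabatic models whose exact H_AB is known by construction (the round-trip
oracle for GMH).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fcidump import IntegralSet
from .gmh import AdiabaticTwoState
from .integrals import (
    AOIntegrals,
    ELEMENT_Z,
    GaussianBasis,
    compute_integrals,
    load_basis,
    lowdin_orthogonalization,
    mo_transform,
)
from .properties import PropertyIntegrals


@dataclass(frozen=True)
class MoleculeGeometry:
    """Atoms + Cartesian coordinates (Å), total charge, spin multiplicity."""

    symbols: tuple
    coordinates: np.ndarray
    charge: int = 0
    multiplicity: int = 1

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "symbols", tuple(self.symbols))
        if len(self.symbols) != len(coords):
            raise ValueError("symbols and coordinates length mismatch")
        for i in range(len(coords)):
            for j in range(i):
                if np.linalg.norm(coords[i] - coords[j]) < 1e-6:
                    raise ValueError(f"coincident nuclei at atoms {j},{i}")
        ne = self.n_electrons
        if ne < 0:
            raise ValueError("more positive charge than electrons")
        if (ne - (self.multiplicity - 1)) % 2 != 0:
            raise ValueError(
                f"multiplicity {self.multiplicity} impossible with {ne} electrons"
            )

    @property
    def n_electrons(self) -> int:
        return int(sum(ELEMENT_Z[s] for s in self.symbols) - self.charge)

    def to_xyz(self) -> str:
        lines = [str(len(self.symbols)), f"charge={self.charge} mult={self.multiplicity}"]
        for s, (x, y, z) in zip(self.symbols, self.coordinates):
            lines.append(f"{s} {x:18.12f} {y:18.12f} {z:18.12f}")
        return "\n".join(lines) + "\n"


def make_h2_dimer(
    d_intra: float, r_sep: float, arrangement: str = "parallel", multiplicity: int = 2
) -> MoleculeGeometry:
    """H₂···H₂⁺ model dimer: both H–H bonds ``d_intra``, center-of-mass
    separation ``r_sep`` (Å), net charge +1, overall inversion symmetry.

    ``arrangement="parallel"`` (default) stacks the two molecules side by
    side with their bond axes parallel (along x) and separated along z;
    this geometry reproduces the reference spin-state contrast (high-spin
    couplings a little over five-fold the low-spin ones) and both decay
    constants.  ``"collinear"`` places all four atoms on the z axis; there
    the σ/σ* lobes point directly at the partner, which exaggerates the
    high-spin coupling (≈17× at 4 Å) and flattens its decay.
    """
    if arrangement == "parallel":
        if r_sep <= 0:
            raise ValueError(f"parallel stack requires r_sep > 0 ({r_sep} given)")
        coords = np.array(
            [
                [-d_intra / 2, 0.0, -r_sep / 2],
                [+d_intra / 2, 0.0, -r_sep / 2],
                [-d_intra / 2, 0.0, +r_sep / 2],
                [+d_intra / 2, 0.0, +r_sep / 2],
            ]
        )
    elif arrangement == "collinear":
        if r_sep <= d_intra:
            raise ValueError(
                f"collinear stack requires r_sep > d_intra ({r_sep} <= {d_intra})"
            )
        z = [
            -r_sep / 2 - d_intra / 2,
            -r_sep / 2 + d_intra / 2,
            +r_sep / 2 - d_intra / 2,
            +r_sep / 2 + d_intra / 2,
        ]
        coords = np.array([[0.0, 0.0, zz] for zz in z])
    else:
        raise NotImplementedError(f"arrangement {arrangement!r} not supported")
    return MoleculeGeometry(
        symbols=("H", "H", "H", "H"), coordinates=coords, charge=1,
        multiplicity=multiplicity,
    )


def make_h2(d: float, charge: int = 0, multiplicity: int = 1) -> MoleculeGeometry:
    """Single H₂ (or H₂⁺) along z, bond length d (Å), centered at origin."""
    coords = np.array([[0.0, 0.0, -d / 2], [0.0, 0.0, d / 2]])
    return MoleculeGeometry(
        symbols=("H", "H"), coordinates=coords, charge=charge,
        multiplicity=multiplicity,
    )


def compute_ao_integrals(
    geom: MoleculeGeometry, basis: GaussianBasis | str, drop_d: bool = False
) -> tuple[np.ndarray, AOIntegrals]:
    """AO-basis integrals for a geometry; returns (overlap, full AO set)."""
    if isinstance(basis, str):
        basis = load_basis(basis)
    ao = compute_integrals(geom.symbols, geom.coordinates, basis, drop_d=drop_d)
    return ao.overlap, ao


def orthonormal_integrals(
    geom: MoleculeGeometry,
    basis: GaussianBasis | str,
    ms2: int | None = None,
    drop_d: bool = False,
    canonicalize: bool = True,
) -> tuple[IntegralSet, PropertyIntegrals]:
    """Löwdin-orthogonalized integral set + dipole integrals for CI.

    No SCF step: FCI in the given space is invariant under orthonormal
    orbital choice, so symmetric orthogonalization of the AO basis is
    sufficient and deterministic.  With ``canonicalize`` the Löwdin
    orbitals are additionally rotated to diagonalize the one-electron core
    Hamiltonian (still SCF-free and FCI-invariant); this orders the
    determinant diagonal physically, which sharpens Davidson start vectors
    and preconditioning considerably in diffuse bases.
    """
    _, ao = compute_ao_integrals(geom, basis, drop_d=drop_d)
    x = lowdin_orthogonalization(ao.overlap)
    if canonicalize:
        hcore = x.T @ ao.core_hamiltonian @ x
        _, u = np.linalg.eigh(hcore)
        # deterministic sign: largest-magnitude component positive
        for k in range(u.shape[1]):
            imax = int(np.argmax(np.abs(u[:, k])))
            if u[imax, k] < 0:
                u[:, k] = -u[:, k]
        x = x @ u
    h = x.T @ ao.core_hamiltonian @ x
    g = mo_transform(ao.eri, x)
    dip = np.einsum("pi,kpq,qj->kij", x, ao.dipole, x, optimize=True)
    ne = geom.n_electrons
    if ms2 is None:
        ms2 = geom.multiplicity - 1
    ints = IntegralSet(
        n_orb=h.shape[0], n_elec=ne, ms2=ms2, e_core=ao.e_nuc, h_one=h, g_two=g
    )
    prop = PropertyIntegrals(
        dipole=dip, nuclear_dipole=ao.nuclear_dipole, gauge_origin=ao.gauge_origin
    )
    return ints, prop


def hubbard_dimer_fcidump(
    t: float, u: float, n_elec: int = 2, ms2: int = 0
) -> IntegralSet:
    """Two-site Hubbard model: h₁₂ = −t, on-site repulsion U.

    Oracle facts: with one electron the splitting is 2t (H_AB ≡ |t|); at
    half filling the singlet ground energy is (U − sqrt(U² + 16t²))/2.
    """
    h = np.array([[0.0, -t], [-t, 0.0]])
    g = np.zeros((2, 2, 2, 2))
    g[0, 0, 0, 0] = u
    g[1, 1, 1, 1] = u
    return IntegralSet(n_orb=2, n_elec=n_elec, ms2=ms2, e_core=0.0, h_one=h, g_two=g)


@dataclass(frozen=True)
class DiabaticModelFixture:
    """Random two-state diabatic model with exactly known H_AB.

    The diabatic transition dipole is zero by construction (the defining
    GMH assumption), so feeding the diagonalized adiabatic data back
    through GMH must recover ``h_ab_au`` to machine precision.
    """

    h_diab: np.ndarray          # 2×2 hartree, off-diagonal = H_AB
    mu_diab: np.ndarray         # diagonal diabatic dipoles (a.u., scalars)
    axis: np.ndarray            # unit vector carrying the dipoles
    adiabatic: AdiabaticTwoState
    seed: int
    h_ab_au: float = field(init=False, default=0.0)

    def __post_init__(self):
        object.__setattr__(self, "h_ab_au", float(self.h_diab[0, 1]))


def random_diabatic_fixture(seed: int) -> DiabaticModelFixture:
    """Seeded diabatic model: H_AB ∈ [0.001, 0.2] a.u., site-energy gap
    ∈ [0, 0.5] a.u., Δμ_diab ∈ [0.5, 10] a.u., random dipole axis."""
    rng = np.random.default_rng(seed)
    h_ab = rng.uniform(0.001, 0.2)
    gap = rng.uniform(0.0, 0.5)
    dmu = rng.uniform(0.5, 10.0)
    mu_off = rng.uniform(-2.0, 2.0)
    axis = rng.normal(size=3)
    axis = axis / np.linalg.norm(axis)

    h_d = np.array([[-gap / 2, h_ab], [h_ab, gap / 2]])
    mu_d = np.diag([mu_off + dmu / 2, mu_off - dmu / 2])
    evals, vecs = np.linalg.eigh(h_d)
    mu_ad = vecs.T @ mu_d @ vecs
    state = AdiabaticTwoState(
        e_ground=float(evals[0]),
        e_excited=float(evals[1]),
        mu_ground=mu_ad[0, 0] * axis,
        mu_excited=mu_ad[1, 1] * axis,
        mu_transition=mu_ad[0, 1] * axis,
        label=f"diabatic-fixture-{seed}",
    )
    return DiabaticModelFixture(
        h_diab=h_d, mu_diab=np.diag(mu_d), axis=axis, adiabatic=state, seed=seed
    )
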