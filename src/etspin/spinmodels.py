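"""Two-site double-exchange model and spin-resolved effective couplings.

One itinerant electron hops (amplitude t) between two sites that each carry
a localized core spin s_core; a ferromagnetic Hund coupling J aligns the
itinerant spin with the core spin of the site it occupies.  Exact
diagonalization in total-spin sectors yields spin-resolved effective
transfer couplings H_AB_eff(S).  In the infinite-Hund (Anderson–Hasegawa)
limit the effective hopping carries the spin factor

    H_AB_eff(S) = |t| (S + 1/2) / (2 s_core + 1)

so that e.g. for s_core = 2 the ratio between the ferromagnetic (S = 9/2)
and antiferromagnetic (S = 1/2) sectors is exactly 5.  The same factor
governs the overlap between charge-localized states of high- and low-spin
donor–acceptor pairs, which is why antiferromagnetically coupled dimers
show systematically smaller couplings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

_S2_PURITY_TOL = 1e-8


def _is_half_integer(x: float) -> bool:
    return abs(2 * x - round(2 * x)) < 1e-12


def spin_matrices(s: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (Sx, Sy, Sz) for spin s; Sy is returned as a complex array."""
    n = int(round(2 * s + 1))
    m = s - np.arange(n)  # m = s, s-1, ..., -s
    sz = np.diag(m)
    # ⟨m+1|S+|m⟩ = sqrt(s(s+1) − m(m+1))
    sp = np.zeros((n, n))
    for k in range(1, n):
        mm = m[k]
        sp[k - 1, k] = math.sqrt(s * (s + 1) - mm * (mm + 1))
    sx = 0.5 * (sp + sp.T)
    sy = -0.5j * (sp - sp.T)
    return sx, sy, sz


@dataclass(frozen=True)
class DoubleExchangeSpec:
    """Two-site double-exchange model parameters.

    ``j_hund = math.inf`` selects the Anderson–Hasegawa limit, implemented
    by projection onto maximal on-site spin before diagonalization.
    ``s0_min`` is the minimal spin of the paramagnetic ions entering the
    spin-overlap factor (0 for the systems considered here).
    """

    s_core: float
    t_hop: float = 1.0
    j_hund: float = math.inf
    s0_min: float = 0.0

    def __post_init__(self):
        if self.s_core < 0 or not _is_half_integer(self.s_core):
            raise ValueError(f"s_core must be a non-negative half-integer, got {self.s_core}")
        if not np.isfinite(self.t_hop):
            raise ValueError("t_hop must be finite")
        if self.j_hund < 0:
            raise ValueError("j_hund must be >= 0 (or math.inf)")

    @property
    def dim(self) -> int:
        n = int(round(2 * self.s_core + 1))
        return n * n * 4

    @property
    def s_max(self) -> float:
        return 2 * self.s_core + 0.5


@dataclass(frozen=True)
class SpinSectorCoupling:
    """Effective coupling in one total-spin sector.

    ``h_ab_eff`` is half the splitting of the lowest bonding/antibonding
    pair; ``eigenvalues`` are the sector eigenvalues at S_z = S.
    """

    s_total: float
    eigenvalues: np.ndarray
    h_ab_eff: float
    degeneracy: int
    s_squared_residual: float = 0.0


def _electron_ops(op2: np.ndarray, site: int | None = None) -> np.ndarray:
    """Lift a 2×2 spin operator into the 4-dim (site ⊗ spin) electron space."""
    if site is None:
        site_m = np.eye(2)
    else:
        site_m = np.diag([1.0, 0.0] if site == 0 else [0.0, 1.0])
    return np.kron(site_m, op2)


def _build_operators(spec: DoubleExchangeSpec):
    """Full-space H (finite J), S², S_z, Hund spin-coupling terms per site."""
    s = spec.s_core
    n = int(round(2 * s + 1))
    sa = spin_matrices(s)
    se = spin_matrices(0.5)
    i_a = np.eye(n)
    i_e4 = np.eye(4)

    def lift_core(op, which):
        if which == "A":
            return np.kron(np.kron(op, i_a), i_e4)
        return np.kron(np.kron(i_a, op), i_e4)

    def lift_elec(op4):
        return np.kron(np.kron(i_a, i_a), op4)

    # Hund terms K_site = S_site · s_e restricted to the occupied site
    k_terms = {}
    for site, which in ((0, "A"), (1, "B")):
        k = np.zeros((spec.dim, spec.dim), dtype=complex)
        for core_op, e_op in zip(sa, se):
            k += lift_core(core_op, which) @ lift_elec(_electron_ops(e_op, site))
        k_terms[which] = k

    hop = lift_elec(np.kron(np.array([[0.0, 1.0], [1.0, 0.0]]), np.eye(2)))
    h = -spec.t_hop * hop
    if np.isfinite(spec.j_hund):
        h = h - spec.j_hund * (k_terms["A"] + k_terms["B"])

    # total spin
    s2 = np.zeros((spec.dim, spec.dim), dtype=complex)
    sz_tot = None
    for axis in range(3):
        tot = (
            lift_core(sa[axis], "A")
            + lift_core(sa[axis], "B")
            + lift_elec(_electron_ops(se[axis]))
        )
        s2 = s2 + tot @ tot
        if axis == 2:
            sz_tot = tot
    return np.real_if_close(h), np.real_if_close(s2), np.real(np.diag(sz_tot)), k_terms


def build_double_exchange_hamiltonian(
    spec: DoubleExchangeSpec,
) -> tuple[np.ndarray, list[tuple[float, float, str, str]]]:
    """Real symmetric Hamiltonian and basis labels (m_A, m_B, site, spin).

    For infinite Hund coupling the returned matrix is the bare hopping
    Hamiltonian on the full product space; the Hund projection is applied
    inside :func:`sector_effective_couplings`.
    """
    h, _, _, _ = _build_operators(spec)
    s = spec.s_core
    n = int(round(2 * s + 1))
    m_vals = [s - k for k in range(n)]
    labels = [
        (ma, mb, site, spin)
        for ma in m_vals
        for mb in m_vals
        for site in ("A", "B")
        for spin in ("alpha", "beta")
    ]
    return np.real(h), labels


def _hund_projector(spec: DoubleExchangeSpec, k_terms) -> np.ndarray:
    """Projector onto maximal on-site spin s_core + 1/2 of the occupied site."""
    s = spec.s_core
    dim = spec.dim
    i_full = np.eye(dim)
    proj = np.zeros((dim, dim), dtype=complex)
    for site, which in ((0, "A"), (1, "B")):
        # site-occupation projector lifted to the full space
        occ = np.kron(np.eye(int(round(2 * s + 1)) ** 2), _electron_ops(np.eye(2), site))
        # eigenvalues of S·s for s ⊗ 1/2: s/2 (S = s+1/2), −(s+1)/2 (S = s−1/2)
        proj += (k_terms[which] + 0.5 * (s + 1) * occ) / (s + 0.5)
    assert np.allclose(proj @ proj, proj, atol=1e-10)
    _ = i_full
    return np.real_if_close(proj)


def sector_effective_couplings(
    spec: DoubleExchangeSpec, s_total: float | None = None
) -> list[SpinSectorCoupling]:
    """Spin-sector-resolved effective couplings by exact diagonalization.

    Works at S_z = S for each accessible total spin S: the S_z block is
    selected from the (diagonal) S_z operator, purified by diagonalizing S²
    within the block, and H is then diagonalized in the pure-S subspace.
    H_AB_eff(S) is half the splitting of the lowest pair.  Sectors are
    returned in decreasing S; ``s_total`` restricts to one sector and raises
    if that sector is inaccessible.
    """
    h, s2, sz_diag, k_terms = _build_operators(spec)
    if not np.isfinite(spec.j_hund):
        p = _hund_projector(spec, k_terms)
        w, v = np.linalg.eigh(p)
        basis = v[:, w > 0.5]
        h = basis.T.conj() @ h @ basis
        s2 = basis.T.conj() @ s2 @ basis
        sz_full = basis.T.conj() @ np.diag(sz_diag) @ basis
    else:
        sz_full = np.diag(sz_diag)

    s_max = spec.s_max
    sectors: list[SpinSectorCoupling] = []
    s_val = s_max
    while s_val > -0.25:
        # restrict to S_z = s_val
        wz, vz = np.linalg.eigh(sz_full)
        sel = np.abs(wz - s_val) < 1e-9
        if not np.any(sel):
            s_val -= 1.0
            continue
        bz = vz[:, sel]
        s2_blk = bz.T.conj() @ s2 @ bz
        w2, v2 = np.linalg.eigh(s2_blk)
        target = s_val * (s_val + 1)
        pure = np.abs(w2 - target) < 1e-6
        if np.any(pure):
            bs = bz @ v2[:, pure]
            h_blk = bs.T.conj() @ h @ bs
            evals = np.sort(np.linalg.eigvalsh(h_blk))
            resid = float(np.max(np.abs(w2[pure] - target)))
            if resid > _S2_PURITY_TOL:
                raise RuntimeError(f"S² purity violated in sector S={s_val}: {resid}")
            if len(evals) >= 2:
                h_eff = 0.5 * abs(evals[1] - evals[0])
            else:
                h_eff = 0.0
            sectors.append(
                SpinSectorCoupling(
                    s_total=s_val,
                    eigenvalues=evals,
                    h_ab_eff=float(h_eff),
                    degeneracy=int(round(2 * s_val + 1)),
                    s_squared_residual=resid,
                )
            )
        s_val -= 1.0

    if s_total is not None:
        for sec in sectors:
            if abs(sec.s_total - s_total) < 1e-9:
                return [sec]
        accessible = [sec.s_total for sec in sectors]
        raise ValueError(
            f"no sector with S_total={s_total}; accessible sectors: {accessible}"
        )
    return sectors


def anderson_hasegawa_factor(s_total: float, s_core: float) -> float:
    """Closed-form spin factor (S + 1/2)/(2 s_core + 1) of the effective hopping."""
    if s_total < 0 or s_core < 0:
        raise ValueError("spins must be non-negative")
    return (s_total + 0.5) / (2 * s_core + 1)


def anderson_hasegawa_ratio(s1: float, s2: float) -> float:
    """Ratio of spin-overlap/coupling factors between two total-spin sectors.

    (S1 + 1/2)/(S2 + 1/2); for S1 = 9/2, S2 = 1/2 this gives the factor 5
    separating ferro- and antiferromagnetically aligned dimers with
    s_core = 2 cores and minimal ionic spin s0 = 0.
    """
    if s1 < 0 or s2 < 0:
        raise ValueError("spins must be non-negative")
    return (s1 + 0.5) / (s2 + 0.5)
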