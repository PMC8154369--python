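"""Gaussian-basis molecular integrals via McMurchie–Davidson recursion.

Computes overlap, kinetic, nuclear-attraction, dipole, and two-electron
repulsion integrals over contracted Cartesian Gaussians (angular momentum
up to l = 3 in the recursions; s, p, d are exercised by the shipped bases),
followed by the solid-harmonic transformation to spherical components and
exact renormalization to unit self-overlap.  Basis sets are read from
NWChem-dialect text (the basis-set-exchange download format).

All kernel arithmetic is in atomic units (bohr, hartree); the public
functions accept coordinates in Å.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .units import ANGSTROM_TO_BOHR

MAX_L = 3  # recursion buffers sized for f; s,p,d are the supported surface
_L_LETTER = {"S": 0, "P": 1, "D": 2, "F": 3}
_SCREEN = 1e-18

ELEMENT_Z = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "S": 16, "Cl": 17, "Ca": 20,
    "Fe": 26,
}

# Cartesian components per l, concatenated: ordering lx descending, then ly
_COMP_OFF = np.array([0, 1, 4, 10, 20], dtype=np.int64)
_CLX = np.zeros(20, dtype=np.int64)
_CLY = np.zeros(20, dtype=np.int64)
_CLZ = np.zeros(20, dtype=np.int64)
_i = 0
for _l in range(4):
    for _lx in range(_l, -1, -1):
        for _ly in range(_l - _lx, -1, -1):
            _CLX[_i], _CLY[_i], _CLZ[_i] = _lx, _ly, _l - _lx - _ly
            _i += 1
assert _i == 20


def n_cart(l: int) -> int:
    return (l + 1) * (l + 2) // 2


def n_sph(l: int) -> int:
    return 2 * l + 1


def _solid_harmonic_block(l: int) -> np.ndarray:
    """(n_cart, n_sph) coefficients of real solid harmonics over raw
    Cartesian polynomials; overall scale is fixed later by renormalization."""
    if l == 0:
        return np.array([[1.0]])
    if l == 1:
        return np.eye(3)
    if l == 2:
        # cart order xx,xy,xz,yy,yz,zz ; sph order m = -2,-1,0,+1,+2
        m = np.zeros((6, 5))
        m[1, 0] = 1.0                      # xy
        m[4, 1] = 1.0                      # yz
        m[0, 2], m[3, 2], m[5, 2] = -0.5, -0.5, 1.0   # (2z²-x²-y²)/2
        m[2, 3] = 1.0                      # xz
        m[0, 4], m[3, 4] = 0.5, -0.5       # (x²-y²)/2
        return m
    raise NotImplementedError(f"spherical transform for l={l} not provided")


# ---------------------------------------------------------------------------
# basis sets
# ---------------------------------------------------------------------------


@dataclass
class GaussianBasis:
    """Per-element shells: list of (l, exponents, contraction coefficients)."""

    name: str
    shells: dict = field(default_factory=dict)

    def for_element(self, symbol: str):
        if symbol not in self.shells:
            raise KeyError(f"basis {self.name!r} has no element {symbol}")
        return self.shells[symbol]

    def without_l_above(self, lmax: int) -> "GaussianBasis":
        kept = {
            el: [sh for sh in shells if sh[0] <= lmax]
            for el, shells in self.shells.items()
        }
        return GaussianBasis(name=f"{self.name}(l<={lmax})", shells=kept)


def parse_nwchem_basis(text: str, name: str = "") -> GaussianBasis:
    """Parse NWChem-format basis text (single-column contractions)."""
    shells: dict = {}
    current = None  # (element, l, exps, coefs)

    def flush():
        nonlocal current
        if current is not None:
            el, l, exps, coefs = current
            if not exps:
                raise ValueError(f"empty shell for {el}")
            e = np.asarray(exps)
            c = np.asarray(coefs)
            if np.any(e <= 0):
                raise ValueError(f"non-positive exponent in {el} shell")
            shells.setdefault(el, []).append((l, e, c))
            current = None

    for raw in text.splitlines():
        line = raw.split("#")[0].strip()
        if not line or line.upper().startswith(("BASIS", "END")):
            continue
        parts = line.split()
        if re.match(r"^[A-Za-z]{1,2}$", parts[0]):
            flush()
            el = parts[0].capitalize()
            ltag = parts[1].upper()
            if ltag not in _L_LETTER:
                raise NotImplementedError(f"angular momentum {ltag} unsupported")
            current = (el, _L_LETTER[ltag], [], [])
        else:
            if current is None:
                raise ValueError(f"primitive line outside a shell: {line!r}")
            current[2].append(float(parts[0].replace("D", "E")))
            current[3].append(float(parts[1].replace("D", "E")))
    flush()
    return GaussianBasis(name=name, shells=shells)


def load_basis(name: str) -> GaussianBasis:
    """Load one of the vendored basis files (sto-3g, cc-pvdz, aug-cc-pvtz)."""
    from importlib.resources import files

    fname = name.lower() + ".nw"
    path = files("etspin.data").joinpath(fname)
    return parse_nwchem_basis(path.read_text(), name=name.lower())


# ---------------------------------------------------------------------------
# shell-array flattening
# ---------------------------------------------------------------------------


@dataclass
class ShellSet:
    """Flattened shell data for the numba kernels (coordinates in bohr)."""

    sh_l: np.ndarray
    sh_center: np.ndarray
    sh_poff: np.ndarray
    prim_exp: np.ndarray
    prim_coef: np.ndarray   # contraction coefficient x primitive norm
    sh_aoff: np.ndarray     # cartesian AO offsets
    n_cart_total: int
    c2s: np.ndarray         # (n_cart_total, n_sph_total)

    @property
    def n_sph_total(self) -> int:
        return self.c2s.shape[1]


def _primitive_norm(alpha: float, l: int) -> float:
    # normalizes the (l,0,0) Cartesian component
    dfac = 1.0
    for k in range(2 * l - 1, 0, -2):
        dfac *= k
    return (2 * alpha / math.pi) ** 0.75 * (4 * alpha) ** (l / 2) / math.sqrt(dfac)


def build_shells(
    symbols, coords_angstrom, basis: GaussianBasis, drop_d: bool = False
) -> ShellSet:
    coords = np.asarray(coords_angstrom, dtype=float) * ANGSTROM_TO_BOHR
    if drop_d:
        basis = basis.without_l_above(1)
    sh_l, centers, poffs, exps, coefs, aoffs = [], [], [0], [], [], []
    ncart_tot = 0
    blocks = []
    for sym, xyz in zip(symbols, coords):
        for l, e, c in basis.for_element(sym):
            if l > MAX_L:
                raise NotImplementedError(f"l={l} beyond supported maximum")
            sh_l.append(l)
            centers.append(xyz)
            exps.extend(e.tolist())
            coefs.extend((c * np.array([_primitive_norm(a, l) for a in e])).tolist())
            poffs.append(len(exps))
            aoffs.append(ncart_tot)
            ncart_tot += n_cart(l)
            blocks.append(_solid_harmonic_block(l))
    nsph_tot = sum(b.shape[1] for b in blocks)
    c2s = np.zeros((ncart_tot, nsph_tot))
    ic = isph = 0
    for b in blocks:
        c2s[ic : ic + b.shape[0], isph : isph + b.shape[1]] = b
        ic += b.shape[0]
        isph += b.shape[1]
    return ShellSet(
        sh_l=np.asarray(sh_l, dtype=np.int64),
        sh_center=np.asarray(centers, dtype=float).reshape(-1, 3),
        sh_poff=np.asarray(poffs, dtype=np.int64),
        prim_exp=np.asarray(exps, dtype=float),
        prim_coef=np.asarray(coefs, dtype=float),
        sh_aoff=np.asarray(aoffs, dtype=np.int64),
        n_cart_total=ncart_tot,
        c2s=c2s,
    )


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _boys(m_max, t, out):
    if t < 1e-13:
        for m in range(m_max + 1):
            out[m] = 1.0 / (2 * m + 1)
        return
    if t < 35.0:
        term = 1.0 / (2 * m_max + 1)
        s = term
        i = 1
        while i < 500:
            term *= 2.0 * t / (2 * m_max + 2 * i + 1)
            s += term
            if term < 1e-17 * s:
                break
            i += 1
        et = math.exp(-t)
        out[m_max] = et * s
        for m in range(m_max, 0, -1):
            out[m - 1] = (2.0 * t * out[m] + et) / (2 * m - 1)
    else:
        st = math.sqrt(t)
        out[0] = 0.5 * math.sqrt(math.pi / t) * math.erf(st)
        et = math.exp(-t)
        for m in range(m_max):
            out[m + 1] = ((2 * m + 1) * out[m] - et) / (2.0 * t)


@njit(cache=True)
def _e1d(l1, l2, a, b, qab, out):
    """Hermite expansion coefficients E_t^{ij} for one axis (includes the
    Gaussian-product prefactor exp(-mu qab²))."""
    p = a + b
    mu = a * b / p
    xpa = -b / p * qab
    xpb = a / p * qab
    for i in range(l1 + 1):
        for j in range(l2 + 1):
            for t in range(l1 + l2 + 1):
                out[i, j, t] = 0.0
    out[0, 0, 0] = math.exp(-mu * qab * qab)
    for i in range(l1 + 1):
        for j in range(l2 + 1):
            if i == 0 and j == 0:
                continue
            if j == 0:
                for t in range(i + j + 1):
                    v = xpa * out[i - 1, j, t]
                    if t > 0:
                        v += out[i - 1, j, t - 1] / (2.0 * p)
                    if t + 1 <= i + j - 1:
                        v += (t + 1) * out[i - 1, j, t + 1]
                    out[i, j, t] = v
            else:
                for t in range(i + j + 1):
                    v = xpb * out[i, j - 1, t]
                    if t > 0:
                        v += out[i, j - 1, t - 1] / (2.0 * p)
                    if t + 1 <= i + j - 1:
                        v += (t + 1) * out[i, j - 1, t + 1]
                    out[i, j, t] = v


@njit(cache=True)
def _r_tensor(L, pexp, x, y, z, rn, boysbuf):
    """Hermite Coulomb integrals R_{tuv} into rn[0]; rn shape (L+2,)*4 min."""
    t_arg = pexp * (x * x + y * y + z * z)
    _boys(L, t_arg, boysbuf)
    for n in range(L + 1):
        rn[n, 0, 0, 0] = (-2.0 * pexp) ** n * boysbuf[n]
    for s in range(1, L + 1):
        for n in range(L - s + 1):
            for t in range(s + 1):
                for u in range(s - t + 1):
                    v = s - t - u
                    if t > 0:
                        val = x * rn[n + 1, t - 1, u, v]
                        if t > 1:
                            val += (t - 1) * rn[n + 1, t - 2, u, v]
                    elif u > 0:
                        val = y * rn[n + 1, t, u - 1, v]
                        if u > 1:
                            val += (u - 1) * rn[n + 1, t, u - 2, v]
                    else:
                        val = z * rn[n + 1, t, u, v - 1]
                        if v > 1:
                            val += (v - 1) * rn[n + 1, t, u, v - 2]
                    rn[n, t, u, v] = val


@njit(cache=True)
def _one_electron_cart(
    sh_l, sh_center, sh_poff, prim_exp, prim_coef, sh_aoff,
    atom_z, atom_xyz, origin, clx, cly, clz, comp_off,
    s_mat, t_mat, v_mat, d_mat,
):
    ns = len(sh_l)
    n_atoms = len(atom_z)
    lm = MAX_L
    ex = np.zeros((lm + 1, lm + 3, 2 * lm + 3))
    ey = np.zeros((lm + 1, lm + 3, 2 * lm + 3))
    ez = np.zeros((lm + 1, lm + 3, 2 * lm + 3))
    rn = np.zeros((2 * lm + 2, 2 * lm + 2, 2 * lm + 2, 2 * lm + 2))
    boysbuf = np.zeros(2 * lm + 2)
    for si in range(ns):
        l1 = sh_l[si]
        nc1 = (l1 + 1) * (l1 + 2) // 2
        ax, ay, az = sh_center[si, 0], sh_center[si, 1], sh_center[si, 2]
        for sj in range(si + 1):
            l2 = sh_l[sj]
            nc2 = (l2 + 1) * (l2 + 2) // 2
            bx, by, bz = sh_center[sj, 0], sh_center[sj, 1], sh_center[sj, 2]
            sblk = np.zeros((nc1, nc2))
            tblk = np.zeros((nc1, nc2))
            vblk = np.zeros((nc1, nc2))
            dblk = np.zeros((3, nc1, nc2))
            for p1 in range(sh_poff[si], sh_poff[si + 1]):
                a = prim_exp[p1]
                for p2 in range(sh_poff[sj], sh_poff[sj + 1]):
                    b = prim_exp[p2]
                    w = prim_coef[p1] * prim_coef[p2]
                    p = a + b
                    _e1d(l1, l2 + 2, a, b, ax - bx, ex)
                    _e1d(l1, l2 + 2, a, b, ay - by, ey)
                    _e1d(l1, l2 + 2, a, b, az - bz, ez)
                    sq = math.sqrt(math.pi / p)
                    px = (a * ax + b * bx) / p
                    py = (a * ay + b * by) / p
                    pz = (a * az + b * bz) / p
                    for c1 in range(nc1):
                        lx1 = clx[comp_off[l1] + c1]
                        ly1 = cly[comp_off[l1] + c1]
                        lz1 = clz[comp_off[l1] + c1]
                        for c2 in range(nc2):
                            lx2 = clx[comp_off[l2] + c2]
                            ly2 = cly[comp_off[l2] + c2]
                            lz2 = clz[comp_off[l2] + c2]
                            sx = ex[lx1, lx2, 0] * sq
                            sy = ey[ly1, ly2, 0] * sq
                            sz = ez[lz1, lz2, 0] * sq
                            sblk[c1, c2] += w * sx * sy * sz
                            # kinetic via shifted-j overlaps
                            tx = 4.0 * b * b * ex[lx1, lx2 + 2, 0] * sq - 2.0 * b * (
                                2 * lx2 + 1
                            ) * sx
                            if lx2 >= 2:
                                tx += lx2 * (lx2 - 1) * ex[lx1, lx2 - 2, 0] * sq
                            ty = 4.0 * b * b * ey[ly1, ly2 + 2, 0] * sq - 2.0 * b * (
                                2 * ly2 + 1
                            ) * sy
                            if ly2 >= 2:
                                ty += ly2 * (ly2 - 1) * ey[ly1, ly2 - 2, 0] * sq
                            tz = 4.0 * b * b * ez[lz1, lz2 + 2, 0] * sq - 2.0 * b * (
                                2 * lz2 + 1
                            ) * sz
                            if lz2 >= 2:
                                tz += lz2 * (lz2 - 1) * ez[lz1, lz2 - 2, 0] * sq
                            tblk[c1, c2] += -0.5 * w * (
                                tx * sy * sz + sx * ty * sz + sx * sy * tz
                            )
                            # dipole about the gauge origin
                            dxm = (ex[lx1, lx2 + 1, 0] + (bx - origin[0]) * ex[lx1, lx2, 0]) * sq
                            dym = (ey[ly1, ly2 + 1, 0] + (by - origin[1]) * ey[ly1, ly2, 0]) * sq
                            dzm = (ez[lz1, lz2 + 1, 0] + (bz - origin[2]) * ez[lz1, lz2, 0]) * sq
                            dblk[0, c1, c2] += w * dxm * sy * sz
                            dblk[1, c1, c2] += w * sx * dym * sz
                            dblk[2, c1, c2] += w * sx * sy * dzm
                    # nuclear attraction
                    for ia in range(n_atoms):
                        lsum = l1 + l2
                        _r_tensor(
                            lsum, p,
                            px - atom_xyz[ia, 0], py - atom_xyz[ia, 1],
                            pz - atom_xyz[ia, 2], rn, boysbuf,
                        )
                        zfac = -atom_z[ia] * 2.0 * math.pi / p * w
                        for c1 in range(nc1):
                            lx1 = clx[comp_off[l1] + c1]
                            ly1 = cly[comp_off[l1] + c1]
                            lz1 = clz[comp_off[l1] + c1]
                            for c2 in range(nc2):
                                lx2 = clx[comp_off[l2] + c2]
                                ly2 = cly[comp_off[l2] + c2]
                                lz2 = clz[comp_off[l2] + c2]
                                acc = 0.0
                                for t in range(lx1 + lx2 + 1):
                                    e1 = ex[lx1, lx2, t]
                                    for u in range(ly1 + ly2 + 1):
                                        e12 = e1 * ey[ly1, ly2, u]
                                        for vv in range(lz1 + lz2 + 1):
                                            acc += e12 * ez[lz1, lz2, vv] * rn[0, t, u, vv]
                                vblk[c1, c2] += zfac * acc
            o1 = sh_aoff[si]
            o2 = sh_aoff[sj]
            for c1 in range(nc1):
                for c2 in range(nc2):
                    s_mat[o1 + c1, o2 + c2] = sblk[c1, c2]
                    s_mat[o2 + c2, o1 + c1] = sblk[c1, c2]
                    t_mat[o1 + c1, o2 + c2] = tblk[c1, c2]
                    t_mat[o2 + c2, o1 + c1] = tblk[c1, c2]
                    v_mat[o1 + c1, o2 + c2] = vblk[c1, c2]
                    v_mat[o2 + c2, o1 + c1] = vblk[c1, c2]
                    for k in range(3):
                        d_mat[k, o1 + c1, o2 + c2] = dblk[k, c1, c2]
                        d_mat[k, o2 + c2, o1 + c1] = dblk[k, c1, c2]


@njit(cache=True)
def _eri_cart(
    sh_l, sh_center, sh_poff, prim_exp, prim_coef, sh_aoff,
    clx, cly, clz, comp_off, out,
):
    ns = len(sh_l)
    lm = MAX_L
    e12x = np.zeros((lm + 1, lm + 1, 2 * lm + 1))
    e12y = np.zeros((lm + 1, lm + 1, 2 * lm + 1))
    e12z = np.zeros((lm + 1, lm + 1, 2 * lm + 1))
    e34x = np.zeros((lm + 1, lm + 1, 2 * lm + 1))
    e34y = np.zeros((lm + 1, lm + 1, 2 * lm + 1))
    e34z = np.zeros((lm + 1, lm + 1, 2 * lm + 1))
    lmax_tot = 4 * lm
    rn = np.zeros((lmax_tot + 2, lmax_tot + 1, lmax_tot + 1, lmax_tot + 1))
    boysbuf = np.zeros(lmax_tot + 2)
    ncmax = (lm + 1) * (lm + 2) // 2
    blk = np.zeros((ncmax, ncmax, ncmax, ncmax))
    two_pi_25 = 2.0 * math.pi ** 2.5

    for si in range(ns):
        l1 = sh_l[si]
        nc1 = (l1 + 1) * (l1 + 2) // 2
        for sj in range(si + 1):
            l2 = sh_l[sj]
            nc2 = (l2 + 1) * (l2 + 2) // 2
            pij = si * (si + 1) // 2 + sj
            abx = sh_center[si, 0] - sh_center[sj, 0]
            aby = sh_center[si, 1] - sh_center[sj, 1]
            abz = sh_center[si, 2] - sh_center[sj, 2]
            rab2 = abx * abx + aby * aby + abz * abz
            for sk in range(ns):
                l3 = sh_l[sk]
                nc3 = (l3 + 1) * (l3 + 2) // 2
                for sl in range(sk + 1):
                    if sk * (sk + 1) // 2 + sl > pij:
                        continue
                    l4 = sh_l[sl]
                    nc4 = (l4 + 1) * (l4 + 2) // 2
                    cdx = sh_center[sk, 0] - sh_center[sl, 0]
                    cdy = sh_center[sk, 1] - sh_center[sl, 1]
                    cdz = sh_center[sk, 2] - sh_center[sl, 2]
                    rcd2 = cdx * cdx + cdy * cdy + cdz * cdz
                    for a1 in range(nc1):
                        for a2 in range(nc2):
                            for a3 in range(nc3):
                                for a4 in range(nc4):
                                    blk[a1, a2, a3, a4] = 0.0
                    ltot = l1 + l2 + l3 + l4
                    for p1 in range(sh_poff[si], sh_poff[si + 1]):
                        a = prim_exp[p1]
                        for p2 in range(sh_poff[sj], sh_poff[sj + 1]):
                            b = prim_exp[p2]
                            p = a + b
                            kab = math.exp(-a * b / p * rab2)
                            for p3 in range(sh_poff[sk], sh_poff[sk + 1]):
                                c = prim_exp[p3]
                                for p4 in range(sh_poff[sl], sh_poff[sl + 1]):
                                    d = prim_exp[p4]
                                    q = c + d
                                    kcd = math.exp(-c * d / q * rcd2)
                                    if kab * kcd < _SCREEN:
                                        continue
                                    w = (
                                        prim_coef[p1] * prim_coef[p2]
                                        * prim_coef[p3] * prim_coef[p4]
                                    )
                                    _e1d(l1, l2, a, b, abx, e12x)
                                    _e1d(l1, l2, a, b, aby, e12y)
                                    _e1d(l1, l2, a, b, abz, e12z)
                                    _e1d(l3, l4, c, d, cdx, e34x)
                                    _e1d(l3, l4, c, d, cdy, e34y)
                                    _e1d(l3, l4, c, d, cdz, e34z)
                                    px = (a * sh_center[si, 0] + b * sh_center[sj, 0]) / p
                                    py = (a * sh_center[si, 1] + b * sh_center[sj, 1]) / p
                                    pz = (a * sh_center[si, 2] + b * sh_center[sj, 2]) / p
                                    qx = (c * sh_center[sk, 0] + d * sh_center[sl, 0]) / q
                                    qy = (c * sh_center[sk, 1] + d * sh_center[sl, 1]) / q
                                    qz = (c * sh_center[sk, 2] + d * sh_center[sl, 2]) / q
                                    alpha = p * q / (p + q)
                                    _r_tensor(
                                        ltot, alpha, px - qx, py - qy, pz - qz,
                                        rn, boysbuf,
                                    )
                                    pref = two_pi_25 / (p * q * math.sqrt(p + q)) * w
                                    for c1 in range(nc1):
                                        lx1 = clx[comp_off[l1] + c1]
                                        ly1 = cly[comp_off[l1] + c1]
                                        lz1 = clz[comp_off[l1] + c1]
                                        for c2 in range(nc2):
                                            lx2 = clx[comp_off[l2] + c2]
                                            ly2 = cly[comp_off[l2] + c2]
                                            lz2 = clz[comp_off[l2] + c2]
                                            for c3 in range(nc3):
                                                lx3 = clx[comp_off[l3] + c3]
                                                ly3 = cly[comp_off[l3] + c3]
                                                lz3 = clz[comp_off[l3] + c3]
                                                for c4 in range(nc4):
                                                    lx4 = clx[comp_off[l4] + c4]
                                                    ly4 = cly[comp_off[l4] + c4]
                                                    lz4 = clz[comp_off[l4] + c4]
                                                    acc = 0.0
                                                    for t in range(lx1 + lx2 + 1):
                                                        e1 = e12x[lx1, lx2, t]
                                                        if e1 == 0.0:
                                                            continue
                                                        for u in range(ly1 + ly2 + 1):
                                                            e2 = e1 * e12y[ly1, ly2, u]
                                                            for vv in range(lz1 + lz2 + 1):
                                                                e123 = e2 * e12z[lz1, lz2, vv]
                                                                for tau in range(lx3 + lx4 + 1):
                                                                    e4 = e34x[lx3, lx4, tau]
                                                                    if e4 == 0.0:
                                                                        continue
                                                                    sgn_t = -1.0 if (tau & 1) else 1.0
                                                                    for nu in range(ly3 + ly4 + 1):
                                                                        e45 = e4 * e34y[ly3, ly4, nu]
                                                                        sgn_u = -sgn_t if (nu & 1) else sgn_t
                                                                        for ph in range(lz3 + lz4 + 1):
                                                                            e456 = e45 * e34z[lz3, lz4, ph]
                                                                            sgn = -sgn_u if (ph & 1) else sgn_u
                                                                            acc += (
                                                                                e123 * e456 * sgn
                                                                                * rn[0, t + tau, u + nu, vv + ph]
                                                                            )
                                                    blk[c1, c2, c3, c4] += pref * acc
                    o1, o2, o3, o4 = sh_aoff[si], sh_aoff[sj], sh_aoff[sk], sh_aoff[sl]
                    for c1 in range(nc1):
                        for c2 in range(nc2):
                            for c3 in range(nc3):
                                for c4 in range(nc4):
                                    v = blk[c1, c2, c3, c4]
                                    i, j, k, l = o1 + c1, o2 + c2, o3 + c3, o4 + c4
                                    out[i, j, k, l] = v
                                    out[j, i, k, l] = v
                                    out[i, j, l, k] = v
                                    out[j, i, l, k] = v
                                    out[k, l, i, j] = v
                                    out[l, k, i, j] = v
                                    out[k, l, j, i] = v
                                    out[l, k, j, i] = v


# ---------------------------------------------------------------------------
# public assembly
# ---------------------------------------------------------------------------


@dataclass
class AOIntegrals:
    """Spherical, unit-normalized AO integrals plus nuclear terms (a.u.)."""

    overlap: np.ndarray
    kinetic: np.ndarray
    nuclear: np.ndarray
    dipole: np.ndarray       # (3, n, n) about gauge_origin
    eri: np.ndarray          # chemists' (ij|kl)
    e_nuc: float
    nuclear_dipole: np.ndarray
    gauge_origin: np.ndarray  # Å

    @property
    def n_orb(self) -> int:
        return self.overlap.shape[0]

    @property
    def core_hamiltonian(self) -> np.ndarray:
        return self.kinetic + self.nuclear


def nuclear_repulsion(charges, coords_angstrom) -> float:
    xyz = np.asarray(coords_angstrom, dtype=float) * ANGSTROM_TO_BOHR
    z = np.asarray(charges, dtype=float)
    e = 0.0
    for i in range(len(z)):
        for j in range(i):
            e += z[i] * z[j] / np.linalg.norm(xyz[i] - xyz[j])
    return e


def center_of_nuclear_charge(charges, coords_angstrom) -> np.ndarray:
    z = np.asarray(charges, dtype=float)
    xyz = np.asarray(coords_angstrom, dtype=float)
    return (z[:, None] * xyz).sum(axis=0) / z.sum()


def compute_integrals(
    symbols,
    coords_angstrom,
    basis: GaussianBasis,
    drop_d: bool = False,
    gauge_origin=None,
) -> AOIntegrals:
    """All AO integrals for a molecule; gauge origin defaults to the center
    of nuclear charge (sensible state dipoles for charged systems)."""
    charges = np.array([ELEMENT_Z[s] for s in symbols], dtype=float)
    coords = np.asarray(coords_angstrom, dtype=float)
    if gauge_origin is None:
        gauge_origin = center_of_nuclear_charge(charges, coords)
    gauge_origin = np.asarray(gauge_origin, dtype=float)

    shells = build_shells(symbols, coords, basis, drop_d=drop_d)
    nc = shells.n_cart_total
    s_c = np.zeros((nc, nc))
    t_c = np.zeros((nc, nc))
    v_c = np.zeros((nc, nc))
    d_c = np.zeros((3, nc, nc))
    atom_xyz = coords * ANGSTROM_TO_BOHR
    origin_bohr = gauge_origin * ANGSTROM_TO_BOHR
    _one_electron_cart(
        shells.sh_l, shells.sh_center, shells.sh_poff, shells.prim_exp,
        shells.prim_coef, shells.sh_aoff, charges, atom_xyz, origin_bohr,
        _CLX, _CLY, _CLZ, _COMP_OFF, s_c, t_c, v_c, d_c,
    )
    eri_c = np.zeros((nc, nc, nc, nc))
    _eri_cart(
        shells.sh_l, shells.sh_center, shells.sh_poff, shells.prim_exp,
        shells.prim_coef, shells.sh_aoff, _CLX, _CLY, _CLZ, _COMP_OFF, eri_c,
    )

    # spherical transform + exact renormalization to unit self-overlap
    m = shells.c2s
    s_sph = m.T @ s_c @ m
    f = 1.0 / np.sqrt(np.diag(s_sph))
    mf = m * f[None, :]
    s = mf.T @ s_c @ mf
    t = mf.T @ t_c @ mf
    v = mf.T @ v_c @ mf
    dip = np.einsum("pi,kpq,qj->kij", mf, d_c, mf, optimize=True)
    eri = np.einsum("pqrs,pi,qj,rk,sl->ijkl", eri_c, mf, mf, mf, mf, optimize=True)

    nuc_dip = ((charges[:, None]) * (atom_xyz - origin_bohr)).sum(axis=0)
    return AOIntegrals(
        overlap=s, kinetic=t, nuclear=v, dipole=dip, eri=eri,
        e_nuc=nuclear_repulsion(charges, coords),
        nuclear_dipole=nuc_dip, gauge_origin=gauge_origin,
    )


def lowdin_orthogonalization(s: np.ndarray, min_eig: float = 1e-9) -> np.ndarray:
    """Symmetric (Löwdin) orthogonalization X = S^{-1/2}."""
    w, u = np.linalg.eigh(s)
    if w.min() < min_eig:
        raise np.linalg.LinAlgError(
            f"AO overlap nearly singular: min eigenvalue {w.min():.3e}"
        )
    return (u / np.sqrt(w)) @ u.T


def mo_transform(eri: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Four-index transform of chemists'-notation integrals."""
    return np.einsum("pqrs,pi,qj,rk,sl->ijkl", eri, c, c, c, c, optimize=True)
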