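"""Shared fixtures and an independent second-quantization oracle.

The oracle builds Hamiltonian / S² / E_pq matrices by explicit fermionic
operator algebra on spin-orbital occupation vectors (Jordan–Wigner signs),
sharing no code with the package's Slater–Condon implementation.
Spin-orbital ordering: alpha block (0..n-1) then beta block (n..2n-1),
matching the package's determinant phase convention.
"""

from __future__ import annotations

import numpy as np
import pytest


def spinorb_bits(sa: int, sb: int, n: int) -> int:
    return (int(sa) & ((1 << n) - 1)) | (int(sb) << n)


def _apply_ops(ops, bits):
    """Apply [('c'|'a', spinorbital), ...] right-to-left; returns (sign, bits)
    or None if annihilated."""
    sign = 1
    for kind, p in reversed(ops):
        occ = (bits >> p) & 1
        if kind == "a":
            if not occ:
                return None
            sign *= -1 if bin(bits & ((1 << p) - 1)).count("1") % 2 else 1
            bits ^= 1 << p
        else:
            if occ:
                return None
            sign *= -1 if bin(bits & ((1 << p) - 1)).count("1") % 2 else 1
            bits |= 1 << p
    return sign, bits


def naive_operator_matrix(terms, dets, n_orb):
    """Matrix of Σ coef·(op string) over determinants given as (sa, sb)."""
    index = {spinorb_bits(sa, sb, n_orb): i for i, (sa, sb) in enumerate(dets)}
    nd = len(dets)
    out = np.zeros((nd, nd))
    for j, (sa, sb) in enumerate(dets):
        bits = spinorb_bits(sa, sb, n_orb)
        for coef, ops in terms:
            res = _apply_ops(ops, bits)
            if res is None:
                continue
            sign, newbits = res
            i = index.get(newbits)
            if i is not None:
                out[i, j] += coef * sign
    return out


def naive_hamiltonian(dets, h, g, e_core=0.0):
    """Dense H from h_pq Σσ a†pσ aqσ + ½ (pq|rs) Σστ a†pσ a†rτ asτ aqσ."""
    n = h.shape[0]
    terms = []
    for p in range(n):
        for q in range(n):
            if h[p, q] != 0.0:
                for s in (0, n):
                    terms.append((h[p, q], [("c", p + s), ("a", q + s)]))
    for p in range(n):
        for q in range(n):
            for r in range(n):
                for s_ in range(n):
                    v = g[p, q, r, s_]
                    if v == 0.0:
                        continue
                    for sp1 in (0, n):
                        for sp2 in (0, n):
                            terms.append(
                                (
                                    0.5 * v,
                                    [
                                        ("c", p + sp1),
                                        ("c", r + sp2),
                                        ("a", s_ + sp2),
                                        ("a", q + sp1),
                                    ],
                                )
                            )
    return naive_operator_matrix(terms, dets, n) + e_core * np.eye(len(dets))


def naive_s_squared(dets, n_orb):
    """Dense S² = S_-S_+ + S_z(S_z+1) over the determinant list."""
    terms = []
    for p in range(n_orb):
        for q in range(n_orb):
            # S_- S_+ = Σ_pq a†_{qβ} a_{qα} a†_{pα} a_{pβ}
            terms.append(
                (1.0, [("c", q + n_orb), ("a", q), ("c", p), ("a", p + n_orb)])
            )
    m = naive_operator_matrix(terms, dets, n_orb)
    nd = len(dets)
    for i, (sa, sb) in enumerate(dets):
        ms = 0.5 * (bin(int(sa)).count("1") - bin(int(sb)).count("1"))
        m[i, i] += ms * (ms + 1.0)
    return m


def naive_e_pq(dets, n_orb, p, q):
    """Dense spin-summed excitation operator E_pq."""
    terms = [(1.0, [("c", p), ("a", q)]), (1.0, [("c", p + n_orb), ("a", q + n_orb)])]
    return naive_operator_matrix(terms, dets, n_orb)


def random_integral_set(n, n_elec, ms2, seed, scale=0.2):
    from etspin.fcidump import IntegralSet

    rng = np.random.default_rng(seed)
    h = rng.normal(size=(n, n))
    h = 0.5 * (h + h.T)
    g = rng.normal(size=(n, n, n, n)) * scale
    g = g + g.transpose(1, 0, 2, 3)
    g = g + g.transpose(0, 1, 3, 2)
    g = g + g.transpose(2, 3, 0, 1)
    return IntegralSet(
        n_orb=n, n_elec=n_elec, ms2=ms2, e_core=rng.normal() * 0.1, h_one=h, g_two=g
    )


@pytest.fixture(scope="session")
def hubbard_half_filled():
    from etspin.fixtures import hubbard_dimer_fcidump

    return hubbard_dimer_fcidump(1.0, 4.0, n_elec=2, ms2=0)
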