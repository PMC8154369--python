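"""Slater–Condon rules over bit-string determinants.

Phase convention: a determinant is the product of alpha creation operators
(ascending orbital index) followed by beta creation operators (ascending).
Single-excitation phases are the parity of the number of occupied orbitals
strictly between the hole and the particle; same-spin doubles apply two
singles sequentially.  Because same-spin excitation operators are quadratic
in fermion operators, alpha and beta excitations carry no cross phase.

Two families of routines live here:

* string-driven sigma builds, diagonal, 1-RDMs and S² for full product
  spaces (numba-compiled; these carry the FCI cost), and
* pairwise matrix elements for arbitrary determinant lists (selected CI),
  plus a dense Hamiltonian builder.

Two-electron integrals are chemists' (ij|kl) throughout.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# bit utilities
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _popcount(x):
    x = x - ((x >> 1) & 0x5555555555555555)
    x = (x & 0x3333333333333333) + ((x >> 2) & 0x3333333333333333)
    x = (x + (x >> 4)) & 0x0F0F0F0F0F0F0F0F
    return (x * 0x0101010101010101) >> 56


def binom_table(n_orb: int) -> np.ndarray:
    t = np.zeros((n_orb + 1, n_orb + 1), dtype=np.int64)
    for i in range(n_orb + 1):
        t[i, 0] = 1
        for j in range(1, i + 1):
            t[i, j] = t[i - 1, j - 1] + t[i - 1, j]
    return t


@njit(cache=True)
def _rank(mask, binom):
    """Colexicographic rank of a string = index in ascending-bitmask order."""
    r = 0
    i = 0
    p = 0
    m = mask
    while m:
        if m & 1:
            i += 1
            r += binom[p, i]
        m >>= 1
        p += 1
    return r


@njit(cache=True, inline="always")
def _single_phase(s, i, a):
    """Parity sign for the excitation i->a on string s (i occupied, a empty)."""
    if i < a:
        mask = ((np.int64(1) << a) - 1) ^ ((np.int64(1) << (i + 1)) - 1)
    else:
        mask = ((np.int64(1) << i) - 1) ^ ((np.int64(1) << (a + 1)) - 1)
    return 1 if (_popcount(s & mask) & 1) == 0 else -1


def occ_table(strings: np.ndarray, k: int) -> np.ndarray:
    """(n_strings, k) table of occupied orbitals per string."""
    out = np.zeros((len(strings), k), dtype=np.int32)
    for idx, s in enumerate(strings):
        s = int(s)
        j = 0
        p = 0
        while s:
            if s & 1:
                out[idx, j] = p
                j += 1
            s >>= 1
            p += 1
    return out


# ---------------------------------------------------------------------------
# product-space kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _hdiag_product(stra, strb, occa, occb, h, g):
    na, ka = occa.shape
    nb, kb = occb.shape
    n = h.shape[0]
    ea = np.zeros(na)
    va = np.zeros((na, n))  # va[Ia, q] = sum_{i in occa} (ii|qq)
    for ia in range(na):
        e = 0.0
        for x in range(ka):
            i = occa[ia, x]
            e += h[i, i]
            for q in range(n):
                va[ia, q] += g[i, i, q, q]
            for y in range(x + 1, ka):
                j = occa[ia, y]
                e += g[i, i, j, j] - g[i, j, j, i]
        ea[ia] = e
    eb = np.zeros(nb)
    for ib in range(nb):
        e = 0.0
        for x in range(kb):
            i = occb[ib, x]
            e += h[i, i]
            for y in range(x + 1, kb):
                j = occb[ib, y]
                e += g[i, i, j, j] - g[i, j, j, i]
        eb[ib] = e
    out = np.empty((na, nb))
    for ia in range(na):
        for ib in range(nb):
            cross = 0.0
            for y in range(kb):
                cross += va[ia, occb[ib, y]]
            out[ia, ib] = ea[ia] + eb[ib] + cross
    return out


@njit(cache=True, inline="always")
def _rank_occ(tmp, k, binom):
    r = 0
    for m in range(k):
        r += binom[tmp[m], m + 1]
    return r


@njit(cache=True, inline="always")
def _occ_replace(occ_row, k, hole1, part1, hole2, part2, tmp):
    """Sorted occupied list with hole1→part1 (and optionally hole2→part2;
    pass hole2 = -1 to skip).  tmp must hold k entries."""
    m = 0
    for x in range(k):
        p = occ_row[x]
        if p != hole1 and p != hole2:
            tmp[m] = p
            m += 1
    tmp[m] = part1
    m += 1
    if hole2 >= 0:
        tmp[m] = part2
        m += 1
    # insertion sort (k is tiny)
    for x in range(1, m):
        key = tmp[x]
        y = x - 1
        while y >= 0 and tmp[y] > key:
            tmp[y + 1] = tmp[y]
            y -= 1
        tmp[y + 1] = key


@njit(cache=True)
def _sigma_same_spin(C, sigma, strings, occ, n_orb, h, g, gx, binom):
    """Singles + same-spin doubles for the row spin; columns are spectators.

    gx is g.transpose(0,2,1,3) (contiguous), so the antisymmetrized double
    element (ia|jb) − (ib|ja) reads from one cache-resident (a,b) tile per
    hole pair.  Only the within-spin part of the single-excitation element
    enters here; cross-spin Coulomb terms live in the cross kernels.
    """
    nstr, k = occ.shape
    ncol = C.shape[1]
    one = np.int64(1)
    vir = np.empty(n_orb, dtype=np.int32)
    tmp = np.empty(k + 2, dtype=np.int64)
    for idx in range(nstr):
        s = strings[idx]
        nv = 0
        for p in range(n_orb):
            if not (s >> p) & 1:
                vir[nv] = p
                nv += 1
        # --- singles
        for x in range(k):
            i = occ[idx, x]
            for v in range(nv):
                a = vir[v]
                sgn = _single_phase(s, i, a)
                _occ_replace(occ[idx], k, i, a, -1, -1, tmp)
                jdx = _rank_occ(tmp, k, binom)
                base = h[i, a]
                for y in range(k):
                    j = occ[idx, y]
                    if j != i:
                        base += g[i, a, j, j] - g[i, j, j, a]
                val = sgn * base
                for col in range(ncol):
                    sigma[jdx, col] += val * C[idx, col]
        # --- same-spin doubles
        for x in range(k):
            i = occ[idx, x]
            for y in range(x + 1, k):
                j = occ[idx, y]
                tile = gx[i, j]
                for v in range(nv):
                    a = vir[v]
                    sgn1 = _single_phase(s, i, a)
                    s1 = (s ^ (one << i)) | (one << a)
                    tile_a = tile[a]
                    for w in range(v + 1, nv):
                        b = vir[w]
                        sgn2 = _single_phase(s1, j, b)
                        _occ_replace(occ[idx], k, i, a, j, b, tmp)
                        jdx = _rank_occ(tmp, k, binom)
                        val = sgn1 * sgn2 * (tile_a[b] - tile[b, a])
                        if ncol == 1:
                            sigma[jdx, 0] += val * C[idx, 0]
                        else:
                            for col in range(ncol):
                                sigma[jdx, col] += val * C[idx, col]


@njit(cache=True)
def _sigma_cross_1beta(C, sigma, stra, occa, n_orb, g, binom):
    """Cross-spin terms for exactly one beta electron (string index = orbital).

    For every alpha excitation E_ia (genuine singles *and* diagonals) the
    beta side is a full matrix-vector product with g[i,a]:

        σ[Ja, l] += sign · Σ_m (ia|lm) C[Ia, m]

    which covers opposite-spin doubles, the beta-Coulomb part of alpha
    singles (m = l term), and the alpha-Coulomb part of beta singles
    (i = a entries).  The doubly diagonal Coulomb piece Σ_i (ii|mm) is
    already in the Hamiltonian diagonal and is subtracted at the end.
    """
    na, ka = occa.shape
    one = np.int64(1)
    vir = np.empty(n_orb, dtype=np.int32)
    for ia in range(na):
        s = stra[ia]
        nv = 0
        for p in range(n_orb):
            if not (s >> p) & 1:
                vir[nv] = p
                nv += 1
        for x in range(ka):
            i = occa[ia, x]
            # diagonal alpha operator E_ii
            gii = g[i, i]
            for m in range(n_orb):
                c = C[ia, m]
                if c != 0.0:
                    row = gii[m]
                    for l in range(n_orb):
                        sigma[ia, l] += row[l] * c
            # genuine alpha singles
            for v in range(nv):
                a = vir[v]
                sgn = _single_phase(s, i, a)
                s1 = (s ^ (one << i)) | (one << a)
                ja = _rank(s1, binom)
                gia = g[i, a]
                for m in range(n_orb):
                    c = sgn * C[ia, m]
                    if c != 0.0:
                        row = gia[m]
                        for l in range(n_orb):
                            sigma[ja, l] += row[l] * c
        # remove the doubly diagonal Coulomb term (already in hdiag)
        for m in range(n_orb):
            w = 0.0
            for x in range(ka):
                i = occa[ia, x]
                w += g[i, i, m, m]
            sigma[ia, m] -= w * C[ia, m]


@njit(cache=True)
def _sigma_cross_general(
    C, sigma, stra, occa, occb, n_orb, bs_off, bs_p, bs_q, bs_sign, bs_target, g, binom
):
    """Cross-spin terms for general electron counts.

    The beta table must include diagonal entries (p=q over occupied, sign
    +1, target = source); alpha diagonals are generated in the kernel and
    the doubly diagonal Coulomb piece is subtracted afterwards.
    """
    na, ka = occa.shape
    nb, kb = occb.shape
    one = np.int64(1)
    vir = np.empty(n_orb, dtype=np.int32)
    for ia in range(na):
        s = stra[ia]
        nv = 0
        for p in range(n_orb):
            if not (s >> p) & 1:
                vir[nv] = p
                nv += 1
        for x in range(ka):
            i = occa[ia, x]
            gii = g[i, i]
            for ib in range(nb):
                c = C[ia, ib]
                if c == 0.0:
                    continue
                for t in range(bs_off[ib], bs_off[ib + 1]):
                    sigma[ia, bs_target[t]] += bs_sign[t] * gii[bs_p[t], bs_q[t]] * c
            for v in range(nv):
                a = vir[v]
                sgn_a = _single_phase(s, i, a)
                s1 = (s ^ (one << i)) | (one << a)
                ja = _rank(s1, binom)
                gia = g[i, a]
                for ib in range(nb):
                    c = sgn_a * C[ia, ib]
                    if c == 0.0:
                        continue
                    for t in range(bs_off[ib], bs_off[ib + 1]):
                        sigma[ja, bs_target[t]] += (
                            bs_sign[t] * gia[bs_p[t], bs_q[t]] * c
                        )
        for ib in range(nb):
            w = 0.0
            for x in range(ka):
                i = occa[ia, x]
                for y in range(kb):
                    j = occb[ib, y]
                    w += g[i, i, j, j]
            sigma[ia, ib] -= w * C[ia, ib]


def beta_singles_table(
    strings: np.ndarray, occ: np.ndarray, n_orb: int, binom, include_diagonal=True
):
    """Flattened singles table (hole, particle, sign, target index); with
    ``include_diagonal`` the occupied p=q entries are appended (sign +1)."""
    offs = [0]
    hp, pp, sg, tg = [], [], [], []
    for idx, s in enumerate(strings):
        s = int(s)
        occs = [p for p in range(n_orb) if (s >> p) & 1]
        virs = [p for p in range(n_orb) if not (s >> p) & 1]
        for i in occs:
            if include_diagonal:
                hp.append(i)
                pp.append(i)
                sg.append(1)
                tg.append(idx)
            for a in virs:
                hp.append(i)
                pp.append(a)
                sg.append(_py_single_phase(s, i, a))
                tg.append(int(_rank(np.int64((s ^ (1 << i)) | (1 << a)), binom)))
        offs.append(len(hp))
    return (
        np.asarray(offs, dtype=np.int64),
        np.asarray(hp, dtype=np.int32),
        np.asarray(pp, dtype=np.int32),
        np.asarray(sg, dtype=np.int8),
        np.asarray(tg, dtype=np.int64),
    )


@njit(cache=True)
def _trdm_half(Cb, Ck, strings, occ, n_orb, binom, out):
    """Accumulate the row-spin part of <bra|E_pq|ket> into out[p,q]."""
    nstr, k = occ.shape
    ncol = Cb.shape[1]
    one = np.int64(1)
    for idx in range(nstr):
        s = strings[idx]
        for x in range(k):
            q = occ[idx, x]
            acc = 0.0
            for col in range(ncol):
                acc += Cb[idx, col] * Ck[idx, col]
            out[q, q] += acc
            for p in range(n_orb):
                if (s >> p) & 1:
                    continue
                sgn = _single_phase(s, q, p)
                s1 = (s ^ (one << q)) | (one << p)
                jdx = _rank(s1, binom)
                acc = 0.0
                for col in range(ncol):
                    acc += Cb[jdx, col] * Ck[idx, col]
                out[p, q] += sgn * acc


@njit(cache=True)
def _s2_product(C, stra, strb, n_alpha, n_beta, n_orb, binom):
    """<C|S²|C> via S² = S_z(S_z+1) + S_-S_+ with explicit fermion phases."""
    na, nb = C.shape
    one = np.int64(1)
    acc = 0.0
    for ia in range(na):
        sa = stra[ia]
        for ib in range(nb):
            c = C[ia, ib]
            if c == 0.0:
                continue
            sb = strb[ib]
            for p in range(n_orb):
                if not (sb >> p) & 1 or (sa >> p) & 1:
                    continue
                # a+_{p alpha} a_{p beta}
                below = (one << p) - 1
                n1 = n_alpha + _popcount(sb & below) + _popcount(sa & below)
                sgn1 = 1 if (n1 & 1) == 0 else -1
                sa1 = sa | (one << p)
                sb1 = sb ^ (one << p)
                for q in range(n_orb):
                    if not (sa1 >> q) & 1 or (sb1 >> q) & 1:
                        continue
                    belowq = (one << q) - 1
                    n2 = (
                        _popcount(sa1 & belowq)
                        + (n_alpha + 1 - 1)
                        + _popcount(sb1 & belowq)
                    )
                    sgn2 = 1 if (n2 & 1) == 0 else -1
                    sa2 = sa1 ^ (one << q)
                    sb2 = sb1 | (one << q)
                    acc += (
                        sgn1
                        * sgn2
                        * c
                        * C[_rank(sa2, binom), _rank(sb2, binom)]
                    )
    ms = 0.5 * (n_alpha - n_beta)
    return ms * (ms + 1.0) + acc


def _py_single_phase(s: int, i: int, a: int) -> int:
    lo, hi = (i, a) if i < a else (a, i)
    mask = ((1 << hi) - 1) ^ ((1 << (lo + 1)) - 1)
    return 1 if bin(s & mask).count("1") % 2 == 0 else -1


@njit(cache=True)
def _sparse_h_same_spin(strings, occ, n_orb, h, g, gx, e_core, binom, cols, vals):
    """CSR data for a pure same-spin sector (no opposite-spin electrons).

    Every row has the same count: 1 diagonal + k(n−k) singles +
    C(k,2)·C(n−k,2) doubles; rows are filled in that fixed order so the
    CSR index pointer is uniform (row_nnz is returned).
    """
    nstr, k = occ.shape
    one = np.int64(1)
    vir = np.empty(n_orb, dtype=np.int32)
    tmp = np.empty(k + 2, dtype=np.int64)
    nv_tot = n_orb - k
    row_nnz = 1 + k * nv_tot + (k * (k - 1) // 2) * (nv_tot * (nv_tot - 1) // 2)
    for idx in range(nstr):
        s = strings[idx]
        pos = idx * row_nnz
        nv = 0
        for p in range(n_orb):
            if not (s >> p) & 1:
                vir[nv] = p
                nv += 1
        # diagonal
        e = e_core
        for x in range(k):
            i = occ[idx, x]
            e += h[i, i]
            for y in range(x + 1, k):
                j = occ[idx, y]
                e += g[i, i, j, j] - g[i, j, j, i]
        cols[pos] = idx
        vals[pos] = e
        pos += 1
        # singles
        for x in range(k):
            i = occ[idx, x]
            for v in range(nv):
                a = vir[v]
                sgn = _single_phase(s, i, a)
                _occ_replace(occ[idx], k, i, a, -1, -1, tmp)
                base = h[i, a]
                for y in range(k):
                    j = occ[idx, y]
                    if j != i:
                        base += g[i, a, j, j] - g[i, j, j, a]
                cols[pos] = _rank_occ(tmp, k, binom)
                vals[pos] = sgn * base
                pos += 1
        # doubles
        for x in range(k):
            i = occ[idx, x]
            for y in range(x + 1, k):
                j = occ[idx, y]
                tile = gx[i, j]
                for v in range(nv):
                    a = vir[v]
                    sgn1 = _single_phase(s, i, a)
                    s1 = (s ^ (one << i)) | (one << a)
                    tile_a = tile[a]
                    for w in range(v + 1, nv):
                        b = vir[w]
                        sgn2 = _single_phase(s1, j, b)
                        _occ_replace(occ[idx], k, i, a, j, b, tmp)
                        cols[pos] = _rank_occ(tmp, k, binom)
                        vals[pos] = sgn1 * sgn2 * (tile_a[b] - tile[b, a])
                        pos += 1
    return row_nnz


# ---------------------------------------------------------------------------
# pairwise matrix elements (arbitrary determinant lists)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _bits_of_diff(x, n_orb, out):
    m = 0
    for p in range(n_orb):
        if (x >> p) & 1:
            out[m] = p
            m += 1
    return m


@njit(cache=True)
def _sc_element(sa1, sb1, sa2, sb2, n_orb, h, g):
    """<D1|H|D2> for determinants given as (alpha, beta) strings."""
    da = _popcount(sa1 ^ sa2) // 2
    db = _popcount(sb1 ^ sb2) // 2
    deg = da + db
    if deg > 2:
        return 0.0
    one = np.int64(1)
    buf = np.empty(4, dtype=np.int64)

    if deg == 0:
        e = 0.0
        for i in range(n_orb):
            oa = (sa2 >> i) & 1
            ob = (sb2 >> i) & 1
            if not (oa or ob):
                continue
            if oa:
                e += h[i, i]
            if ob:
                e += h[i, i]
            for j in range(n_orb):
                ja = (sa2 >> j) & 1
                jb = (sb2 >> j) & 1
                if oa and ja:
                    e += 0.5 * (g[i, i, j, j] - g[i, j, j, i])
                if ob and jb:
                    e += 0.5 * (g[i, i, j, j] - g[i, j, j, i])
                if oa and jb:
                    e += 0.5 * g[i, i, j, j]
                if ob and ja:
                    e += 0.5 * g[i, i, j, j]
        return e

    if deg == 1:
        if da == 1:
            s_same, s_same_bra, s_cross = sa2, sa1, sb2
        else:
            s_same, s_same_bra, s_cross = sb2, sb1, sa2
        _bits_of_diff(s_same & ~s_same_bra, n_orb, buf)
        i = buf[0]
        _bits_of_diff(s_same_bra & ~s_same, n_orb, buf)
        a = buf[0]
        sgn = _single_phase(s_same, i, a)
        val = h[i, a]
        for k in range(n_orb):
            if (s_same >> k) & 1 and k != i:
                val += g[i, a, k, k] - g[i, k, k, a]
            if (s_cross >> k) & 1:
                val += g[i, a, k, k]
        return sgn * val

    # deg == 2
    if da == 2 or db == 2:
        s2_, s1_ = (sa2, sa1) if da == 2 else (sb2, sb1)
        nh = _bits_of_diff(s2_ & ~s1_, n_orb, buf)
        i, j = buf[0], buf[1]
        _bits_of_diff(s1_ & ~s2_, n_orb, buf)
        a, b = buf[0], buf[1]
        sgn1 = _single_phase(s2_, i, a)
        sm = (s2_ ^ (one << i)) | (one << a)
        sgn2 = _single_phase(sm, j, b)
        _ = nh
        return sgn1 * sgn2 * (g[i, a, j, b] - g[i, b, j, a])

    # one alpha + one beta single
    _bits_of_diff(sa2 & ~sa1, n_orb, buf)
    i = buf[0]
    _bits_of_diff(sa1 & ~sa2, n_orb, buf)
    a = buf[0]
    _bits_of_diff(sb2 & ~sb1, n_orb, buf)
    j = buf[0]
    _bits_of_diff(sb1 & ~sb2, n_orb, buf)
    b = buf[0]
    sgn = _single_phase(sa2, i, a) * _single_phase(sb2, j, b)
    return sgn * g[i, a, j, b]


@njit(cache=True)
def _dense_h_list(dets, n_orb, h, g, e_core):
    nd = dets.shape[0]
    out = np.empty((nd, nd))
    for p in range(nd):
        for q in range(p, nd):
            v = _sc_element(dets[p, 0], dets[p, 1], dets[q, 0], dets[q, 1], n_orb, h, g)
            out[p, q] = v
            out[q, p] = v
        out[p, p] += e_core
    return out
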