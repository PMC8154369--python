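"""CI eigensolvers: dense diagonalization and block Davidson iteration.

Full product spaces use string-driven sigma builds (see :mod:`.slater`);
general determinant lists (selected CI) go through a dense pairwise
Hamiltonian.  Davidson starts from unit vectors on the lowest diagonal
elements and converges on residual norms, so CI vectors are reproducible
bit-for-bit for a fixed determinant ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import slater
from .cispace import CISpace, occ_list
from .fcidump import IntegralSet

DENSE_CUTOFF = 1200
_DAVIDSON_TOL = 1e-8


@dataclass
class CIState:
    """One CI eigenstate: energy (hartree), normalized coefficients over the
    space's determinant list, spin expectation ⟨S²⟩, and solver residual."""

    energy: float
    coefficients: np.ndarray
    space: CISpace
    s_squared: float
    residual_norm: float = 0.0

    @property
    def spin_pure(self) -> bool:
        """True if ⟨S²⟩ is within 1e-6 of S(S+1) for some (half-)integer S."""
        s_est = 0.5 * (np.sqrt(1.0 + 4.0 * max(self.s_squared, 0.0)) - 1.0)
        s = round(2 * s_est) / 2
        return abs(self.s_squared - s * (s + 1)) < 1e-6


class ProductSpaceEngine:
    """Cached string tables + sigma/diagonal/RDM builds for one product space."""

    def __init__(self, ints: IntegralSet, space: CISpace):
        if not space.is_product:
            raise ValueError("ProductSpaceEngine requires a full product space")
        if ints.n_orb != space.n_orb:
            raise ValueError("integral/space orbital dimension mismatch")
        self.ints = ints
        self.space = space
        self.n = space.n_orb
        self.stra = np.ascontiguousarray(space.strings_a)
        self.strb = np.ascontiguousarray(space.strings_b)
        self.occa = slater.occ_table(self.stra, space.n_alpha)
        self.occb = slater.occ_table(self.strb, space.n_beta)
        self.binom = slater.binom_table(self.n)
        self.h = np.ascontiguousarray(ints.h_one)
        self.g = np.ascontiguousarray(ints.g_two)
        # (ia|jb) reordered to [i,j,a,b] for cache-resident double-excitation tiles
        self.gx = np.ascontiguousarray(ints.g_two.transpose(0, 2, 1, 3))
        self.shape = (len(self.stra), len(self.strb))
        self._hdiag = None
        self._bs = None  # beta-singles table, built lazily for the general path
        self._sparse = None

    @property
    def bs(self):
        if self._bs is None:
            self._bs = slater.beta_singles_table(
                self.strb, self.occb, self.n, self.binom, include_diagonal=True
            )
        return self._bs

    def hdiag(self) -> np.ndarray:
        if self._hdiag is None:
            d = slater._hdiag_product(
                self.stra, self.strb, self.occa, self.occb, self.h, self.g
            )
            self._hdiag = d + self.ints.e_core
        return self._hdiag

    # pure same-spin sectors up to this many stored elements use an explicit
    # sparse Hamiltonian: one enumeration pass, then cheap matvecs
    SPARSE_NNZ_LIMIT = 150_000_000

    def _sparse_h(self):
        if self._sparse is None:
            import scipy.sparse as sps

            nstr, k = self.occa.shape
            nv = self.n - k
            row_nnz = 1 + k * nv + (k * (k - 1) // 2) * (nv * (nv - 1) // 2)
            cols = np.empty(nstr * row_nnz, dtype=np.int32)
            vals = np.empty(nstr * row_nnz, dtype=np.float64)
            slater._sparse_h_same_spin(
                self.stra, self.occa, self.n, self.h, self.g, self.gx,
                self.ints.e_core, self.binom, cols, vals,
            )
            indptr = np.arange(nstr + 1, dtype=np.int64) * row_nnz
            self._sparse = sps.csr_matrix(
                (vals, cols, indptr), shape=(nstr, nstr)
            )
        return self._sparse

    def _use_sparse(self) -> bool:
        if self.space.n_beta != 0 or self.space.n_alpha == 0:
            return False
        nstr, k = self.occa.shape
        nv = self.n - k
        row_nnz = 1 + k * nv + (k * (k - 1) // 2) * (nv * (nv - 1) // 2)
        return nstr * row_nnz <= self.SPARSE_NNZ_LIMIT and nstr > DENSE_CUTOFF

    def sigma(self, c: np.ndarray) -> np.ndarray:
        """H·c; the string kernels carry only off-diagonal couplings, the
        diagonal (including e_core) enters through hdiag."""
        na, nb = self.space.n_alpha, self.space.n_beta
        if self._use_sparse():
            return (self._sparse_h() @ c.ravel()).reshape(self.shape)
        c = np.ascontiguousarray(c.reshape(self.shape))
        out = self.hdiag() * c
        if na >= 1:
            slater._sigma_same_spin(
                c, out, self.stra, self.occa, self.n, self.h, self.g, self.gx,
                self.binom,
            )
        if nb >= 1:
            ct = np.ascontiguousarray(c.T)
            out_t = np.zeros_like(ct)
            slater._sigma_same_spin(
                ct, out_t, self.strb, self.occb, self.n, self.h, self.g, self.gx,
                self.binom,
            )
            out += out_t.T
        if na >= 1 and nb >= 1:
            if nb == 1:
                slater._sigma_cross_1beta(
                    c, out, self.stra, self.occa, self.n, self.g, self.binom
                )
            elif na == 1:
                ct = np.ascontiguousarray(c.T)
                out_t = np.zeros_like(ct)
                slater._sigma_cross_1beta(
                    ct, out_t, self.strb, self.occb, self.n, self.g, self.binom
                )
                out += out_t.T
            else:
                slater._sigma_cross_general(
                    c, out, self.stra, self.occa, self.occb, self.n, *self.bs,
                    self.g, self.binom,
                )
        return out

    def s_squared(self, c: np.ndarray) -> float:
        c = np.ascontiguousarray(c.reshape(self.shape))
        return float(
            slater._s2_product(
                c, self.stra, self.strb, self.space.n_alpha, self.space.n_beta,
                self.n, self.binom,
            )
        )

    def transition_rdm(self, c_bra: np.ndarray, c_ket: np.ndarray) -> np.ndarray:
        cb = np.ascontiguousarray(c_bra.reshape(self.shape))
        ck = np.ascontiguousarray(c_ket.reshape(self.shape))
        out = np.zeros((self.n, self.n))
        slater._trdm_half(cb, ck, self.stra, self.occa, self.n, self.binom, out)
        out_b = np.zeros((self.n, self.n))
        slater._trdm_half(
            np.ascontiguousarray(cb.T), np.ascontiguousarray(ck.T),
            self.strb, self.occb, self.n, self.binom, out_b,
        )
        return out + out_b


def davidson(
    sigma_fn,
    hdiag: np.ndarray,
    n_roots: int,
    tol: float = _DAVIDSON_TOL,
    max_iter: int = 300,
    max_subspace: int = 30,
):
    """Block Davidson for the lowest ``n_roots`` eigenpairs.

    ``sigma_fn`` maps a flat vector to H·v; start vectors are unit vectors
    on the lowest diagonal entries (stable argsort → deterministic).
    Returns (eigenvalues, eigenvectors (n,k), residual norms, iterations).
    """
    n = len(hdiag)
    if n_roots > n:
        raise ValueError(f"n_roots={n_roots} exceeds dimension {n}")
    # one guard root protects against converging onto a higher eigenpair
    # when the start block happens to overlap it more strongly
    n_block = min(n_roots + 1, n)
    max_subspace = min(max(max_subspace, 8 * n_block), n)
    order = np.argsort(hdiag, kind="stable")
    v_list = []
    for k in range(min(2 * n_block, n)):
        e = np.zeros(n)
        e[order[k]] = 1.0
        v_list.append(e)
    V = np.column_stack(v_list)
    W = np.column_stack([sigma_fn(V[:, k]) for k in range(V.shape[1])])
    n_sigma = V.shape[1]

    for it in range(max_iter):
        G = V.T @ W
        G = 0.5 * (G + G.T)
        theta_full, y_full = np.linalg.eigh(G)
        theta, y = theta_full[:n_block], y_full[:, :n_block]
        X = V @ y
        R = W @ y - X * theta
        rnorms = np.linalg.norm(R, axis=0)
        if np.all(rnorms[:n_roots] < tol):
            return theta[:n_roots], X[:, :n_roots], rnorms[:n_roots], it

        new_vecs = []
        for k in range(n_block):
            if rnorms[k] < tol:
                continue
            denom = theta[k] - hdiag
            denom = np.where(np.abs(denom) < 1e-10, 1e-10, denom)
            t = R[:, k] / denom
            for _ in range(2):  # twice-is-enough Gram-Schmidt
                t -= V @ (V.T @ t)
                for nv in new_vecs:
                    t -= nv * (nv @ t)
            nrm = np.linalg.norm(t)
            if nrm > 1e-8:
                new_vecs.append(t / nrm)
        if not new_vecs:
            # residuals stalled at preconditioner level; accept if close
            if np.all(rnorms[:n_roots] < 100 * tol):
                return theta[:n_roots], X[:, :n_roots], rnorms[:n_roots], it
            raise RuntimeError(
                f"Davidson stagnated at iteration {it}: residuals {rnorms}"
            )

        if V.shape[1] + len(new_vecs) > max_subspace:
            # thick restart: keep twice the block of lowest Ritz vectors
            keep = min(2 * n_block, y_full.shape[1])
            V, _ = np.linalg.qr(V @ y_full[:, :keep])
            W = np.column_stack([sigma_fn(V[:, k]) for k in range(V.shape[1])])
            n_sigma += V.shape[1]
        T = np.column_stack(new_vecs)
        V = np.column_stack([V, T])
        W = np.column_stack([W, *(sigma_fn(T[:, k]) for k in range(T.shape[1]))])
        n_sigma += T.shape[1]

    raise RuntimeError(
        f"Davidson failed to converge in {max_iter} iterations; "
        f"{n_sigma} sigma builds, residuals {rnorms}"
    )


def dense_hamiltonian(ints: IntegralSet, space: CISpace) -> np.ndarray:
    """Full Hamiltonian matrix over the space's determinant list."""
    return slater._dense_h_list(
        space.dets, space.n_orb, np.ascontiguousarray(ints.h_one),
        np.ascontiguousarray(ints.g_two), ints.e_core,
    )


def solve_ci(
    ints: IntegralSet,
    space: CISpace,
    n_states: int = 1,
    method: str = "auto",
    tol: float = _DAVIDSON_TOL,
) -> list[CIState]:
    """Lowest eigenstates of the Hamiltonian in the given determinant space.

    ``method``: "dense", "davidson", or "auto" (Davidson for product spaces
    above :data:`DENSE_CUTOFF` determinants, dense otherwise).
    """
    if n_states < 1 or n_states > space.size:
        raise ValueError(
            f"n_states={n_states} outside 1..{space.size} (space dimension)"
        )
    if ints.n_orb != space.n_orb:
        raise ValueError("integral set and CI space have different orbital counts")
    if (ints.n_elec != space.n_alpha + space.n_beta) or (
        ints.ms2 != space.ms2
    ):
        raise ValueError(
            "electron count / ms2 of the integral set does not match the space"
        )

    if method == "auto":
        method = (
            "davidson" if (space.is_product and space.size > DENSE_CUTOFF) else "dense"
        )

    if method == "davidson":
        if not space.is_product:
            raise NotImplementedError("Davidson is implemented for product spaces")
        eng = ProductSpaceEngine(ints, space)
        hd = eng.hdiag().ravel()
        evals, evecs, rnorms, _ = davidson(
            lambda v: eng.sigma(v).ravel(), hd, n_states, tol=tol
        )
        states = [
            CIState(
                energy=float(evals[k]),
                coefficients=evecs[:, k].copy(),
                space=space,
                s_squared=eng.s_squared(evecs[:, k]),
                residual_norm=float(rnorms[k]),
            )
            for k in range(n_states)
        ]
    elif method == "dense":
        if space.size > 20000:
            raise MemoryError(
                f"dense diagonalization refused for dimension {space.size}"
            )
        hmat = dense_hamiltonian(ints, space)
        evals, evecs = np.linalg.eigh(hmat)
        states = [
            CIState(
                energy=float(evals[k]),
                coefficients=evecs[:, k].copy(),
                space=space,
                s_squared=s_squared_list(space, evecs[:, k])
                if not space.is_product
                else ProductSpaceEngine(ints, space).s_squared(evecs[:, k]),
                residual_norm=0.0,
            )
            for k in range(n_states)
        ]
    else:
        raise ValueError(f"unknown method {method!r}")
    return states


# ---------------------------------------------------------------------------
# determinant-list fallbacks (selected CI spaces are desk-scale)
# ---------------------------------------------------------------------------


def _sp_phase(s: int, i: int, a: int) -> int:
    return slater._py_single_phase(s, i, a)


def s_squared_list(space: CISpace, c: np.ndarray) -> float:
    """⟨S²⟩ over a general determinant list (same algebra as the kernel)."""
    acc = 0.0
    na = space.n_alpha
    for idx, (sa, sb) in enumerate(space.dets.tolist()):
        ci = c[idx]
        if ci == 0.0:
            continue
        for p in occ_list(sb):
            if (sa >> p) & 1:
                continue
            below = (1 << p) - 1
            sgn1 = -1 if (na + bin(sb & below).count("1") + bin(sa & below).count("1")) % 2 else 1
            sa1, sb1 = sa | (1 << p), sb ^ (1 << p)
            for q in occ_list(sa1):
                if (sb1 >> q) & 1:
                    continue
                bq = (1 << q) - 1
                sgn2 = (
                    -1
                    if (bin(sa1 & bq).count("1") + na + bin(sb1 & bq).count("1")) % 2
                    else 1
                )
                key = (sa1 ^ (1 << q), sb1 | (1 << q))
                j = space._index.get(key)
                if j is not None:
                    acc += sgn1 * sgn2 * ci * c[j]
    ms = 0.5 * space.ms2
    return ms * (ms + 1.0) + acc


def transition_rdm_list(space: CISpace, c_bra: np.ndarray, c_ket: np.ndarray) -> np.ndarray:
    """Spin-summed ⟨bra|E_pq|ket⟩ over a general determinant list."""
    n = space.n_orb
    out = np.zeros((n, n))
    for idx, (sa, sb) in enumerate(space.dets.tolist()):
        ck = c_ket[idx]
        if ck == 0.0:
            continue
        for s_str, other, is_alpha in ((sa, sb, True), (sb, sa, False)):
            for q in occ_list(s_str):
                out[q, q] += c_bra[idx] * ck
                for p in range(n):
                    if (s_str >> p) & 1:
                        continue
                    s1 = (s_str ^ (1 << q)) | (1 << p)
                    key = (s1, sb) if is_alpha else (sa, s1)
                    j = space._index.get(key)
                    if j is not None:
                        out[p, q] += _sp_phase(s_str, q, p) * c_bra[j] * ck
    return out


def s_squared(state: CIState) -> float:
    """⟨S²⟩ of a CI state, recomputed from its coefficients."""
    space = state.space
    if space.is_product:
        c = np.ascontiguousarray(
            state.coefficients.reshape(len(space.strings_a), len(space.strings_b))
        )
        return float(
            slater._s2_product(
                c, np.ascontiguousarray(space.strings_a),
                np.ascontiguousarray(space.strings_b), space.n_alpha,
                space.n_beta, space.n_orb, slater.binom_table(space.n_orb),
            )
        )
    return s_squared_list(space, state.coefficients)


def one_rdm(state: CIState, ints: IntegralSet | None = None) -> np.ndarray:
    """One-particle (spin-summed) density matrix of a CI state."""
    return transition_one_rdm(state, state, ints)


def transition_one_rdm(
    bra: CIState, ket: CIState, ints: IntegralSet | None = None
) -> np.ndarray:
    """⟨bra|E_pq|ket⟩; for bra = ket this is the state 1-RDM (trace n_elec)."""
    if bra.space is not ket.space and not np.array_equal(
        bra.space.dets, ket.space.dets
    ):
        raise ValueError("bra and ket live in different determinant spaces")
    space = bra.space
    if space.is_product:
        if ints is None:
            # RDMs need only the string tables; reuse a dummy integral set
            n = space.n_orb
            ints = IntegralSet(
                n_orb=n, n_elec=space.n_alpha + space.n_beta, ms2=space.ms2,
                e_core=0.0, h_one=np.zeros((n, n)), g_two=np.zeros((n, n, n, n)),
            )
        eng = ProductSpaceEngine(ints, space)
        return eng.transition_rdm(bra.coefficients, ket.coefficients)
    return transition_rdm_list(space, bra.coefficients, ket.coefficients)
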