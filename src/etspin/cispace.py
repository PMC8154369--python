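"""Determinant spaces for CI calculations.

Determinants are pairs of spin strings (alpha, beta), each an int64
bitmask with bit p set when spatial orbital p holds an electron of that
spin.  Strings are ordered by ascending bitmask integer (colexicographic
order of the occupied-orbital sets); full product spaces are alpha-major:
determinant index = ia * n_beta_strings + ib.

Spaces come in two flavours: *product* spaces (full CI over all strings,
amenable to fast string-driven sigma builds) and general determinant
*lists* (reference-restricted selected CI).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np


def strings_for(n_orb: int, k: int) -> np.ndarray:
    """All k-electron strings in n_orb orbitals, ascending bitmask order."""
    if k < 0 or k > n_orb:
        raise ValueError(f"cannot place {k} electrons in {n_orb} orbitals")
    masks = np.fromiter(
        (sum(1 << p for p in c) for c in combinations(range(n_orb), k)),
        dtype=np.int64,
    )
    masks.sort()
    return masks


def det_from_occ(alpha_occ, beta_occ) -> tuple[int, int]:
    """Build a determinant from lists of occupied spatial orbitals."""
    sa = 0
    for p in alpha_occ:
        sa |= 1 << int(p)
    sb = 0
    for p in beta_occ:
        sb |= 1 << int(p)
    if bin(sa).count("1") != len(list(alpha_occ)) or bin(sb).count("1") != len(
        list(beta_occ)
    ):
        raise ValueError("duplicate orbitals in occupation list")
    return sa, sb


def occ_list(mask: int) -> list[int]:
    out = []
    p = 0
    while mask:
        if mask & 1:
            out.append(p)
        mask >>= 1
        p += 1
    return out


@dataclass
class CISpace:
    """A determinant space with fixed electron counts and S_z."""

    n_orb: int
    n_alpha: int
    n_beta: int
    dets: np.ndarray  # (ndet, 2) int64: [alpha string, beta string]
    strings_a: np.ndarray | None = None  # set for full product spaces
    strings_b: np.ndarray | None = None
    reference_configs: np.ndarray | None = None
    max_excitation: int | str = "full"
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.dets = np.asarray(self.dets, dtype=np.int64).reshape(-1, 2)
        for sa, sb in self.dets:
            if bin(int(sa)).count("1") != self.n_alpha or bin(int(sb)).count(
                "1"
            ) != self.n_beta:
                raise ValueError(
                    f"determinant ({sa:b},{sb:b}) has wrong electron counts"
                )
            if int(sa) >> self.n_orb or int(sb) >> self.n_orb:
                raise ValueError("determinant uses orbitals outside the space")
        keys = [tuple(d) for d in self.dets.tolist()]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate determinants in space")
        self._index = {k: i for i, k in enumerate(keys)}

    @property
    def size(self) -> int:
        return len(self.dets)

    @property
    def is_product(self) -> bool:
        return self.strings_a is not None

    @property
    def ms2(self) -> int:
        return self.n_alpha - self.n_beta

    def index_of(self, det: tuple[int, int]) -> int:
        return self._index[tuple(int(x) for x in det)]


def _exc_degree(s1: int, s2: int) -> int:
    return bin(s1 ^ s2).count("1") // 2


def build_ci_space(
    n_orb: int,
    n_alpha: int,
    n_beta: int,
    reference_configs=None,
    max_excitation: int | str = "full",
) -> CISpace:
    """Enumerate an FCI or reference-restricted selected-CI space.

    ``max_excitation="full"`` gives all C(n_orb,n_alpha)*C(n_orb,n_beta)
    determinants as a product space.  With an integer bound, the space is
    the union over ``reference_configs`` (determinant tuples) of all
    determinants within that many total substitutions; the references
    themselves are always contained (distance 0).
    """
    sa_all = strings_for(n_orb, n_alpha)
    sb_all = strings_for(n_orb, n_beta)

    if max_excitation == "full":
        dets = np.empty((len(sa_all) * len(sb_all), 2), dtype=np.int64)
        dets[:, 0] = np.repeat(sa_all, len(sb_all))
        dets[:, 1] = np.tile(sb_all, len(sa_all))
        return CISpace(
            n_orb=n_orb, n_alpha=n_alpha, n_beta=n_beta, dets=dets,
            strings_a=sa_all, strings_b=sb_all, max_excitation="full",
        )

    max_exc = int(max_excitation)
    if not reference_configs:
        raise ValueError(
            "selected CI with finite max_excitation needs reference_configs"
        )
    refs = np.asarray(
        [tuple(int(x) for x in r) for r in reference_configs], dtype=np.int64
    ).reshape(-1, 2)
    for ra, rb in refs:
        if bin(int(ra)).count("1") != n_alpha or bin(int(rb)).count("1") != n_beta:
            raise ValueError("reference configuration has wrong electron counts")

    selected = []
    for sa in sa_all:
        for sb in sb_all:
            for ra, rb in refs:
                if _exc_degree(int(sa), int(ra)) + _exc_degree(int(sb), int(rb)) <= max_exc:
                    selected.append((int(sa), int(sb)))
                    break
    dets = np.asarray(sorted(selected), dtype=np.int64)
    return CISpace(
        n_orb=n_orb, n_alpha=n_alpha, n_beta=n_beta, dets=dets,
        reference_configs=refs, max_excitation=max_exc,
    )
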