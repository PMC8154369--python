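"""FCIDUMP-format integral sets (Molpro-style text dialect).

The format carries a namelist header (``&FCI NORB=..,NELEC=..,MS2=..,
ORBSYM=..,ISYM=.. &END``) followed by records ``value i j k l`` with
1-based orbital indices: ``i j 0 0`` records are one-electron integrals,
``0 0 0 0`` the core (nuclear-repulsion + frozen) energy, and general
records the two-electron integrals (ij|kl) in chemists' notation with the
full 8-fold permutational symmetry implied.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np


@dataclass
class IntegralSet:
    """Second-quantized Hamiltonian data over an orthonormal orbital set.

    ``h_one`` is the symmetric one-electron matrix (hartree), ``g_two`` the
    fully expanded (n,n,n,n) two-electron tensor in chemists' notation
    (ij|kl) with 8-fold symmetry, ``e_core`` the scalar core energy.
    """

    n_orb: int
    n_elec: int
    ms2: int
    e_core: float
    h_one: np.ndarray
    g_two: np.ndarray
    orbsym: list[int] = field(default_factory=list)

    def __post_init__(self):
        n = self.n_orb
        self.h_one = np.asarray(self.h_one, dtype=float)
        self.g_two = np.asarray(self.g_two, dtype=float)
        if self.h_one.shape != (n, n):
            raise ValueError(f"h_one shape {self.h_one.shape} != ({n},{n})")
        if self.g_two.shape != (n, n, n, n):
            raise ValueError(f"g_two shape {self.g_two.shape} != ({n},)*4")
        if self.n_elec < 0 or self.n_elec > 2 * n:
            raise ValueError(f"n_elec={self.n_elec} incompatible with n_orb={n}")
        if (self.n_elec - self.ms2) % 2 != 0 or abs(self.ms2) > self.n_elec:
            raise ValueError(f"ms2={self.ms2} incompatible with n_elec={self.n_elec}")
        if not self.orbsym:
            self.orbsym = [1] * n

    def validate_symmetry(self, tol: float = 1e-10) -> None:
        """Check h_one symmetry and the 8-fold permutational symmetry of g_two."""
        if not np.allclose(self.h_one, self.h_one.T, atol=tol):
            raise ValueError("h_one is not symmetric")
        g = self.g_two
        for perm in [(1, 0, 2, 3), (0, 1, 3, 2), (2, 3, 0, 1)]:
            if not np.allclose(g, g.transpose(perm), atol=tol):
                raise ValueError(f"g_two violates permutational symmetry {perm}")

    @property
    def n_alpha(self) -> int:
        return (self.n_elec + self.ms2) // 2

    @property
    def n_beta(self) -> int:
        return (self.n_elec - self.ms2) // 2


_INT_RE = re.compile(r"[-+]?\d+")


def _parse_header(text: str) -> tuple[dict, int]:
    """Parse the &FCI ... &END (or '/') namelist; return fields and end offset."""
    m = re.search(r"&FCI(.*?)(?:&END|/)", text, flags=re.S | re.I)
    if m is None:
        raise ValueError("malformed FCIDUMP: missing &FCI ... &END header")
    body = m.group(1)
    fields: dict = {}
    for key in ("NORB", "NELEC", "MS2", "ISYM"):
        km = re.search(rf"{key}\s*=\s*([-+]?\d+)", body, flags=re.I)
        if km:
            fields[key] = int(km.group(1))
    om = re.search(r"ORBSYM\s*=\s*([\d,\s]+)", body, flags=re.I)
    if om:
        fields["ORBSYM"] = [int(x) for x in _INT_RE.findall(om.group(1))]
    for key in ("NORB", "NELEC"):
        if key not in fields:
            raise ValueError(f"malformed FCIDUMP header: {key} missing")
    return fields, m.end()


def read_fcidump(source) -> IntegralSet:
    """Read an FCIDUMP from a path, text string, or open text stream."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
        if "\n" not in text and "&" not in text:
            with open(text) as fh:
                text = fh.read()

    fields, end = _parse_header(text)
    n = fields["NORB"]
    n_elec = fields["NELEC"]
    ms2 = fields.get("MS2", n_elec % 2)
    h = np.zeros((n, n))
    g = np.zeros((n, n, n, n))
    e_core = 0.0

    for lineno, line in enumerate(text[end:].splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"malformed FCIDUMP record at line {lineno}: {line!r}")
        val = float(parts[0].replace("D", "E").replace("d", "e"))
        i, j, k, l = (int(x) for x in parts[1:])
        for idx in (i, j, k, l):
            if idx < 0 or idx > n:
                raise ValueError(
                    f"orbital index {idx} out of range 1..{n} at line {lineno}"
                )
        if i == j == k == l == 0:
            e_core = val
        elif k == 0 and l == 0:
            if i == 0 or j == 0:
                raise ValueError(f"malformed one-electron record at line {lineno}")
            h[i - 1, j - 1] = val
            h[j - 1, i - 1] = val
        else:
            if 0 in (i, j, k, l):
                raise ValueError(f"malformed two-electron record at line {lineno}")
            ii, jj, kk, ll = i - 1, j - 1, k - 1, l - 1
            for a, b, c, d in _eightfold(ii, jj, kk, ll):
                g[a, b, c, d] = val

    ints = IntegralSet(
        n_orb=n, n_elec=n_elec, ms2=ms2, e_core=e_core, h_one=h, g_two=g,
        orbsym=fields.get("ORBSYM", []),
    )
    return ints


def _eightfold(i, j, k, l):
    return {
        (i, j, k, l), (j, i, k, l), (i, j, l, k), (j, i, l, k),
        (k, l, i, j), (l, k, i, j), (k, l, j, i), (l, k, j, i),
    }


def write_fcidump(ints: IntegralSet, dest=None, tol: float = 0.0) -> str:
    """Serialize an IntegralSet; returns the text (and writes if dest given).

    Only the canonical representative of each 8-fold-symmetric class is
    written (i>=j, k>=l, (ij)>=(kl) in compound order).
    """
    n = ints.n_orb
    orbsym = ",".join(str(s) for s in ints.orbsym)
    lines = [
        f"&FCI NORB={n},NELEC={ints.n_elec},MS2={ints.ms2},",
        f" ORBSYM={orbsym},",
        " ISYM=1,",
        "&END",
    ]
    g = ints.g_two
    for i in range(n):
        for j in range(i + 1):
            ij = i * (i + 1) // 2 + j
            for k in range(i + 1):
                for l in range(k + 1):
                    if k * (k + 1) // 2 + l > ij:
                        continue
                    v = g[i, j, k, l]
                    if abs(v) > tol:
                        lines.append(
                            f"{v:23.16E} {i + 1:4d} {j + 1:4d} {k + 1:4d} {l + 1:4d}"
                        )
    for i in range(n):
        for j in range(i + 1):
            v = ints.h_one[i, j]
            if abs(v) > tol:
                lines.append(f"{v:23.16E} {i + 1:4d} {j + 1:4d}    0    0")
    lines.append(f"{ints.e_core:23.16E}    0    0    0    0")
    text = "\n".join(lines) + "\n"
    if dest is not None:
        if hasattr(dest, "write"):
            dest.write(text)
        else:
            with open(dest, "w") as fh:
                fh.write(text)
    return text
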