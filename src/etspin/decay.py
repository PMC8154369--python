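"""Exponential distance decay of electron-transfer couplings.

|H_AB| falls off (near-)exponentially with donor–acceptor distance d.  The
default ("half") convention writes

    |H_AB(d)| = A exp(−β d / 2)

as used for coupling-decay benchmarks of symmetric dimers; the alternative
("full") convention A exp(−β d) halves β.  The fit is ordinary least
squares of ln|H_AB| against d.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CONVENTIONS = ("half", "full")


@dataclass(frozen=True)
class DecayFit:
    """Fitted decay: β (Å⁻¹), prefactor A (meV), r², and the convention."""

    beta: float
    prefactor_a: float
    r_squared: float
    convention: str
    n_points: int

    def to_json(self, path=None) -> str:
        s = json.dumps(
            {
                "beta_per_angstrom": self.beta,
                "prefactor_mev": self.prefactor_a,
                "r_squared": self.r_squared,
                "convention": self.convention,
                "n_points": self.n_points,
            },
            indent=1,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def fit_decay(curve: pd.DataFrame, convention: str = "half") -> DecayFit:
    """Fit ln|H_AB| vs distance on a coupling curve.

    ``curve`` needs columns (distance, h_ab); at least two distinct
    distances and strictly nonzero couplings are required.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; use one of {CONVENTIONS}")
    d = np.asarray(curve["distance"], dtype=float)
    h = np.asarray(curve["h_ab"], dtype=float)
    if len(d) < 2 or len(np.unique(d)) < 2:
        raise ValueError("decay fit needs at least two distinct distances")
    bad = np.where(h == 0.0)[0]
    if bad.size:
        raise ValueError(
            f"nonpositive |H_AB| at rows {bad.tolist()} "
            f"(distances {d[bad].tolist()}): cannot take logarithm"
        )

    lnh = np.log(np.abs(h))
    if len(d) == 2:
        slope = (lnh[1] - lnh[0]) / (d[1] - d[0])
        intercept = lnh[0] - slope * d[0]
        r2 = 1.0
    else:
        res = stats.linregress(d, lnh)
        slope, intercept = res.slope, res.intercept
        r2 = float(res.rvalue**2)

    beta = -slope * (2.0 if convention == "half" else 1.0)
    return DecayFit(
        beta=float(beta),
        prefactor_a=float(np.exp(intercept)),
        r_squared=r2,
        convention=convention,
        n_points=len(d),
    )
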