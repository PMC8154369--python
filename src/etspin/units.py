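"""Unit constants and conversions.

Internal convention: energies are carried in hartree, distances in Å,
dipoles in atomic units (e·bohr).  Couplings are *reported* in meV and
decay constants in Å⁻¹, matching common practice in the electron-transfer
literature.
"""

HARTREE_TO_EV = 27.211386245988
HARTREE_TO_MEV = HARTREE_TO_EV * 1000.0
EV_TO_MEV = 1000.0
BOHR_TO_ANGSTROM = 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM


def hartree_to_mev(e: float) -> float:
    return e * HARTREE_TO_MEV


def mev_to_hartree(e: float) -> float:
    return e / HARTREE_TO_MEV
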