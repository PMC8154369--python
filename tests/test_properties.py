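"""State/transition dipoles, CT-partner selection, dipole-dump I/O."""

import dataclasses

import numpy as np
import pytest

from conftest import random_integral_set
from etspin.cispace import build_ci_space
from etspin.cisolve import solve_ci
from etspin.fixtures import hubbard_dimer_fcidump, make_h2, orthonormal_integrals
from etspin.gmh import GMHUndefinedError
from etspin.properties import (
    PropertyIntegrals,
    dipole_moments,
    make_adiabatic_pair,
    read_property_integrals,
    select_ct_partner,
    state_dipole,
    write_property_integrals,
)


def hubbard_prop(d=1.0):
    """Site-dipole operator for the two-site model: z = ±d/2."""
    dip = np.zeros((3, 2, 2))
    dip[2] = np.diag([-d / 2, d / 2])
    return PropertyIntegrals(dipole=dip)


def test_dipole_from_rdm_equals_finite_field_derivative():
    # Hellmann–Feynman on the Hubbard dimer with a field along the site axis
    t, u = 1.0, 2.5
    space = build_ci_space(2, 1, 1)
    prop = hubbard_prop()
    lam = 1e-5
    energies = []
    for sign in (+1, -1):
        ints = hubbard_dimer_fcidump(t, u)
        ints.h_one = ints.h_one + sign * lam * prop.dipole[2]
        energies.append(solve_ci(ints, space, 1)[0].energy)
    deriv = (energies[0] - energies[1]) / (2 * lam)
    st = solve_ci(hubbard_dimer_fcidump(t, u), space, 1)[0]
    mu = state_dipole(st, prop, hubbard_dimer_fcidump(t, u))
    # μ_elec = −tr(γ z) = −dE/dλ
    assert mu[2] == pytest.approx(-deriv, abs=1e-7)


def test_symmetric_dimer_state_dipoles_equal_and_transition_large():
    # symmetric two-site model: both adiabats carry zero dipole, the
    # transition dipole carries the full charge displacement
    ints = hubbard_dimer_fcidump(0.5, 0.0, n_elec=1, ms2=1)
    space = build_ci_space(2, 1, 0)
    sts = solve_ci(ints, space, 2)
    mus, trans = dipole_moments(sts, hubbard_prop(2.0), ints)
    assert mus[0][2] == pytest.approx(0.0, abs=1e-12)
    assert mus[1][2] == pytest.approx(0.0, abs=1e-12)
    assert abs(trans[0, 1, 2]) == pytest.approx(1.0, abs=1e-12)  # d/2


def test_transition_dipoles_symmetric_between_real_states():
    ints = random_integral_set(4, 3, 1, seed=31)
    space = build_ci_space(4, 2, 1)
    sts = solve_ci(ints, space, 3)
    rng = np.random.default_rng(0)
    dip = rng.normal(size=(3, 4, 4))
    dip = 0.5 * (dip + dip.transpose(0, 2, 1))
    prop = PropertyIntegrals(dipole=dip)
    _, trans = dipole_moments(sts, prop, ints)
    np.testing.assert_allclose(trans, trans.transpose(1, 0, 2), atol=1e-12)


def test_select_ct_partner_picks_largest_projection():
    ints = hubbard_dimer_fcidump(0.5, 0.0, n_elec=1, ms2=1)
    space = build_ci_space(2, 1, 0)
    sts = solve_ci(ints, space, 2)
    prop = hubbard_prop(2.0)
    assert select_ct_partner(sts, prop, np.array([0, 0, 1.0]), ints) == 1
    # axis orthogonal to the transition dipole → no CT state
    with pytest.raises(GMHUndefinedError, match="no CT state"):
        select_ct_partner(sts, prop, np.array([1.0, 0, 0]), ints)


def test_select_ct_partner_agrees_with_exhaustive_gmh_search():
    from etspin.gmh import gmh_coupling

    ints = random_integral_set(4, 3, 1, seed=42, scale=0.05)
    space = build_ci_space(4, 2, 1)
    sts = solve_ci(ints, space, 5)
    rng = np.random.default_rng(1)
    dip = rng.normal(size=(3, 4, 4))
    dip = 0.5 * (dip + dip.transpose(0, 2, 1))
    prop = PropertyIntegrals(dipole=dip)
    axis = np.array([0.0, 0.0, 1.0])
    chosen = select_ct_partner(sts, prop, axis, ints)
    # exhaustive: largest |H_AB| over all partners of the ground state
    best, best_h = None, -1.0
    for j in range(1, 5):
        pair = make_adiabatic_pair(sts, prop, 0, j, ints)
        proj = abs(float(pair.mu_transition @ axis))
        if proj < 1e-9:
            continue
        h = abs(gmh_coupling(pair).h_ab)
        if h > best_h:
            best, best_h = j, h
    # the largest projected transition dipole gives the dominant coupling
    pair_c = make_adiabatic_pair(sts, prop, 0, chosen, ints)
    assert abs(gmh_coupling(pair_c).h_ab) >= 0.5 * best_h


def test_make_adiabatic_pair_roundtrip_units():
    ints = hubbard_dimer_fcidump(0.3, 1.0)
    space = build_ci_space(2, 1, 1)
    sts = solve_ci(ints, space, 2)
    pair = make_adiabatic_pair(sts, hubbard_prop(), 0, 1, ints, label="hub")
    assert pair.delta_e == pytest.approx(sts[1].energy - sts[0].energy)
    assert pair.label == "hub"


def test_property_dump_roundtrip(tmp_path):
    rng = np.random.default_rng(3)
    dip = rng.normal(size=(3, 4, 4))
    dip = 0.5 * (dip + dip.transpose(0, 2, 1))
    prop = PropertyIntegrals(
        dipole=dip, nuclear_dipole=np.array([0.1, 0.2, -0.3]),
        gauge_origin=np.array([1.0, 0.0, 2.0]),
    )
    base = str(tmp_path / "dims")
    write_property_integrals(prop, base)
    back = read_property_integrals(base)
    np.testing.assert_allclose(back.dipole, prop.dipole, atol=1e-14)
    np.testing.assert_allclose(back.nuclear_dipole, prop.nuclear_dipole)
    np.testing.assert_allclose(back.gauge_origin, prop.gauge_origin)


def test_dimension_mismatch_raises():
    ints = hubbard_dimer_fcidump(1.0, 1.0)
    space = build_ci_space(2, 1, 1)
    sts = solve_ci(ints, space, 1)
    bad = PropertyIntegrals(dipole=np.zeros((3, 3, 3)))
    with pytest.raises(ValueError, match="mismatch"):
        dipole_moments(sts, bad, ints)


def test_gauge_origin_shift_leaves_gmh_coupling_invariant():
    """Full-stack gauge check: H2 FCI pair diabatized at two gauge origins."""
    from etspin.gmh import gmh_coupling
    import etspin.integrals as ig
    from etspin.cispace import build_ci_space

    geom = make_h2(1.2)
    couplings = []
    for origin in (None, np.array([0.5, -0.3, 2.0])):
        ao = ig.compute_integrals(geom.symbols, geom.coordinates,
                                  ig.load_basis("sto-3g"), gauge_origin=origin)
        x = ig.lowdin_orthogonalization(ao.overlap)
        from etspin.fcidump import IntegralSet

        ints = IntegralSet(
            n_orb=2, n_elec=2, ms2=0, e_core=ao.e_nuc,
            h_one=x.T @ ao.core_hamiltonian @ x, g_two=ig.mo_transform(ao.eri, x),
        )
        prop = PropertyIntegrals(
            dipole=np.einsum("pi,kpq,qj->kij", x, ao.dipole, x),
            nuclear_dipole=ao.nuclear_dipole, gauge_origin=ao.gauge_origin,
        )
        sts = solve_ci(ints, build_ci_space(2, 1, 1), 3)
        j = select_ct_partner(sts, prop, np.array([0, 0, 1.0]), ints)
        couplings.append(gmh_coupling(make_adiabatic_pair(sts, prop, 0, j, ints)).h_ab)
    assert abs(couplings[0]) == pytest.approx(abs(couplings[1]), rel=1e-10)
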