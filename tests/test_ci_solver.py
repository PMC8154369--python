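"""CI eigensolver against an independent fermionic-algebra oracle.

The conftest oracle constructs H, S², and E_pq matrices by explicit
second-quantized operator application with Jordan–Wigner signs, so any
phase or Slater–Condon error in the package shows up here.
"""

import dataclasses
import math

import numpy as np
import pytest

from conftest import (
    naive_e_pq,
    naive_hamiltonian,
    naive_s_squared,
    random_integral_set,
)
from etspin.cispace import build_ci_space, det_from_occ
from etspin.cisolve import (
    ProductSpaceEngine,
    davidson,
    dense_hamiltonian,
    one_rdm,
    s_squared_list,
    solve_ci,
    transition_one_rdm,
)
from etspin.fixtures import hubbard_dimer_fcidump
from etspin.integrals import mo_transform


@pytest.mark.parametrize("na,nb", [(1, 0), (2, 1), (2, 2), (3, 1)])
def test_dense_hamiltonian_matches_fermionic_oracle(na, nb):
    n = 4
    ints = random_integral_set(n, na + nb, na - nb, seed=na * 10 + nb)
    space = build_ci_space(n, na, nb)
    h_pkg = dense_hamiltonian(ints, space)
    h_ref = naive_hamiltonian(space.dets.tolist(), ints.h_one, ints.g_two, ints.e_core)
    np.testing.assert_allclose(h_pkg, h_ref, atol=1e-12)


@pytest.mark.parametrize("na,nb", [(2, 1), (2, 2), (3, 0)])
def test_sigma_kernels_match_dense(na, nb):
    n = 5
    ints = random_integral_set(n, na + nb, na - nb, seed=7)
    space = build_ci_space(n, na, nb)
    eng = ProductSpaceEngine(ints, space)
    h = dense_hamiltonian(ints, space)
    rng = np.random.default_rng(3)
    for _ in range(3):
        v = rng.normal(size=space.size)
        np.testing.assert_allclose(eng.sigma(v).ravel(), h @ v, atol=1e-11)


def test_hubbard_half_filling_closed_form(hubbard_half_filled):
    space = build_ci_space(2, 1, 1)
    st = solve_ci(hubbard_half_filled, space, n_states=1)[0]
    u, t = 4.0, 1.0
    exact = (u - math.sqrt(u * u + 16 * t * t)) / 2
    assert st.energy == pytest.approx(exact, abs=1e-10)
    assert st.s_squared == pytest.approx(0.0, abs=1e-10)


def test_one_electron_system_is_h_matrix_eigenproblem():
    ints = random_integral_set(5, 1, 1, seed=2)
    ints.g_two[:] = 0.0
    space = build_ci_space(5, 1, 0)
    states = solve_ci(ints, space, n_states=2)
    evals = np.linalg.eigvalsh(ints.h_one) + ints.e_core
    assert states[0].energy == pytest.approx(evals[0], abs=1e-12)
    assert states[1].energy == pytest.approx(evals[1], abs=1e-12)


def test_hubbard_one_electron_splitting_is_two_t(hubbard_half_filled):
    ints = dataclasses.replace(hubbard_half_filled, n_elec=1, ms2=1)
    states = solve_ci(ints, build_ci_space(2, 1, 0), n_states=2)
    assert states[1].energy - states[0].energy == pytest.approx(2.0, abs=1e-12)


def test_davidson_equals_dense_diagonalization():
    # medium space (dim 600) solved both ways
    n = 6
    ints = random_integral_set(n, 4, 0, seed=11)
    space = build_ci_space(n, 2, 2)
    assert 200 < space.size <= 2000
    d = solve_ci(ints, space, n_states=3, method="dense")
    v = solve_ci(ints, space, n_states=3, method="davidson")
    for a, b in zip(d, v):
        assert a.energy == pytest.approx(b.energy, abs=1e-10)
        assert abs(abs(np.dot(a.coefficients, b.coefficients)) - 1) < 1e-8


def test_davidson_reproducible_bit_for_bit():
    ints = random_integral_set(5, 3, 1, seed=5)
    space = build_ci_space(5, 2, 1)
    a = solve_ci(ints, space, n_states=2, method="davidson")
    b = solve_ci(ints, space, n_states=2, method="davidson")
    assert a[0].energy == b[0].energy
    assert np.array_equal(a[0].coefficients, b[0].coefficients)


def test_variational_monotonicity_of_selected_spaces():
    n = 5
    ints = random_integral_set(n, 3, 1, seed=9, scale=0.1)
    ref = det_from_occ([0, 1], [0])
    energies = []
    for k in (0, 1, 2, 3):
        space = build_ci_space(n, 2, 1, reference_configs=[ref], max_excitation=k)
        energies.append(solve_ci(ints, space, n_states=1)[0].energy)
    assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(energies, energies[1:]))
    # selected CI at maximal excitation reproduces FCI exactly
    fci = solve_ci(ints, build_ci_space(n, 2, 1), n_states=1)[0].energy
    assert energies[-1] == pytest.approx(fci, abs=1e-12)


def test_orbital_rotation_invariance_of_fci():
    n = 4
    ints = random_integral_set(n, 2, 0, seed=13, scale=0.1)
    space = build_ci_space(n, 1, 1)
    e0 = solve_ci(ints, space, n_states=1)[0].energy
    rng = np.random.default_rng(1)
    q, _ = np.linalg.qr(rng.normal(size=(n, n)))
    rot = dataclasses.replace(
        ints, h_one=q.T @ ints.h_one @ q, g_two=mo_transform(ints.g_two, q)
    )
    e1 = solve_ci(rot, space, n_states=1)[0].energy
    assert e1 == pytest.approx(e0, abs=1e-9)


def test_s_squared_matches_dense_spin_operator():
    n = 4
    for na, nb, seed in [(2, 1, 0), (2, 2, 1), (3, 1, 2)]:
        space = build_ci_space(n, na, nb)
        s2_ref = naive_s_squared(space.dets.tolist(), n)
        ints = random_integral_set(n, na + nb, na - nb, seed=seed)
        eng = ProductSpaceEngine(ints, space)
        rng = np.random.default_rng(seed)
        v = rng.normal(size=space.size)
        v /= np.linalg.norm(v)
        assert eng.s_squared(v) == pytest.approx(float(v @ s2_ref @ v), abs=1e-10)
        assert s_squared_list(space, v) == pytest.approx(
            float(v @ s2_ref @ v), abs=1e-10
        )


def test_high_spin_determinant_has_maximal_s_squared():
    space = build_ci_space(4, 3, 0)
    ints = random_integral_set(4, 3, 3, seed=3)
    st = solve_ci(ints, space, n_states=1)[0]
    assert st.s_squared == pytest.approx(1.5 * 2.5, abs=1e-10)
    assert st.spin_pure


def test_rdm_matches_excitation_operator_oracle():
    n = 4
    ints = random_integral_set(n, 3, 1, seed=21)
    space = build_ci_space(n, 2, 1)
    sts = solve_ci(ints, space, n_states=2)
    g_pkg = transition_one_rdm(sts[0], sts[1], ints)
    for p in range(n):
        for q in range(n):
            e_ref = naive_e_pq(space.dets.tolist(), n, p, q)
            val = float(sts[0].coefficients @ e_ref @ sts[1].coefficients)
            assert g_pkg[p, q] == pytest.approx(val, abs=1e-10)
    # state RDM: symmetric, trace = n_elec, occupations within [0, 2]
    rdm = one_rdm(sts[0], ints)
    np.testing.assert_allclose(rdm, rdm.T, atol=1e-10)
    assert np.trace(rdm) == pytest.approx(3.0, abs=1e-10)
    occ = np.linalg.eigvalsh(rdm)
    assert occ.min() > -1e-10 and occ.max() < 2 + 1e-10


def test_transition_rdm_transposes_under_state_swap():
    ints = random_integral_set(4, 2, 0, seed=8)
    space = build_ci_space(4, 1, 1)
    sts = solve_ci(ints, space, n_states=2)
    g01 = transition_one_rdm(sts[0], sts[1], ints)
    g10 = transition_one_rdm(sts[1], sts[0], ints)
    np.testing.assert_allclose(g01, g10.T, atol=1e-12)
    assert abs(np.trace(g01)) < 1e-10  # orthogonal states


def test_single_determinant_rdm_is_idempotent_occupation():
    space = build_ci_space(3, 1, 1)
    ints = random_integral_set(3, 2, 0, seed=4)
    c = np.zeros(space.size)
    c[space.index_of(det_from_occ([0], [0]))] = 1.0
    st = solve_ci(ints, space, n_states=1)[0]
    st = dataclasses.replace(st, coefficients=c)
    rdm = one_rdm(st, ints)
    np.testing.assert_allclose(rdm, np.diag([2.0, 0, 0]), atol=1e-12)


def test_solver_input_validation():
    ints = random_integral_set(3, 2, 0, seed=0)
    space = build_ci_space(3, 1, 1)
    with pytest.raises(ValueError, match="n_states"):
        solve_ci(ints, space, n_states=100)
    with pytest.raises(ValueError, match="ms2|electron"):
        solve_ci(ints, build_ci_space(3, 2, 0), n_states=1)
    bad = random_integral_set(4, 2, 0, seed=0)
    with pytest.raises(ValueError, match="orbital"):
        solve_ci(bad, space, n_states=1)


def test_davidson_rejects_too_many_roots():
    with pytest.raises(ValueError, match="exceeds"):
        davidson(lambda v: v, np.zeros(3), 5)
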