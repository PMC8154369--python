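# Methods

This note documents the models implemented in `etspin`, the choices made
where the design was genuinely open, and what the synthetic model systems
do and do not establish about real donor–acceptor systems.

## Scientific scope

The package quantifies how the spin state of a donor–acceptor pair affects
the electronic coupling matrix element H_AB that enters electron-transfer
(ET) rate theories quadratically.  It implements the full computational
chain on desk-scale model systems:

1. determinant CI (full, CAS-style, and reference-restricted selected CI)
   over second-quantized integrals in the FCIDUMP text format,
2. state, transition-dipole and spin (S²) properties of the CI states,
3. two-state generalized Mulliken–Hush (GMH) diabatization,
4. exponential distance-decay fits of |H_AB(d)| (decay constant β),
5. exact diagonalization of a two-site double-exchange model with core
   spins, giving the spin-sector-resolved effective couplings and the
   Anderson–Hasegawa spin factor.

## GMH diabatization

For a ground/CT adiabatic pair with energies E₁ ≤ E₂, state dipoles
μ_AA, μ_BB and transition dipole μ_AB — all projected on the direction of
the transition dipole — the coupling between the charge-localized
(diabatic) states obtained by zeroing the diabatic transition moment is

    H_AB = μ_AB ΔE / sqrt((μ_AA − μ_BB)² + 4 μ_AB²),   ΔE = E₂ − E₁.

*Numerics.* When |μ_AA − μ_BB| < 1e−8 a.u. the symmetric reduction
H_AB = ΔE/2 is used verbatim; this avoids catastrophic cancellation and is
exact for the inversion-symmetric dimers studied here.  The invariants
|H_AB| ≤ ΔE/2 (equality in the symmetric case) and gauge-origin
independence are enforced by tests.  Signs are retained in `GMHResult`;
curves and decay fits use magnitudes, since only |H_AB| is physically
comparable between separate diagonalizations.

*Degenerate pairs.* When the adiabatic splitting falls below 1e−10
hartree the two states are an arbitrary mixture of the localized pair;
the pipeline then diagonalizes the axis-dipole operator inside the 2×2
block and re-forms the ± combinations before GMH.

## Determinant CI

Determinants are (alpha, beta) bit-string pairs in colexicographic order,
alpha-major; the phase convention is alpha creation operators (ascending
orbital) before beta.  Matrix elements follow the Slater–Condon rules with
chemists'-notation integrals (ij|kl).

* Full product spaces use string-driven sigma builds: same-spin
  singles/doubles per spin channel plus cross-spin kernels in which every
  alpha excitation E_ia (diagonals included) multiplies the beta side;
  for the common one-beta-electron case this is a cache-friendly
  matrix–vector product with g[i,a].  Pure same-spin sectors of moderate
  size additionally materialize the sparse Hamiltonian once (uniform
  row-count CSR) and iterate with cheap matvecs.
* Arbitrary determinant lists (selected CI) use pairwise elements and
  dense diagonalization; selected spaces are the union of all
  determinants within `max_excitation` total substitutions of the
  reference configurations.
* Eigenpairs come from block Davidson iteration: deterministic unit-vector
  starts on the lowest diagonal entries (stable sort), one guard root,
  diagonal preconditioning, twice-applied Gram–Schmidt, thick restarts
  keeping twice the block of lowest Ritz vectors, convergence at residual
  norm 1e−8 hartree.  Dense diagonalization replaces Davidson below 1200
  determinants and cross-checks it in tests up to dimension 2000.

*Orbitals.*  No SCF is performed.  The AO basis is Löwdin-orthogonalized
(S^−1/2) and then rotated to diagonalize the one-electron core
Hamiltonian, with a deterministic sign convention.  Both steps leave every
FCI observable invariant; the canonicalization matters operationally —
with diffuse augmented bases the raw Löwdin determinant diagonal is so
unphysical that Davidson converges an order of magnitude more slowly and
can land on wrong roots.

*S².*  Spin expectations are evaluated as ⟨S_z(S_z+1) + S_−S_+⟩ with
explicit fermionic phases, validated against an independently constructed
dense spin operator.  States are flagged pure when ⟨S²⟩ is within 1e−6 of
S(S+1).

## Gaussian integrals

A native McMurchie–Davidson engine computes overlap, kinetic,
nuclear-attraction, dipole and two-electron repulsion integrals over
contracted Cartesian Gaussians (recursions written for l ≤ 3; s, p, d are
exercised and tested), followed by the solid-harmonic transformation and
exact renormalization of every contracted function to unit self-overlap.
The Boys function uses a downward-recursion series below T = 35 and the
erf-based closed form with upward recursion above.  Primitive screening
discards quartets whose Gaussian-product prefactors fall below 1e−18.
Hydrogen STO-3G, cc-pVDZ, aug-cc-pVDZ and aug-cc-pVTZ basis sets are
vendored as NWChem-format text.

Validation is by independent routes: Gauss–Hermite quadrature for
overlap/kinetic/dipole, the classic s-orbital closed forms for nuclear
attraction and repulsion, scipy's incomplete gamma for the Boys function,
translation/rotation invariance of FCI energies (which exercises all
angular blocks), and physical anchors (H-atom and H₂⁺ energies bracketed
by their exact values).

## The H₂···H₂⁺ model study

The synthetic stand-in for a symmetric ET system is H₂···H₂⁺: a neutral
H₂ donor and an H₂⁺ acceptor, both with the same H–H bond length
(0.74 Å equilibrium or 2.50 Å stretched), at center-of-mass separations
4–7 Å in 0.5 Å steps.  The low-spin (LS) channel is the doublet
(S = 1/2): hole transfer through the compact σ orbitals.  The high-spin
(HS) channel is the quartet (S = 3/2): the donor is a σ¹σ*¹ triplet and
the transfer runs through the much more diffuse σ* orbitals, giving
several-fold larger couplings with slower distance decay.

*Arrangement.*  The two molecules are stacked side by side with parallel
bond axes (perpendicular to the separation axis), preserving inversion
symmetry.  This choice was settled empirically against the reference
behaviour the model is meant to emulate: with the parallel stack the
quartet/doublet coupling ratio is ≈5.8 at 4 Å and the fitted decay
constants are β(HS) ≈ 2.2 and β(LS) ≈ 3.9 Å⁻¹; a collinear chain
(all four atoms on one axis, σ/σ* lobes pointing at the partner) inflates
the HS/LS ratio to ≈17 and flattens the HS decay to β ≈ 1.6.  Only the
parallel stack reproduces the known spin-state contrast (a factor of
five-and-a-bit) together with both decay constants, so it is the default;
`make_h2_dimer(..., arrangement="collinear")` retains the alternative.

*Basis.*  aug-cc-pVTZ on hydrogen.  On the dimer distance grid the two d
shells per atom are dropped (52 instead of 92 orbitals), which keeps the
doublet FCI at 69k and the quartet at 22k determinants and the full
two-sector, seven-distance study at roughly seven minutes on one CPU.
The d shells are compact (exponents 1.057/0.247) and do not carry the
long-range tails that control the decay; in bases where the comparison is
cheap their removal does not change the couplings at the printed
precision.  The isolated-H₂ singlet–triplet gap at 2.50 Å (an
all-electron FCI on 46 orbitals) uses the full basis including d.

*State selection.*  Each sector solves three FCI roots; the CT partner of
the ground state is the root maximizing the |transition dipole| projected
on the stacking axis (`select_ct_partner`).  In augmented bases the
spectrum above the resonance pair contains diffuse ion-pair/Rydberg-like
states; explicit selection keeps them out of the GMH pair.

*Decay fits.*  β is an ordinary least-squares fit of ln|H_AB| against d.
The default ("half") convention |H_AB| = A·exp(−β d/2) is the one under
which the quoted reference decay constants for this system are
reproduced; a flag selects A·exp(−β d) (which exactly halves β).  Note
that neither channel is perfectly exponential over 4–7 Å — the local
log-slope steepens with distance — so fitted β values carry a mild
window dependence of order ±10%.

## Two-site double-exchange model

One itinerant electron hops between two sites with core spin s_core each;
Hilbert space (2s_core+1)²·4.  The Hund term −J S_core·s_e acts on the
occupied site; hopping −t preserves the itinerant spin.  Total-spin
resolution diagonalizes S² inside the (diagonal) S_z = S block and then H
inside the pure-S subspace — no Clebsch–Gordan construction.  The
infinite-Hund (Anderson–Hasegawa) limit is an explicit projection onto
maximal on-site spin s_core + 1/2 before diagonalization, avoiding
large-J arithmetic.  In that limit the effective coupling per sector is
exactly

    H_AB_eff(S) = |t| (S + 1/2) / (2 s_core + 1),

so for s_core = 2 the ferromagnetic (S = 9/2) and antiferromagnetic
(S = 1/2) sectors differ by exactly a factor 5 — the same spin factor
that governs the overlap of charge-localized states in high- vs low-spin
dimers of high-spin ions (minimal ionic spin s₀ = 0).  Finite-J spectra
reproduce the closed form to better than 1% already at J = 50 t and
recover the ferromagnetic double-exchange ground state.

## What the synthetic systems do not show

The model study establishes the spin-state mechanisms (orbital occupation
and the spin-overlap factor) on systems where FCI is exact.  It does not
emulate transition-metal electronic structure: multi-d-electron ions,
ligand-field covalency, or antiferromagnetic exchange in Fe dimers and
Fe–S/Fe–O clusters require CASSCF/NEVPT2-level machinery that is out of
scope.  Accordingly, package-level claims about those systems are limited
to the double-exchange abstraction (the ratio-5 spin factor) rather than
absolute coupling values.

## Problem sizes and determinism

Default study conditions: 7 separations × 2 spin sectors, 52 orbitals
(dimer grid), 3 roots per sector; singlet–triplet gap at 46 orbitals;
double-exchange spaces up to dimension 100.  All solvers are
deterministic (fixed determinant ordering, deterministic starts and sign
conventions); the only randomized components are the seeded diabatic
test fixtures, which are reproducible from their seed.
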