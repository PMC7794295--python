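# Methods

## Model

Atoms are quantum Drude oscillators: a quasi-particle of charge −q bound
harmonically to a nucleus +q. We fix q = 1 (atomic units throughout), so
the oscillator mass is m = 1/(αω²) and the static polarizability α and
frequency ω fully determine the response. Free-atom α, C₆ and van der
Waals radii are tabulated in `data/free_atom.dat` (Chu–Dalgarno
polarizabilities/C₆ as adopted by the Hirshfeld-volume rescaling scheme);
atom-in-molecule values follow from the volume ratios v and an optional
polarizability scale s:

    α = s·v·α_free,  C₆ = (s·v)²·C₆_free,  R_vdw = v^{1/3}·R_free,
    ω = 4C₆/(3α²).

Note ω is invariant under both v and s: rescaling the volume or the
polarizability moves α and C₆ together along the QDO relation
C₆ = (3/4)α²ω. "Increasing the polarizability by 50 %" therefore means
α → 1.5α at fixed ω with C₆ → 2.25·C₆.

### Dipole coupling and sign convention

The dipole tensor is defined as T = ∇∇(1/r) = (3rr − r²I)/r⁵. Expanding
the Coulomb interaction of two neutral oscillators to bilinear order in the
cloud displacements d_A, d_B gives the coupling −q²·d_AᵀT d_B; the
coupling tensor with respect to the two *atom* positions is −T. The
3N×3N interaction matrix therefore has blocks

    C_ii = ω_i² I,   C_ij = −ω_i ω_j √(α_i α_j) f_ij T(R_ij),

with Fermi damping f(R) = 1/(1+exp(−a(R/(β(R_A+R_B)) − 1))). The sign is
observable only for three or more atoms (a two-atom spectrum is symmetric
under it), but it is essential for the beyond-dipole correction: with the
consistent sign, the dipole part of the full Coulomb expectation cancels
E_dip exactly at leading order, leaving the genuine beyond-dipole content.

Eigendecomposition of C yields the mode frequencies ω_DC,k = √λ_k and

    E_MBD = ½Σ_k ω_DC,k − (3/2)Σ_i ω_i.

A non-positive λ_k aborts with a polarization-catastrophe error naming the
offending eigenvalue.

### Gaussian ground states

In mass-weighted coordinates the ground-state covariance of the coupled
system is ½C^{−1/2}, computed from the same eigendecomposition (no second
matrix-root routine); displacement covariance Σ = M^{−1/2}(½C^{−1/2})M^{−1/2}.
The uncoupled state is block-diagonal with isotropic blocks (α_iω_i/2)I.

### Coulomb singles

The perturbation is the damped beyond-dipole potential
V′ = Σ_{A<B} f_dcs(R_AB)(V_Coul − V_dip) with the *bare* dipole tensor
subtracted inside the damped difference and a single damping factor on the
difference (both readings coincide asymptotically; this one is the verbatim
one). E_DCS = ⟨V′⟩_DC − ⟨V′⟩₀ removes the non-zero mean-field part of the
beyond-dipole interaction.

All expectations reduce to K(r,Σ) = E[1/|r+u|] for Gaussian u. Per pair:

    ⟨V_Coul⟩ = q²[1/R − K(R,Σ_BB) − K(R,Σ_AA) + K(R,Σ_AA+Σ_BB−Σ_AB−Σ_BA)]
    J-pair    = same with the cross blocks dropped (mean densities)
    ⟨V_dip⟩  = −q² Tr(T Σ_AB)

The Hartree/correlation split E_DCS = (J[ρ_DC] − J[ρ₀]) + (E_corr − E_dip)
is an algebraic identity as long as the damping multiplies every pair term
uniformly, which is what the implementation does (the standalone J values
reported in the breakdown are therefore damped pair sums). The classical J
terms use per-atom marginal covariances only.

### Smeared-Coulomb kernel

K(r,Σ) = (2/√π)∫₀^∞ det(I+2t²Σ)^{−1/2} exp(−t²rᵀ(I+2t²Σ)^{−1}r) dt with the
substitution t = u/(1−u) and Gauss–Legendre quadrature whose node count
doubles (128 → 16384 cap) until the relative change is below 10⁻¹¹ — a
tolerance chosen so that the strongly cancelling four-term pair combinations
remain accurate even at 60 Bohr separations. Isotropic covariances short-cut
to erf(|r|/√(2s))/|r| (√(2/πs) at the origin). Kernel calls for all pairs
of a system are batched on a shared node grid and chunked to bound memory.

### Monte-Carlo oracle

`mc_expectation` samples the state's Gaussian (Cholesky, chunked) and
averages V′ per sample; it is bit-reproducible for a fixed seed (default
20210108) and serves purely as an independent check on the quadrature path.

## Damping defaults

| variant | a | β | applies to |
|---|---|---|---|
| mbd | 6.0 | 0.83 | dipole coupling in the Hamiltonian |
| dcs | 10.12 | 1.4 | the beyond-dipole perturbation V′ |

The dcs values are the published ones for this correction; the mbd values
are the conventional plain-MBD choice and are configurable — the absolute
host–guest numbers depend on this choice and on whether screened
polarizabilities are supplied (see Limitations).

## Synthetic structures

* **Armchair nanotubes.** Carbon-ring diameter d = 3na_CC/π (6.780 Å for
  (5,5), 8.136 Å for (6,6) at a_CC = 1.42 Å). All carbons are placed
  exactly on that cylinder; in-ring bonds are exact chords of length a_CC
  and the axial layer rise is solved so diagonal bonds are also exactly
  a_CC. The axial period then exceeds the flat-graphene value by ~0.5 % at
  n = 5 (vanishing with n) — the metric price of rolling without stretching
  any bond. Length = largest whole number of unit cells below the target;
  rim carbons get one hydrogen each (C–H 1.09 Å) along the local sp²
  direction (opposite the sum of the existing bonds).
* **Embedded bodies.** Two collinear 2-atom bodies, internal separation
  4 Bohr, centers ±R/2. Toy oscillator defaults α = 25 Bohr³, ω = 0.5 Ha,
  R_vdw = 2.5 Bohr give intra-body coupling fα/s³ ≈ 0.35 — strongly
  correlated but safely inside the stability region — so each cloud
  acquires a clear quadrupolar deformation and the electrostatic (J)
  channel of the body–body Coulomb-singles interaction, which decays as
  R⁻⁵, is visible above the faster-decaying correlation channels.
* **Toy confinement.** Rings of rare-gas oscillators stacked into a tube
  (`build_host_tube` / `build_confined_dimer`); the test fixture uses 7
  rings of 6 Ar atoms, radius 5.5 Bohr, spacing 5 Bohr, with two Xe guests
  on the axis. This emulates a polarizable cylindrical cavity at desk
  scale; it does not emulate chemical bonding, screened (atom-in-molecule)
  response, or the surface density of a real nanotube wall.

What passing tests on these fixtures shows: the implementation's internal
consistency (exact sum rule, oracle agreement, symmetry invariance) and the
model's qualitative long-range physics (R⁻⁶ vs R⁻⁵ decay channels,
screening of the dipolar channel under confinement, the interior maximum of
|E_DCS/E_MBD|). What it does not show: quantitative transferability to real
materials, which requires externally computed Hirshfeld volumes and,
strictly, a screened polarizability model.

## Fluctuation densities

The rasterized field is the cloud part only, −Σ q_i N(r; R_i, Σ_ii);
nuclear deltas are excluded (they cancel in every difference field and
rasterizing them only creates artifacts). Default grid: 0.25 Bohr spacing,
6 Bohr padding; a capture check requires the integrated cloud charge to
match −Σq_i within 0.1 % and instructs to enlarge the padding otherwise
(heavy clouds, e.g. free Xe with σ ≈ 2.6 Bohr, need ≥ 13 Bohr). Cube files
follow the standard layout (z fastest), noting the ±0.003 a.u. iso-value
convention for difference densities.

## Fragment energies and scans

E_int for guests in a host uses the four-term subtraction
E(host+A+B) + E(host) − E(host+A) − E(host+B); every subsystem re-solves
its own modes and states but keeps the per-atom parameters of the full
system, so the subtraction isolates interaction, not parametrization drift.
With a single guest the formula degenerates, and the supermolecular binding
E(complex) − E(host) − E(guest) is returned instead. Decay exponents are
least-squares slopes of log|E| against log R; a sign change inside the fit
window is rejected.

## Numerical choices and degenerate inputs

* Degenerate Hamiltonian eigenvalues need no tie-breaking: every downstream
  quantity is a function of C, not of individual eigenvectors.
* Covariance blocks are read directly from the dense 3N×3N Σ; no sparsity
  is exploited (systems of interest are a few hundred atoms).
* PSD checks tolerate −10⁻¹⁰ relative eigenvalue noise; kernel eigenvalues
  are clipped at zero; Σ → 0 falls back to the point-charge 1/R.
* The Fermi damping exponent is clipped at ±700 to avoid overflow deep
  inside the repulsive wall.
* Problem sizes in the shipped tests: Monte-Carlo oracle at 10⁷ samples on
  2- and 3-atom systems; decay fits on 11 points over 20–60 Bohr; grids at
  0.4–0.5 Bohr spacing; the largest Coulomb-singles evaluation is an
  82-atom capped (5,5) tube with two encapsulated Xe.

## Known limitations

* **No self-consistent screening.** The Hamiltonian uses plain damped MBD;
  Hirshfeld ratios are user inputs (defaulting to 1). Published absolute
  host–guest numbers were produced with screened parameters and
  DFT-derived volumes, so absolute binding values here are not comparable
  without those inputs.
* **Finite-body decay window.** For the collinear embedded-body fixture the
  apparent dispersion exponent over 20–60 Bohr is ≈ −6.2 to −6.3, not −6:
  with cross-pair distances R−4, R, R, R+4 the pairwise sum carries a
  multipolar finite-size factor ≈ 1 + 10.5(4/R)², purely geometric and
  independent of the oscillator parameters. The −6 asymptote is recovered
  for point bodies or larger R.
* **Confined Coulomb singles.** In this unscreened model, confinement
  *reduces* the repulsive guest–guest Coulomb-singles interaction wherever
  the dipolar channel is also screened: the shrinkage of the guest–guest
  correlation outweighs the environment-induced quadrupole repulsion, which
  the strong V′ damping suppresses at wall contact. A model with screened
  response can invert this balance.
* Gradients/forces, periodic boundary conditions, frequency-dependent
  response and higher perturbation orders are out of scope.
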