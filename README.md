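# mbdcs

Many-body van der Waals dispersion from coupled quantum Drude oscillators,
plus the first-order correction toward full Coulomb coupling between the
oscillators ("dipole-correlated Coulomb singles", DCS), with analysis tools
for molecules under nanoscale confinement.

## Who this is for

Researchers in molecular modelling and structural bioinformatics who want to
go beyond pairwise or dipole-limited dispersion corrections: the package
computes how long-range electronic correlation polarizes the fluctuating
charge of atoms in cavities, nanotubes and host–guest complexes, and how
that polarization feeds back into the interaction energy.

## The model

Each atom *i* is a quantum Drude oscillator: a charge −*q* bound
harmonically (frequency ω<sub>i</sub>) to a nucleus +*q*, with static
polarizability α<sub>i</sub> = q²/(m<sub>i</sub>ω<sub>i</sub>²).
Parameters come from free-atom reference data scaled by Hirshfeld volume
ratios (α<sub>i</sub> = s·v<sub>i</sub>·α<sub>free</sub>,
C₆<sub>i</sub> = (s·v<sub>i</sub>)²·C₆<sub>free</sub>,
ω<sub>i</sub> = 4C₆/3α²). Coupling all oscillators through the damped
dipole–dipole potential gives a quadratic Hamiltonian solved exactly by one
3N×3N eigendecomposition; the many-body dispersion energy is the
zero-point shift

E_MBD = ½ Σ<sub>k</sub> ω<sub>DC,k</sub> − (3/2) Σ<sub>i</sub> ω<sub>i</sub>.

The exact ground states Ψ_DC and Ψ₀ of the coupled and uncoupled systems
are zero-mean Gaussians. The first-order correction toward *full* Coulomb
coupling is

E_DCS = ⟨Ψ_DC|V′|Ψ_DC⟩ − ⟨Ψ₀|V′|Ψ₀⟩,
V′ = Σ<sub>A&lt;B</sub> f<sub>damp</sub>(R<sub>AB</sub>)·(V<sub>Coul</sub> − V<sub>dip</sub>),

with the Fermi damping f(R) = 1/(1+exp(−a(R/(β·S<sub>vdW</sub>)−1))),
a = 10.12, β = 1.4 for V′. All Gaussian expectations reduce to the smeared
Coulomb kernel K(r,Σ) = E[1/|r+u|], evaluated by quadrature (closed erf form
for isotropic Σ). E_DCS splits exactly into a classical
dispersion–polarization part and a beyond-dipole correlation part,

E_DCS = (J[ρ_DC] − J[ρ₀]) + (E_corr[Ψ_DC] − E_dip[Ψ_DC]),

and the package also rasterizes the fluctuation densities ρ_DC, ρ₀ and
their differences on grids (cube files), computes the displaced-charge
descriptor ∫|Δρ|, host–guest geometry descriptors (f_d, f_a, inverse-R⁵
sums), builds hydrogen-capped armchair carbon nanotubes with encapsulated
guests, and runs fragment-based binding scans.

## Worked example

A xenon dimer binding curve in vacuum (distances in Å, energies in kJ/mol):

```python
import numpy as np
from mbdcs import Geometry, binding_scan

def dimer(r):
    return Geometry(elements=["Xe", "Xe"],
                    coordinates=np.array([[0, 0, -r/2], [0, 0, r/2]]),
                    labels=["guestA", "guestB"])

curve = binding_scan(dimer, np.arange(4.0, 9.1, 0.5))
print(curve.to_frame().to_string(index=False))
```

prints

```
 separation_angstrom  e_mbd_kjmol  e_dcs_kjmol  e_vdw_kjmol  ratio_abs
                4.00     -1.95530      0.10480     -1.85050    0.05360
                4.50     -1.41400      0.10328     -1.31072    0.07304
                5.00     -0.90680      0.08818     -0.81863    0.09724
                5.50     -0.55761      0.06397     -0.49365    0.11472
                6.00     -0.34348      0.03800     -0.30548    0.11064
                7.00     -0.13940      0.00742     -0.13198    0.05322
                8.00     -0.06282      0.00095     -0.06187    0.01507
                9.00     -0.03101      0.00013     -0.03088    0.00413
```

The dispersion energy is attractive and relaxes like R⁻⁶; the Coulomb
singles are a small repulsive correction whose *relative* weight
|E_DCS/E_MBD| peaks near 5.5–6 Å before decaying to zero — the
characteristic interior maximum of the ratio curve.

The same scan inside a confining host (a capped nanotube from
`build_armchair_cnt` + `place_guests`, or a toy oscillator tube from
`build_confined_dimer`) uses the four-term fragment subtraction
E_int = E(host+A+B) + E(host) − E(host+A) − E(host+B).

## Command line

```sh
mbdcs build-cnt --n 5 --length 30 --guest Xe --sep 4.0 -o cnt.xyz
mbdcs mbd-energy cnt.xyz
mbdcs decompose dimer.xyz -o report.json   # totals + J/correlation split
mbdcs scan --n 6 --length 30 --guest Xe -o curve.csv
mbdcs delta-rho complex.xyz -o delta_rho.cube
mbdcs descriptors complex.xyz --guest-frag guestA --ring-frags r1,...,r8
mbdcs fit-decay curve.csv --column e_mbd_kjmol
```

Geometries are extended XYZ (optional `hirsh_ratio` and `frag` per-atom
columns); configuration is YAML (damping parameters, polarizability scaling,
grids, scan ranges, Monte-Carlo seed).

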