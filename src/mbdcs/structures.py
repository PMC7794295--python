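"""Programmatic structure builders.

Everything the test- and analysis workflows consume is generated here:
hydrogen-capped armchair carbon nanotubes with optional encapsulated guests,
collinear "embedded body" fixtures for asymptotic-decay analysis, and toy
oscillator clusters (rings, tubes of rings) that emulate polarizable
confinement at desk scale.

Nanotube construction.  An armchair (n, n) tube has carbon-ring diameter
d = (sqrt(3) a_CC / pi) * sqrt(3) n = 3 n a_CC / pi.  The builder keeps every
carbon exactly on that cylinder and chooses the in-ring bond as an exact
chord of length a_CC; the remaining angular slack of each cell is split
between the two diagonal steps, whose axial rise is then solved so the
diagonal bonds are also exactly a_CC.  The axial period therefore comes out
very slightly longer than the graphene value 2 * sqrt(3) a_CC / 2 (by ~0.5%
for n = 5, vanishing with n) — the price of rolling a flat sheet onto a
cylinder without stretching any bond.  Rim carbons are terminated with
hydrogens placed along the local sp2 direction of the missing neighbor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .geometry import Geometry
from .units import BOHR_TO_ANGSTROM

__all__ = ["NanotubeSpec", "build_armchair_cnt", "armchair_diameter",
           "place_guests", "build_embedded_body_fixture",
           "build_ring_cluster", "build_host_tube", "build_confined_dimer"]


@dataclass(frozen=True)
class NanotubeSpec:
    """Armchair nanotube recipe: chiral indices (n, n), target length (A)."""

    n: int
    length: float               # target tube length, Angstrom
    a_cc: float = 1.42          # C-C bond length, Angstrom
    c_h: float = 1.09           # C-H bond length for the rim caps, Angstrom
    cap: bool = True

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValidationError("armchair index n must be >= 3")
        if self.length <= 0 or self.a_cc <= 0 or self.c_h <= 0:
            raise ValidationError("lengths must be positive")


def armchair_diameter(n: int, a_cc: float = 1.42) -> float:
    """Carbon-ring diameter of an (n, n) tube: 3 n a_CC / pi (Angstrom)."""
    return 3.0 * n * a_cc / math.pi


def _armchair_layout(spec: NanotubeSpec):
    radius = 0.5 * armchair_diameter(spec.n, spec.a_cc)
    phi_bond = 2.0 * math.asin(spec.a_cc / (2.0 * radius))
    cell_angle = 2.0 * math.pi / spec.n
    delta = 0.5 * (cell_angle - 2.0 * phi_bond)
    if delta <= 0:
        raise ValidationError(f"(n={spec.n}) tube too narrow for a_cc={spec.a_cc}")
    chord = 2.0 * radius * math.sin(0.5 * delta)
    dz_sq = spec.a_cc**2 - chord**2
    if dz_sq <= 0:
        raise ValidationError("diagonal bond cannot be closed on this cylinder")
    dz = math.sqrt(dz_sq)
    return radius, phi_bond, delta, dz


def build_armchair_cnt(spec: NanotubeSpec) -> Geometry:
    """Hydrogen-capped armchair (n, n) carbon nanotube, axis along z.

    The realized length is the largest whole number of axial unit cells that
    fits the target; all C-C bonds are exactly ``a_cc`` and all carbons sit
    exactly on the cylinder of the analytic diameter.
    """
    radius, phi_bond, delta, dz = _armchair_layout(spec)
    period = 2.0 * dz
    n_cells = int(spec.length // period)
    if n_cells < 1:
        raise ValidationError(
            f"target length {spec.length} A is shorter than one unit cell "
            f"({period:.3f} A)"
        )
    n_layers = 2 * n_cells
    cell_angle = 2.0 * math.pi / spec.n

    angles_a = np.concatenate(
        [[c * cell_angle, c * cell_angle + phi_bond] for c in range(spec.n)]
    )
    angles_b = np.concatenate(
        [[c * cell_angle + phi_bond + delta,
          c * cell_angle + 2.0 * phi_bond + delta] for c in range(spec.n)]
    )

    coords = []
    z0 = -0.5 * (n_layers - 1) * dz
    for layer in range(n_layers):
        ang = angles_a if layer % 2 == 0 else angles_b
        z = z0 + layer * dz
        for a in ang:
            coords.append((radius * math.cos(a), radius * math.sin(a), z))
    carbons = np.asarray(coords)
    elements = ["C"] * len(carbons)
    labels = ["host"] * len(carbons)

    if spec.cap:
        h_coords = _cap_hydrogens(carbons, spec.a_cc, spec.c_h)
        elements += ["H"] * len(h_coords)
        labels += ["host"] * len(h_coords)
        all_coords = np.vstack([carbons, h_coords])
    else:
        all_coords = carbons
    return Geometry(elements=elements, coordinates=all_coords, labels=labels)


def _cap_hydrogens(carbons: np.ndarray, a_cc: float, c_h: float) -> np.ndarray:
    """One H per under-coordinated carbon, opposite the sum of its bonds."""
    from scipy.spatial.distance import cdist

    dist = cdist(carbons, carbons)
    bonded = (dist > 1e-6) & (dist < a_cc * 1.05)
    h_list = []
    for i in range(len(carbons)):
        neighbors = np.flatnonzero(bonded[i])
        if len(neighbors) >= 3:
            continue
        vecs = carbons[neighbors] - carbons[i]
        vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
        direction = -vecs.sum(axis=0)
        norm = np.linalg.norm(direction)
        if norm < 1e-8:
            raise ValidationError("cannot orient cap hydrogen")
        h_list.append(carbons[i] + c_h * direction / norm)
    return np.asarray(h_list)


def place_guests(
    host: Geometry,
    separation: float,
    guest_element: str = "Xe",
    n_guests: int = 2,
) -> Geometry:
    """Center guest atoms on the host tube axis, symmetric about its midpoint.

    Guests are placed on the z axis at the host's axial center +- R/2 (two
    guests) or at the center (one guest); fragment labels are set to
    ``host`` / ``guestA`` / ``guestB``.
    """
    if n_guests not in (1, 2):
        raise ValidationError("place_guests supports 1 or 2 guests")
    if separation < 0:
        raise ValidationError("separation must be non-negative")
    carbon_idx = [i for i, e in enumerate(host.elements) if e == "C"]
    ref = host.coordinates[carbon_idx] if carbon_idx else host.coordinates
    center = ref.mean(axis=0)
    half_len = ref[:, 2].max() - center[2]
    if n_guests == 2 and separation / 2.0 >= half_len:
        raise ValidationError(
            f"guest separation {separation} A does not fit inside the host "
            f"(half-length {half_len:.2f} A)"
        )
    offsets = [0.0] if n_guests == 1 else [-0.5 * separation, 0.5 * separation]
    tags = ["guestA"] if n_guests == 1 else ["guestA", "guestB"]
    guest_coords = np.array([[center[0], center[1], center[2] + dz]
                             for dz in offsets])
    guests = Geometry(
        elements=[guest_element] * n_guests,
        coordinates=guest_coords,
        labels=tags,
    )
    host_labeled = Geometry(
        elements=host.elements,
        coordinates=host.coordinates,
        hirshfeld_ratios=host.hirshfeld_ratios,
        labels=host.labels if host.labels is not None else ["host"] * host.n_atoms,
    )
    return Geometry.merge([host_labeled, guests])


def build_embedded_body_fixture(
    body_distance: float,
    internal_separation: float = 4.0,
    element: str = "Xe",
) -> Geometry:
    """Two collinear 2-atom bodies on the z axis (distances in Bohr).

    Body centers sit at -+ body_distance/2; within each body the two atoms
    are ``internal_separation`` apart.  Center of mass at the origin.
    """
    if body_distance <= internal_separation:
        raise ValidationError("body distance must exceed the internal separation")
    half_r = 0.5 * body_distance
    half_s = 0.5 * internal_separation
    z_bohr = np.array([-half_r - half_s, -half_r + half_s,
                       half_r - half_s, half_r + half_s])
    coords = np.zeros((4, 3))
    coords[:, 2] = z_bohr * BOHR_TO_ANGSTROM
    return Geometry(
        elements=[element] * 4,
        coordinates=coords,
        labels=["bodyA", "bodyA", "bodyB", "bodyB"],
    )


def embedded_body_oscillators(
    body_distance: float,
    internal_separation: float = 4.0,
    alpha: float = 25.0,
    omega: float = 0.5,
    r_vdw: float = 2.5,
):
    """Collinear embedded-body fixture as bare toy oscillators (Bohr, a.u.).

    The defaults give a strongly dipole-correlated pair (coupling
    ``f alpha / s^3`` about 0.35 at the internal separation, safely inside
    the stability region) so that the intra-body correlation induces a
    clearly visible quadrupolar deformation of each cloud — the study
    condition under which the body-body Coulomb-singles interaction
    exhibits its slow electrostatic decay.
    """
    from .oscillators import OscillatorSet

    if body_distance <= internal_separation:
        raise ValidationError("body distance must exceed the internal separation")
    half_r = 0.5 * body_distance
    half_s = 0.5 * internal_separation
    z = np.array([-half_r - half_s, -half_r + half_s,
                  half_r - half_s, half_r + half_s])
    pos = np.zeros((4, 3))
    pos[:, 2] = z
    return OscillatorSet.from_parameters(pos, alpha, omega, r_vdw)


def build_ring_cluster(
    radius: float,
    n_ring: int = 8,
    ring_element: str = "Ar",
    center_element: str = "Xe",
    with_center: bool = True,
) -> Geometry:
    """Planar ring of atoms (radius in Bohr) with an optional central guest."""
    if n_ring < 3:
        raise ValidationError("ring needs at least 3 atoms")
    if radius <= 0:
        raise ValidationError("ring radius must be positive")
    angles = 2.0 * np.pi * np.arange(n_ring) / n_ring
    coords = np.zeros((n_ring, 3))
    coords[:, 0] = radius * np.cos(angles)
    coords[:, 1] = radius * np.sin(angles)
    elements = [ring_element] * n_ring
    labels = ["host"] * n_ring
    if with_center:
        coords = np.vstack([coords, [[0.0, 0.0, 0.0]]])
        elements.append(center_element)
        labels.append("guestA")
    return Geometry(elements=elements, coordinates=coords * BOHR_TO_ANGSTROM,
                    labels=labels)


def build_host_tube(
    ring_radius: float,
    n_rings: int = 5,
    ring_spacing: float = 4.0,
    n_per_ring: int = 8,
    element: str = "Ar",
    stagger: bool = True,
) -> Geometry:
    """Stack of atom rings around the z axis: a toy polarizable tube (Bohr)."""
    parts = []
    z0 = -0.5 * (n_rings - 1) * ring_spacing
    for k in range(n_rings):
        offset = (np.pi / n_per_ring) * (k % 2) if stagger else 0.0
        angles = 2.0 * np.pi * np.arange(n_per_ring) / n_per_ring + offset
        coords = np.zeros((n_per_ring, 3))
        coords[:, 0] = ring_radius * np.cos(angles)
        coords[:, 1] = ring_radius * np.sin(angles)
        coords[:, 2] = z0 + k * ring_spacing
        parts.append(coords)
    coords = np.vstack(parts) * BOHR_TO_ANGSTROM
    n = len(coords)
    return Geometry(elements=[element] * n, coordinates=coords,
                    labels=["host"] * n)


def build_confined_dimer(
    separation: float,
    ring_radius: float = 5.5,
    n_rings: int = 5,
    ring_spacing: float = 4.0,
    n_per_ring: int = 8,
    host_element: str = "Ar",
    guest_element: str = "Xe",
) -> Geometry:
    """Guest dimer on the axis of a toy host tube (all distances in Bohr)."""
    host = build_host_tube(ring_radius, n_rings, ring_spacing, n_per_ring,
                           host_element)
    half = 0.5 * separation
    guests = Geometry(
        elements=[guest_element] * 2,
        coordinates=np.array([[0.0, 0.0, -half], [0.0, 0.0, half]])
        * BOHR_TO_ANGSTROM,
        labels=["guestA", "guestB"],
    )
    return Geometry.merge([host, guests])
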