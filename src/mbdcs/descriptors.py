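"""Geometric and energetic descriptors for host-guest complexes.

These are cheap scalar measures that can be compared against the
Coulomb-singles contribution of a complex: a proximity sum f_d (inverse
guest-host distances), an axial-radial asymmetry f_a built from a plane
through the guest's long axis, an inverse-fifth-power contact sum that
mimics the electrostatics of correlation-induced quadrupoles, and the
relative Coulomb-singles contribution f_e.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import SingularityError, ValidationError
from .geometry import Geometry

__all__ = ["DescriptorSet", "proximity_fd", "r5_metric",
           "axial_radial_asymmetry", "relative_dcs", "describe_complex"]

_MIN_CONTACT = 1e-8  # Angstrom


@dataclass
class DescriptorSet:
    f_d: float                 # 1/Angstrom
    f_a: float                 # dimensionless, in [-1, 1]
    a_par: float               # 1/Angstrom
    a_perp: float              # 1/Angstrom
    r5: float                  # 1/Angstrom^5
    f_e: float | None = None   # dimensionless


def _inverse_power_sum(guest: np.ndarray, host: np.ndarray, power: int) -> float:
    if len(guest) == 0 or len(host) == 0:
        raise ValidationError("guest and host fragments must be non-empty")
    dist = cdist(guest, host)
    if dist.min() < _MIN_CONTACT:
        raise SingularityError("guest and host share an atom position")
    return float((dist ** -power).sum())


def proximity_fd(guest: np.ndarray, host: np.ndarray) -> float:
    """Sum of inverse guest-host atom distances (1/Angstrom)."""
    return _inverse_power_sum(np.atleast_2d(guest), np.atleast_2d(host), 1)


def r5_metric(guest: np.ndarray, host: np.ndarray) -> float:
    """Sum of inverse fifth powers of guest-host distances (1/Angstrom^5)."""
    return _inverse_power_sum(np.atleast_2d(guest), np.atleast_2d(host), 5)


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    """Elongated axis: top eigenvector of the coordinate second-moment tensor."""
    centered = coords - coords.mean(axis=0)
    moments = centered.T @ centered / len(coords)
    vals, vecs = np.linalg.eigh(moments)
    if vals[-1] <= 0:
        raise ValidationError("guest geometry is a single point")
    if (vals[-1] - vals[-2]) / vals[-1] < 1e-6:
        raise ValidationError(
            "guest principal axis is degenerate (inertia eigenvalue tie)"
        )
    return vecs[:, -1]


def _plane_normal(coords: np.ndarray) -> np.ndarray:
    """Normal of the best plane through a set of points (smallest moment)."""
    centered = coords - coords.mean(axis=0)
    moments = centered.T @ centered / len(coords)
    _, vecs = np.linalg.eigh(moments)
    return vecs[:, 0]


def axial_radial_asymmetry(
    guest: np.ndarray,
    ring_units: Sequence[np.ndarray],
) -> tuple[float, float, float]:
    """Axial/radial vicinity sums and the asymmetry f_a.

    The separating plane P_v contains the guest's elongated principal axis
    and is perpendicular to the mean plane of the host ring.  Ring units are
    ranked by the distance of their centroid to P_v; the closest half are
    axial.  A_par / A_perp are inverse-distance sums from every guest atom
    to every atom of the axial / radial units, and
    f_a = (A_par - A_perp)/(A_par + A_perp).
    """
    guest = np.atleast_2d(np.asarray(guest, dtype=float))
    units = [np.atleast_2d(np.asarray(u, dtype=float)) for u in ring_units]
    if len(units) < 2 or len(units) % 2 != 0:
        raise ValidationError("need an even number (>= 2) of ring units")
    axis = _principal_axis(guest)
    ring_atoms = np.vstack(units)
    normal_ring = _plane_normal(ring_atoms)
    normal_pv = np.cross(axis, normal_ring)
    norm = np.linalg.norm(normal_pv)
    if norm < 1e-8:
        raise ValidationError(
            "guest axis is parallel to the ring normal; P_v plane undefined"
        )
    normal_pv /= norm
    anchor = guest.mean(axis=0)
    dists = np.array([abs((u.mean(axis=0) - anchor) @ normal_pv) for u in units])
    order = np.argsort(dists, kind="stable")
    half = len(units) // 2
    axial = np.vstack([units[k] for k in order[:half]])
    radial = np.vstack([units[k] for k in order[half:]])
    a_par = proximity_fd(guest, axial)
    a_perp = proximity_fd(guest, radial)
    f_a = (a_par - a_perp) / (a_par + a_perp)
    return a_par, a_perp, f_a


def relative_dcs(values: Mapping[str, float], reference: str) -> dict[str, float]:
    """f_e per system: each Coulomb-singles energy over the reference one."""
    if reference not in values:
        raise ValidationError(f"reference key {reference!r} not in values")
    ref = values[reference]
    if ref == 0.0:
        raise ValidationError("reference Coulomb-singles energy is zero")
    return {key: val / ref for key, val in values.items()}


def describe_complex(
    geometry: Geometry,
    guest_label: str,
    ring_labels: Sequence[str] | None = None,
    host_labels: Sequence[str] | None = None,
    e_dcs_ratio: float | None = None,
) -> DescriptorSet:
    """All descriptors of a labeled host-guest geometry in one call.

    ``ring_labels`` name the host ring units for f_a; when omitted, f_a is
    computed by treating every host fragment as one unit (requires an even
    fragment count).
    """
    frags = geometry.fragments()
    if guest_label not in frags:
        raise ValidationError(f"no fragment labeled {guest_label!r}")
    guest = geometry.coordinates[frags[guest_label]]
    if host_labels is None:
        host_labels = [lab for lab in frags if lab != guest_label]
    host = np.vstack([geometry.coordinates[frags[lab]] for lab in host_labels])
    if ring_labels is None:
        ring_labels = list(host_labels)
    units = [geometry.coordinates[frags[lab]] for lab in ring_labels]
    a_par, a_perp, f_a = axial_radial_asymmetry(guest, units)
    return DescriptorSet(
        f_d=proximity_fd(guest, host),
        f_a=f_a,
        a_par=a_par,
        a_perp=a_perp,
        r5=r5_metric(guest, host),
        f_e=e_dcs_ratio,
    )
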