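"""Real-space density of electronic fluctuations.

The mean charge density of the Drude clouds in a Gaussian ground state is a
sum of per-atom normal distributions carrying charge ``-q_i`` with the
marginal displacement covariance as spread (nuclear point charges are kept
out of the rasterized field: they cancel identically in every difference
quantity, and rasterizing deltas only produces artifacts).

Differences of such densities between the dipole-coupled and uncoupled
states — and between a complex and its isolated monomers — visualize how
long-range correlation polarizes the fluctuating charge.  The integral of
the absolute density difference ("displaced charge") is a scalar descriptor
that tracks the magnitude of the Coulomb-singles contribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import GridCaptureError, ValidationError
from .geometry import Geometry
from .oscillators import GaussianState, OscillatorSet
from .reference import ATOMIC_NUMBERS

__all__ = ["DensityGrid", "make_grid", "fluctuation_density",
           "dispersion_polarization_density", "delta_rho", "displaced_charge",
           "write_cube"]

DEFAULT_SPACING = 0.25  # Bohr
DEFAULT_PADDING = 6.0   # Bohr


@dataclass
class DensityGrid:
    """Regular orthorhombic volumetric grid (atomic units)."""

    origin: np.ndarray    # (3,) Bohr
    spacing: np.ndarray   # (3,) Bohr
    values: np.ndarray    # (nx, ny, nz) e / Bohr^3

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.spacing <= 0):
            raise ValidationError("grid spacing must be positive")
        if self.values.ndim != 3:
            raise ValidationError("grid values must be a 3-D array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[k] + self.spacing[k] * np.arange(self.shape[k])
            for k in range(3)
        )

    def integral(self) -> float:
        return float(self.values.sum() * self.voxel_volume)

    def same_geometry(self, other: "DensityGrid") -> bool:
        return (self.shape == other.shape
                and np.allclose(self.origin, other.origin, atol=1e-10)
                and np.allclose(self.spacing, other.spacing, atol=1e-12))

    def _binary(self, other: "DensityGrid", sign: float) -> "DensityGrid":
        if not self.same_geometry(other):
            raise ValidationError("grids have different geometry")
        return DensityGrid(self.origin.copy(), self.spacing.copy(),
                           self.values + sign * other.values)

    def __add__(self, other: "DensityGrid") -> "DensityGrid":
        return self._binary(other, +1.0)

    def __sub__(self, other: "DensityGrid") -> "DensityGrid":
        return self._binary(other, -1.0)


def make_grid(
    positions: np.ndarray,
    spacing: float | Sequence[float] = DEFAULT_SPACING,
    padding: float = DEFAULT_PADDING,
) -> DensityGrid:
    """Empty grid enclosing ``positions`` (Bohr) with the given padding."""
    positions = np.atleast_2d(positions)
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
    lo = positions.min(axis=0) - padding
    hi = positions.max(axis=0) + padding
    counts = np.ceil((hi - lo) / spacing).astype(int) + 1
    return DensityGrid(origin=lo, spacing=spacing,
                       values=np.zeros(tuple(counts)))


def _accumulate_gaussians(
    grid: DensityGrid,
    centers: np.ndarray,
    covariances: np.ndarray,
    charges: np.ndarray,
) -> None:
    ax, ay, az = grid.axes()
    # mesh as flat (P, 3) points, chunked to bound memory
    nx, ny, nz = grid.shape
    yz = np.empty((ny * nz, 2))
    yy, zz = np.meshgrid(ay, az, indexing="ij")
    yz[:, 0] = yy.ravel()
    yz[:, 1] = zz.ravel()
    for a in range(len(charges)):
        inv = np.linalg.inv(covariances[a])
        norm = charges[a] / np.sqrt((2.0 * np.pi) ** 3
                                    * np.linalg.det(covariances[a]))
        dy = yz[:, 0] - centers[a, 1]
        dz = yz[:, 1] - centers[a, 2]
        base = (inv[1, 1] * dy**2 + inv[2, 2] * dz**2 + 2.0 * inv[1, 2] * dy * dz)
        lin = 2.0 * (inv[0, 1] * dy + inv[0, 2] * dz)
        for ix in range(nx):
            dx = ax[ix] - centers[a, 0]
            expo = inv[0, 0] * dx**2 + dx * lin + base
            grid.values[ix] += (norm * np.exp(-0.5 * expo)).reshape(ny, nz)


def fluctuation_density(
    osc: OscillatorSet,
    state: GaussianState,
    grid: DensityGrid | None = None,
    spacing: float | Sequence[float] = DEFAULT_SPACING,
    padding: float = DEFAULT_PADDING,
    capture_tol: float = 1e-3,
) -> DensityGrid:
    """Rasterize the mean Drude-cloud charge density of ``state``.

    The cloud part is ``-sum_i q_i N(r; R_i, Sigma_ii)``; the compensating
    nuclear point charges are reported separately by callers that need them.
    Raises :class:`GridCaptureError` when the integrated cloud charge misses
    ``-sum q_i`` by more than ``capture_tol`` (grid too small for the spread
    of the clouds — increase ``padding``).
    """
    if state.n != osc.n:
        raise ValidationError("state does not match the oscillator set")
    if grid is None:
        grid = make_grid(osc.positions, spacing, padding)
    else:
        grid = DensityGrid(grid.origin.copy(), grid.spacing.copy(),
                           np.zeros(grid.shape))
    covs = np.stack([state.marginal(i) for i in range(osc.n)])
    _accumulate_gaussians(grid, osc.positions, covs, -osc.charge)
    expected = -float(osc.charge.sum())
    captured = grid.integral()
    if abs(captured - expected) > capture_tol * abs(expected):
        raise GridCaptureError(
            f"grid captures {captured / expected:.6f} of the cloud charge; "
            "increase the grid padding"
        )
    return grid


def dispersion_polarization_density(
    osc: OscillatorSet,
    state_dc: GaussianState,
    state_0: GaussianState,
    grid: DensityGrid | None = None,
    spacing: float | Sequence[float] = DEFAULT_SPACING,
    padding: float = DEFAULT_PADDING,
) -> DensityGrid:
    """Delta-rho = rho_DC - rho_0 on a common grid (monopole-free field)."""
    if grid is None:
        grid = make_grid(osc.positions, spacing, padding)
    rho_dc = fluctuation_density(osc, state_dc, grid)
    rho_0 = fluctuation_density(osc, state_0, grid)
    return rho_dc - rho_0


def delta_rho(
    complex_grid: DensityGrid, monomer_grids: Sequence[DensityGrid]
) -> DensityGrid:
    """Difference field of a complex with respect to its isolated monomers."""
    out = complex_grid
    for mono in monomer_grids:
        out = out - mono
    return out


def displaced_charge(grid: DensityGrid) -> float:
    """Integral of |rho| over the grid (e); zero iff the field vanishes."""
    return float(np.abs(grid.values).sum() * grid.voxel_volume)


def write_cube(
    path: str | Path,
    grid: DensityGrid,
    geometry: Geometry | None = None,
    comment: str = "mbdcs fluctuation density",
) -> None:
    """Write a Gaussian cube file (Bohr units, z-fastest value order).

    The second header line records the +-0.003 a.u. iso-value conventionally
    used for difference-density surfaces.
    """
    lines = [comment, "iso-surface convention: +-0.003 a.u."]
    natoms = geometry.n_atoms if geometry is not None else 0
    ox, oy, oz = grid.origin
    lines.append(f"{natoms:5d} {ox:12.6f} {oy:12.6f} {oz:12.6f}")
    for k in range(3):
        vec = np.zeros(3)
        vec[k] = grid.spacing[k]
        lines.append(f"{grid.shape[k]:5d} {vec[0]:12.6f} {vec[1]:12.6f} "
                     f"{vec[2]:12.6f}")
    if geometry is not None:
        for sym, pos in zip(geometry.elements, geometry.positions_bohr):
            z = ATOMIC_NUMBERS.get(sym, 0)
            lines.append(f"{z:5d} {float(z):12.6f} {pos[0]:12.6f} "
                         f"{pos[1]:12.6f} {pos[2]:12.6f}")
    flat = grid.values.reshape(grid.shape[0] * grid.shape[1], grid.shape[2])
    for row in flat:
        for start in range(0, row.size, 6):
            chunk = row[start:start + 6]
            lines.append(" ".join(f"{v:13.5e}" for v in chunk))
    Path(path).write_text("\n".join(lines) + "\n")
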