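"""Coupled quantum Drude oscillators: the many-body dispersion (MBD) model.

Every atom is represented by a charged quasi-particle (charge ``-q``)
harmonically bound to its nucleus (charge ``+q``) with frequency ``omega``.
The static polarizability of such an oscillator is ``alpha = q^2/(m omega^2)``.
All oscillators are coupled through the damped dipole-dipole potential, which
keeps the Hamiltonian quadratic, so the coupled problem is solved exactly by
one symmetric 3N x 3N eigendecomposition.  The dispersion energy is the
zero-point-energy shift

    E_MBD = 1/2 sum_k omega_DC,k  -  3/2 sum_i omega_i,

and the exact ground states of the coupled and uncoupled systems are
zero-mean Gaussians whose displacement covariances feed the Coulomb-singles
correction and the fluctuation-density analysis.

Conventions: atomic units throughout; Drude charge fixed at ``q = 1`` so
``m = 1/(alpha omega^2)``.  Energies of the model depend only on ``alpha``,
``omega`` and the displacement covariance, which this convention pins down.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import scipy.linalg

from .errors import (ConditioningError, PolarizationCatastropheError,
                     SingularityError, ValidationError)
from .geometry import Geometry
from .reference import FreeAtomReference, default_table

__all__ = [
    "DampingParams", "OscillatorSet", "ModeSpectrum", "GaussianState",
    "parametrize", "dipole_tensor", "fermi_damping", "damping_matrix",
    "interaction_matrix", "solve_modes", "mbd_energy", "ground_state",
    "coupled_states",
]


@dataclass(frozen=True)
class DampingParams:
    """Fermi-type short-range damping f(R) = 1/(1 + exp(-a (R/(beta S_vdw) - 1)))."""

    a: float
    beta: float
    variant: str = "mbd"

    def __post_init__(self) -> None:
        if self.a <= 0 or self.beta <= 0:
            raise ValidationError("damping parameters a and beta must be positive")

    @classmethod
    def mbd(cls, a: float = 6.0, beta: float = 0.83) -> "DampingParams":
        """Damping for the dipole coupling in the MBD Hamiltonian."""
        return cls(a=a, beta=beta, variant="mbd")

    @classmethod
    def dcs(cls, a: float = 10.12, beta: float = 1.4) -> "DampingParams":
        """Damping for the beyond-dipole perturbation V' (Coulomb singles)."""
        return cls(a=a, beta=beta, variant="dcs")

    @classmethod
    def undamped(cls) -> "DampingParams":
        """f identically ~1: steep switch far inside any physical separation."""
        return cls(a=1e6, beta=1e-6, variant="undamped")


@dataclass
class OscillatorSet:
    """Per-atom Drude-oscillator parameters plus positions (atomic units)."""

    positions: np.ndarray  # (N, 3) Bohr
    alpha: np.ndarray      # (N,) Bohr^3
    omega: np.ndarray      # (N,) Hartree
    r_vdw: np.ndarray      # (N,) Bohr
    charge: np.ndarray     # (N,) e
    mass: np.ndarray       # (N,) m_e

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        for name in ("alpha", "omega", "r_vdw", "charge", "mass"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name),
                                                         dtype=float)))
        n = self.positions.shape[0]
        if self.positions.shape != (n, 3):
            raise ValidationError("positions must have shape (N, 3)")
        for name in ("alpha", "omega", "r_vdw", "charge", "mass"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValidationError(f"{name} must have shape ({n},)")
            if np.any(arr <= 0):
                raise ValidationError(f"{name} entries must be positive")
        consistency = self.charge**2 / (self.mass * self.omega**2)
        if not np.allclose(consistency, self.alpha, rtol=1e-12, atol=0.0):
            raise ValidationError(
                "inconsistent oscillator parameters: alpha != q^2/(m omega^2)"
            )

    @classmethod
    def from_parameters(
        cls,
        positions: np.ndarray,
        alpha: np.ndarray | float,
        omega: np.ndarray | float,
        r_vdw: np.ndarray | float,
    ) -> "OscillatorSet":
        """Build with the q = 1 convention, m = 1/(alpha omega^2)."""
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        n = positions.shape[0]
        alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (n,)).copy()
        omega = np.broadcast_to(np.asarray(omega, dtype=float), (n,)).copy()
        r_vdw = np.broadcast_to(np.asarray(r_vdw, dtype=float), (n,)).copy()
        return cls(
            positions=positions,
            alpha=alpha,
            omega=omega,
            r_vdw=r_vdw,
            charge=np.ones(n),
            mass=1.0 / (alpha * omega**2),
        )

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def subset(self, indices: Sequence[int] | np.ndarray) -> "OscillatorSet":
        idx = np.asarray(indices, dtype=int)
        return OscillatorSet(
            positions=self.positions[idx],
            alpha=self.alpha[idx],
            omega=self.omega[idx],
            r_vdw=self.r_vdw[idx],
            charge=self.charge[idx],
            mass=self.mass[idx],
        )

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "OscillatorSet":
        pos = self.positions
        if rotation is not None:
            pos = pos @ np.asarray(rotation).T
        if translation is not None:
            pos = pos + np.asarray(translation)
        return replace(self, positions=pos)


def parametrize(
    geometry: Geometry,
    table: FreeAtomReference | None = None,
    alpha_scale: float | np.ndarray = 1.0,
) -> OscillatorSet:
    """Map atoms onto Drude oscillators via Hirshfeld-scaled free-atom data.

    With volume ratio ``v_i`` and polarizability scale ``s_i``:

        alpha_i = s_i v_i alpha_free,   C6_i = (s_i v_i)^2 C6_free,
        R_i^vdw = v_i^(1/3) R_free,     omega_i = 4 C6_i / (3 alpha_i^2).

    Note ``omega`` is invariant under the scaling of C6 and alpha by the same
    ``v``, and scales as ``1/s`` under a pure polarizability scale.
    """
    if table is None:
        table = default_table()
    n = geometry.n_atoms
    scale = np.broadcast_to(np.asarray(alpha_scale, dtype=float), (n,))
    if np.any(scale <= 0):
        raise ValidationError("alpha_scale must be strictly positive")
    ratios = geometry.ratios_or_ones()
    alpha = np.empty(n)
    c6 = np.empty(n)
    r_vdw = np.empty(n)
    for i, sym in enumerate(geometry.elements):
        entry = table[sym]
        sv = scale[i] * ratios[i]
        alpha[i] = sv * entry.alpha
        c6[i] = sv**2 * entry.c6
        r_vdw[i] = ratios[i] ** (1.0 / 3.0) * entry.r_vdw
    omega = 4.0 * c6 / (3.0 * alpha**2)
    return OscillatorSet.from_parameters(
        positions=geometry.positions_bohr, alpha=alpha, omega=omega, r_vdw=r_vdw
    )


def dipole_tensor(r: np.ndarray) -> np.ndarray:
    """Bare dipole tensor T_ab = (3 r_a r_b - |r|^2 d_ab)/|r|^5 = grad grad (1/|r|).

    Note the sign convention: expanding the Coulomb interaction of two
    neutral Drude oscillators to bilinear order in the cloud displacements
    gives the coupling ``-q_A q_B d_A^T T d_B``; equivalently, the coupling
    tensor differentiated with respect to the two ATOM positions is ``-T``.
    """
    r = np.asarray(r, dtype=float)
    dist = np.linalg.norm(r)
    if dist <= 0.0:
        raise SingularityError("dipole tensor undefined at zero separation")
    return (3.0 * np.outer(r, r) - dist**2 * np.eye(3)) / dist**5


def fermi_damping(
    dist: float | np.ndarray,
    r_vdw_a: float | np.ndarray,
    r_vdw_b: float | np.ndarray,
    params: DampingParams,
) -> float | np.ndarray:
    """Fermi switch in (0, 1), midpoint at R = beta (R_A^vdw + R_B^vdw)."""
    s_vdw = params.beta * (np.asarray(r_vdw_a) + np.asarray(r_vdw_b))
    x = np.asarray(dist) / s_vdw - 1.0
    # clip the exponent to dodge overflow warnings far inside the wall
    return 1.0 / (1.0 + np.exp(np.clip(-params.a * x, -700.0, 700.0)))


def damping_matrix(osc: OscillatorSet, params: DampingParams) -> np.ndarray:
    """Pairwise damping factors f_ij (diagonal set to 0)."""
    diff = osc.positions[:, None, :] - osc.positions[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    f = fermi_damping(dist, osc.r_vdw[:, None], osc.r_vdw[None, :], params)
    np.fill_diagonal(f, 0.0)
    return f


def interaction_matrix(osc: OscillatorSet, params: DampingParams | None = None
                       ) -> np.ndarray:
    """The 3N x 3N coupled-oscillator matrix C (units Hartree^2).

    Diagonal blocks ``omega_i^2 I``; off-diagonal blocks
    ``omega_i omega_j sqrt(alpha_i alpha_j) f_ij T(R_ij)``.
    """
    if params is None:
        params = DampingParams.mbd()
    n = osc.n
    c = np.zeros((3 * n, 3 * n))
    for i in range(n):
        c[3 * i:3 * i + 3, 3 * i:3 * i + 3] = osc.omega[i] ** 2 * np.eye(3)
    for i in range(n):
        for j in range(i + 1, n):
            rij = osc.positions[j] - osc.positions[i]
            dist = np.linalg.norm(rij)
            if dist <= 1e-10:
                raise SingularityError(f"atoms {i} and {j} coincide")
            f = fermi_damping(dist, osc.r_vdw[i], osc.r_vdw[j], params)
            # coupling tensor w.r.t. the two atom positions = -grad grad (1/R)
            block = -(osc.omega[i] * osc.omega[j]
                      * np.sqrt(osc.alpha[i] * osc.alpha[j])
                      * f * dipole_tensor(rij))
            c[3 * i:3 * i + 3, 3 * j:3 * j + 3] = block
            c[3 * j:3 * j + 3, 3 * i:3 * i + 3] = block
    return c


@dataclass
class ModeSpectrum:
    """Eigenmodes of the dipole-coupled Hamiltonian."""

    eigenvalues: np.ndarray   # (3N,) Hartree^2, ascending
    mode_matrix: np.ndarray   # (3N, 3N) orthogonal, columns are modes
    omega_dc: np.ndarray      # (3N,) sqrt(eigenvalues)
    omega_0: np.ndarray       # (3N,) uncoupled frequencies (each omega_i x3)


def solve_modes(c: np.ndarray, omega_0: np.ndarray | None = None) -> ModeSpectrum:
    """Diagonalize the interaction matrix; reject unstable coupling.

    ``omega_0`` defaults to the square roots of the diagonal of ``c`` (the
    diagonal blocks are ``omega_i^2 I``).
    """
    c = np.asarray(c, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] % 3:
        raise ValidationError("interaction matrix must be square of size 3N")
    if not np.allclose(c, c.T, rtol=0.0, atol=1e-10 * max(1.0, abs(c).max())):
        raise ValidationError("interaction matrix must be symmetric")
    eigenvalues, modes = scipy.linalg.eigh(c)
    if eigenvalues[0] <= 0.0:
        raise PolarizationCatastropheError(
            "polarization catastrophe: smallest coupled-mode eigenvalue "
            f"{eigenvalues[0]:.6e} Hartree^2 is non-positive"
        )
    if omega_0 is None:
        omega_0 = np.sqrt(np.diag(c))
    else:
        omega_0 = np.repeat(np.asarray(omega_0, dtype=float), 3)
    return ModeSpectrum(
        eigenvalues=eigenvalues,
        mode_matrix=modes,
        omega_dc=np.sqrt(eigenvalues),
        omega_0=omega_0,
    )


def mbd_energy(osc: OscillatorSet, params: DampingParams | None = None) -> float:
    """Many-body dispersion energy (Hartree): zero-point shift of the modes."""
    spectrum = solve_modes(interaction_matrix(osc, params), osc.omega)
    return 0.5 * spectrum.omega_dc.sum() - 0.5 * spectrum.omega_0.sum()


@dataclass
class GaussianState:
    """Zero-mean 3N-dimensional Gaussian ground state (displacement space)."""

    covariance: np.ndarray  # (3N, 3N) Bohr^2
    correlated: bool

    def __post_init__(self) -> None:
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.covariance.ndim != 2 or self.covariance.shape[0] != \
                self.covariance.shape[1] or self.covariance.shape[0] % 3:
            raise ValidationError("covariance must be square of size 3N")

    @property
    def n(self) -> int:
        return self.covariance.shape[0] // 3

    def marginal(self, i: int) -> np.ndarray:
        """3x3 displacement covariance of oscillator i."""
        return self.covariance[3 * i:3 * i + 3, 3 * i:3 * i + 3]

    def cross(self, i: int, j: int) -> np.ndarray:
        """3x3 cross-covariance block <d_i d_j^T>."""
        return self.covariance[3 * i:3 * i + 3, 3 * j:3 * j + 3]

    def cholesky(self) -> np.ndarray:
        try:
            return np.linalg.cholesky(self.covariance)
        except np.linalg.LinAlgError as exc:
            raise ConditioningError(
                "state covariance is not positive definite"
            ) from exc

    def sample(self, n_samples: int, rng: np.random.Generator) -> np.ndarray:
        """Draw displacement vectors, shape (n_samples, 3N)."""
        chol = self.cholesky()
        z = rng.standard_normal((n_samples, self.covariance.shape[0]))
        return z @ chol.T


def ground_state(
    osc: OscillatorSet,
    spectrum: ModeSpectrum | None = None,
    correlated: bool = True,
) -> GaussianState:
    """Exact Gaussian ground state of the (un)coupled oscillator system.

    Correlated: in mass-weighted coordinates the covariance is
    ``(1/2) C^(-1/2)``, mapped back to displacements with ``M^(-1/2)`` on both
    sides.  Uncorrelated: block-diagonal isotropic ``(alpha_i omega_i / 2) I``.
    """
    if not correlated:
        cov = np.zeros((3 * osc.n, 3 * osc.n))
        for i in range(osc.n):
            cov[3 * i:3 * i + 3, 3 * i:3 * i + 3] = (
                0.5 * osc.alpha[i] * osc.omega[i] * np.eye(3)
            )
        return GaussianState(covariance=cov, correlated=False)
    if spectrum is None:
        raise ValidationError("correlated ground state requires a ModeSpectrum")
    inv_sqrt = (spectrum.mode_matrix
                * (0.5 / spectrum.omega_dc)) @ spectrum.mode_matrix.T
    mh = 1.0 / np.sqrt(np.repeat(osc.mass, 3))
    cov = inv_sqrt * np.outer(mh, mh)
    cov = 0.5 * (cov + cov.T)
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ConditioningError(
            "correlated ground-state covariance is not positive definite"
        ) from exc
    return GaussianState(covariance=cov, correlated=True)


def coupled_states(
    osc: OscillatorSet, params: DampingParams | None = None
) -> tuple[GaussianState, GaussianState]:
    """Convenience: (correlated, uncorrelated) ground states for one system."""
    spectrum = solve_modes(interaction_matrix(osc, params), osc.omega)
    return ground_state(osc, spectrum, True), ground_state(osc, correlated=False)
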