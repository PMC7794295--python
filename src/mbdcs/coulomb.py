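"""Dipole-correlated Coulomb singles (DCS).

The MBD Hamiltonian couples oscillators only through the dipole-dipole
tensor.  The first-order correction toward full Coulomb coupling is the
expectation of the damped beyond-dipole potential

    V' = sum_{A<B} f_AB (V_Coul^AB - V_dip^AB)

over the correlated ground state, minus the same expectation over the
uncorrelated state (which removes the non-zero mean-field part of the
beyond-dipole interaction):

    E_DCS = <Psi_DC| V' |Psi_DC> - <Psi_0| V' |Psi_0>.

Because every state involved is a zero-mean Gaussian, all expectations
reduce to the smeared-Coulomb kernel K(r, Sigma) = E[ 1/|r + u| ] for
u ~ N(0, Sigma), evaluated here by one-dimensional quadrature (with a
closed-form erf path for isotropic covariances).

The energy also splits in the Hartree/correlation fashion,

    E_DCS = (J[rho_DC] - J[rho_0]) + (E_corr[Psi_DC] - E_dip[Psi_DC]),

where J[rho] is the classical electrostatic energy of the mean fluctuation
densities (per-atom marginals only), E_corr the part of the full Coulomb
expectation beyond J, and E_dip the expectation of the bare dipole coupling.
The damping factor multiplies every pair term uniformly, which keeps the
split an exact identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import erf

from .errors import (ConditioningError, QuadratureError, SingularityError,
                     ValidationError)
from .oscillators import (DampingParams, GaussianState, OscillatorSet,
                          dipole_tensor, fermi_damping)

__all__ = [
    "gaussian_coulomb_kernel", "pair_coulomb_expectation",
    "pair_hartree_expectation", "pair_dipole_expectation",
    "dcs_energy", "dcs_decomposition", "DCSBreakdown",
    "mc_expectation", "McEstimate", "DEFAULT_MC_SEED",
]

DEFAULT_MC_SEED = 20210108
_KERNEL_RTOL = 1e-11
_MAX_NODES = 2**14
_ISO_TOL = 1e-10


@lru_cache(maxsize=16)
def _gl_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights mapped from [-1, 1] to (0, 1)."""
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (x + 1.0), 0.5 * w


def _kernel_quadrature(
    rp2: np.ndarray, vals: np.ndarray, rtol: float, max_nodes: int
) -> np.ndarray:
    """Batched quadrature for K: rp2 (m,3) squared principal components,
    vals (m,3) principal variances.  Returns (m,) kernel values.

    Uses the substitution t = u/(1-u) on
    K = (2/sqrt(pi)) int_0^inf prod_i (1+2 t^2 s_i)^(-1/2)
        exp(-t^2 sum_i rp_i^2/(1+2 t^2 s_i)) dt
    and doubles the Gauss-Legendre node count until convergence.
    """
    m = rp2.shape[0]
    result = np.full(m, np.nan)
    prev = None
    n_nodes = 128
    while True:
        u, w = _gl_nodes(n_nodes)
        t2 = (u / (1.0 - u)) ** 2
        jac = 1.0 / (1.0 - u) ** 2
        denom = 1.0 + 2.0 * t2[None, :, None] * vals[:, None, :]  # (m, nu, 3)
        logdet = 0.5 * np.log(denom).sum(axis=-1)
        expo = t2[None, :] * (rp2[:, None, :] / denom).sum(axis=-1)
        integrand = np.exp(-logdet - expo) * jac[None, :]
        result = (2.0 / math.sqrt(math.pi)) * integrand @ w
        if prev is not None:
            err = np.abs(result - prev) / np.maximum(np.abs(result), 1e-300)
            if err.max() <= rtol:
                return result
        prev = result
        if n_nodes >= max_nodes:
            raise QuadratureError(
                "smeared-Coulomb quadrature did not converge: achieved "
                f"relative change {err.max():.3e} at {n_nodes} nodes"
            )
        n_nodes *= 2


def _kernel_isotropic(dist: np.ndarray, variance: np.ndarray) -> np.ndarray:
    """Closed form for Sigma = s I: erf(|r|/sqrt(2 s))/|r|, with the
    |r| -> 0 limit sqrt(2/(pi s))."""
    dist = np.asarray(dist, dtype=float)
    variance = np.asarray(variance, dtype=float)
    out = np.empty(np.broadcast(dist, variance).shape)
    dist, variance = np.broadcast_arrays(dist, variance)
    at_origin = dist < 1e-14
    out[at_origin] = np.sqrt(2.0 / (np.pi * variance[at_origin]))
    d = dist[~at_origin]
    out[~at_origin] = erf(d / np.sqrt(2.0 * variance[~at_origin])) / d
    return out


def kernel_batch(
    r: np.ndarray,
    sigma: np.ndarray,
    rtol: float = _KERNEL_RTOL,
    max_nodes: int = _MAX_NODES,
) -> np.ndarray:
    """Vectorized K(r, Sigma) for r (m,3) and Sigma (m,3,3)."""
    r = np.asarray(r, dtype=float).reshape(-1, 3)
    sigma = np.asarray(sigma, dtype=float).reshape(-1, 3, 3)
    if sigma.shape[0] != r.shape[0]:
        raise ValidationError("kernel batch: r and sigma lengths differ")
    if not np.allclose(sigma, np.swapaxes(sigma, 1, 2), rtol=0.0,
                       atol=1e-10 * max(1.0, np.abs(sigma).max())):
        raise ValidationError("covariance matrices must be symmetric")
    vals, vecs = np.linalg.eigh(sigma)
    if vals.min() < -1e-10 * max(1.0, np.abs(vals).max()):
        raise ValidationError("covariance matrices must be positive semi-definite")
    vals = np.clip(vals, 0.0, None)
    dist = np.linalg.norm(r, axis=1)
    out = np.empty(r.shape[0])

    degenerate = vals[:, -1] < 1e-14          # point-charge limit
    if np.any(degenerate & (dist < 1e-14)):
        raise SingularityError("K(0, 0): point charge at zero separation")
    out[degenerate] = 1.0 / dist[degenerate]

    spread = ~degenerate
    iso = spread & (vals[:, -1] <= (1.0 + _ISO_TOL) * np.maximum(vals[:, 0], 1e-300))
    if np.any(iso):
        out[iso] = _kernel_isotropic(dist[iso], vals[iso].mean(axis=1))

    todo = spread & ~iso
    if np.any(todo):
        rp = np.einsum("mab,ma->mb", vecs[todo], r[todo])
        # chunk to bound the (m, n_nodes, 3) work arrays
        idx = np.flatnonzero(todo)
        for start in range(0, idx.size, 2048):
            sel = idx[start:start + 2048]
            rp_sel = rp[start:start + 2048]
            out[sel] = _kernel_quadrature(rp_sel**2, vals[sel], rtol, max_nodes)
    return out


def gaussian_coulomb_kernel(
    r: np.ndarray,
    sigma: np.ndarray,
    rtol: float = 1e-9,
    max_nodes: int = _MAX_NODES,
) -> float:
    """Expected Coulomb potential K(r, Sigma) = E[1/|r + u|], u ~ N(0, Sigma).

    ``r`` in Bohr, ``sigma`` a symmetric PSD 3x3 covariance in Bohr^2; the
    result is in 1/Bohr.  Isotropic covariances use the closed erf form,
    anisotropic ones an adaptive Gauss-Legendre quadrature (relative
    tolerance ``rtol``).
    """
    rtol = min(rtol, _KERNEL_RTOL)
    return float(kernel_batch(np.asarray(r, dtype=float).reshape(1, 3),
                              np.asarray(sigma, dtype=float).reshape(1, 3, 3),
                              rtol=rtol, max_nodes=max_nodes)[0])


# -- pair expectations -----------------------------------------------------

def _pair_blocks(state: GaussianState, i: int, j: int):
    saa = state.marginal(i)
    sbb = state.marginal(j)
    sab = state.cross(i, j)
    return saa, sbb, sab


def _check_psd(mat: np.ndarray, what: str) -> np.ndarray:
    vals = np.linalg.eigvalsh(mat)
    if vals.min() < -1e-10 * max(1.0, abs(vals).max()):
        raise ConditioningError(f"{what} is not positive semi-definite")
    return mat


def pair_coulomb_expectation(
    osc: OscillatorSet, i: int, j: int, state: GaussianState
) -> float:
    """<V_Coul^AB> over the state: full smeared Coulomb energy of the pair.

    Each oscillator is a +q point nucleus plus a Gaussian -q cloud displaced
    by d; with R = R_B - R_A the four charge-charge terms average to

        q_A q_B [ 1/R - K(R, S_BB) - K(R, S_AA)
                  + K(R, S_AA + S_BB - S_AB - S_BA) ].
    """
    if i == j:
        raise ValidationError("pair expectation needs two distinct oscillators")
    rij = osc.positions[j] - osc.positions[i]
    dist = np.linalg.norm(rij)
    if dist <= 0:
        raise SingularityError(f"atoms {i} and {j} coincide")
    saa, sbb, sab = _pair_blocks(state, i, j)
    rel = _check_psd(saa + sbb - sab - sab.T, "covariance of d_B - d_A")
    q2 = osc.charge[i] * osc.charge[j]
    ks = kernel_batch(np.stack([rij, rij, rij]), np.stack([sbb, saa, rel]))
    return float(q2 * (1.0 / dist - ks[0] - ks[1] + ks[2]))


def pair_hartree_expectation(
    osc: OscillatorSet, i: int, j: int, state: GaussianState
) -> float:
    """Classical (Hartree) pair energy J of the mean fluctuation densities.

    Identical to the full expectation but with the cross-covariance dropped:
    the clouds interact as independent mean densities."""
    if i == j:
        raise ValidationError("pair expectation needs two distinct oscillators")
    rij = osc.positions[j] - osc.positions[i]
    dist = np.linalg.norm(rij)
    if dist <= 0:
        raise SingularityError(f"atoms {i} and {j} coincide")
    saa, sbb, _ = _pair_blocks(state, i, j)
    q2 = osc.charge[i] * osc.charge[j]
    ks = kernel_batch(np.stack([rij, rij, rij]), np.stack([sbb, saa, saa + sbb]))
    return float(q2 * (1.0 / dist - ks[0] - ks[1] + ks[2]))


def pair_dipole_expectation(
    osc: OscillatorSet, i: int, j: int, state: GaussianState
) -> float:
    """<V_dip^AB> = -q_A q_B Tr( T(R_AB) . <d_A d_B^T> ); zero if uncorrelated.

    The sign matches the bilinear term of the expanded pair Coulomb
    interaction (see :func:`mbdcs.oscillators.dipole_tensor`)."""
    if i == j:
        raise ValidationError("pair expectation needs two distinct oscillators")
    if not state.correlated:
        return 0.0
    t = dipole_tensor(osc.positions[j] - osc.positions[i])
    sab = state.cross(i, j)
    return float(-osc.charge[i] * osc.charge[j] * np.trace(t @ sab))


# -- DCS energy and decomposition -----------------------------------------

@dataclass
class DCSBreakdown:
    """E_DCS and its Hartree/correlation split (all Hartree, damped pair sums)."""

    e_dcs: float
    j_dc: float
    j_0: float
    e_corr: float
    e_dip: float
    per_pair: pd.DataFrame

    def identity_residual(self) -> float:
        """|e_dcs - (j_dc - j_0) - (e_corr - e_dip)|; an exact algebraic zero."""
        return abs(self.e_dcs - (self.j_dc - self.j_0) - (self.e_corr - self.e_dip))


def _validate_states(osc: OscillatorSet, state_dc: GaussianState,
                     state_0: GaussianState) -> None:
    if state_dc.n != osc.n or state_0.n != osc.n:
        raise ValidationError("state dimensions do not match the oscillator set")


def dcs_decomposition(
    osc: OscillatorSet,
    state_dc: GaussianState,
    state_0: GaussianState,
    params: DampingParams | None = None,
    rtol: float = _KERNEL_RTOL,
) -> DCSBreakdown:
    """Evaluate E_DCS together with its Hartree/correlation components.

    All kernel evaluations for all pairs are batched; the damping factor
    f_dcs(R_AB) multiplies every pair term uniformly.
    """
    if params is None:
        params = DampingParams.dcs()
    _validate_states(osc, state_dc, state_0)
    n = osc.n
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    if not pairs:
        empty = pd.DataFrame(columns=["i", "j", "r", "f_damp", "j_dc", "j_0",
                                      "e_corr", "e_dip", "e_dcs"])
        return DCSBreakdown(0.0, 0.0, 0.0, 0.0, 0.0, empty)

    m = len(pairs)
    rvec = np.empty((m, 3))
    dist = np.empty(m)
    fdamp = np.empty(m)
    q2 = np.empty(m)
    edip = np.empty(m)
    saa_dc = np.empty((m, 3, 3))
    sbb_dc = np.empty((m, 3, 3))
    rel_dc = np.empty((m, 3, 3))
    sum_dc = np.empty((m, 3, 3))
    saa_0 = np.empty((m, 3, 3))
    sbb_0 = np.empty((m, 3, 3))
    sum_0 = np.empty((m, 3, 3))
    for k, (i, j) in enumerate(pairs):
        rij = osc.positions[j] - osc.positions[i]
        d = np.linalg.norm(rij)
        if d <= 1e-10:
            raise SingularityError(f"atoms {i} and {j} coincide")
        rvec[k] = rij
        dist[k] = d
        fdamp[k] = fermi_damping(d, osc.r_vdw[i], osc.r_vdw[j], params)
        q2[k] = osc.charge[i] * osc.charge[j]
        a, b, ab = _pair_blocks(state_dc, i, j)
        saa_dc[k], sbb_dc[k] = a, b
        rel_dc[k] = a + b - ab - ab.T
        sum_dc[k] = a + b
        edip[k] = -q2[k] * np.trace(dipole_tensor(rij) @ ab)
        a0, b0, _ = _pair_blocks(state_0, i, j)
        saa_0[k], sbb_0[k] = a0, b0
        sum_0[k] = a0 + b0
    _check_psd_batch(rel_dc)

    def combo(ka: np.ndarray, kb: np.ndarray, kx: np.ndarray) -> np.ndarray:
        return q2 * (1.0 / dist - ka - kb + kx)

    k_aa_dc = kernel_batch(rvec, saa_dc, rtol)
    k_bb_dc = kernel_batch(rvec, sbb_dc, rtol)
    k_rel_dc = kernel_batch(rvec, rel_dc, rtol)
    k_sum_dc = kernel_batch(rvec, sum_dc, rtol)
    k_aa_0 = kernel_batch(rvec, saa_0, rtol)
    k_bb_0 = kernel_batch(rvec, sbb_0, rtol)
    k_sum_0 = kernel_batch(rvec, sum_0, rtol)

    v_full_dc = combo(k_aa_dc, k_bb_dc, k_rel_dc)
    j_dc = combo(k_aa_dc, k_bb_dc, k_sum_dc)
    j_0 = combo(k_aa_0, k_bb_0, k_sum_0)
    e_corr = v_full_dc - j_dc
    pair_dcs = fdamp * ((j_dc - j_0) + (e_corr - edip))

    table = pd.DataFrame({
        "i": [p[0] for p in pairs],
        "j": [p[1] for p in pairs],
        "r": dist,
        "f_damp": fdamp,
        "j_dc": fdamp * j_dc,
        "j_0": fdamp * j_0,
        "e_corr": fdamp * e_corr,
        "e_dip": fdamp * edip,
        "e_dcs": pair_dcs,
    })
    return DCSBreakdown(
        e_dcs=float(pair_dcs.sum()),
        j_dc=float((fdamp * j_dc).sum()),
        j_0=float((fdamp * j_0).sum()),
        e_corr=float((fdamp * e_corr).sum()),
        e_dip=float((fdamp * edip).sum()),
        per_pair=table,
    )


def _check_psd_batch(mats: np.ndarray) -> None:
    vals = np.linalg.eigvalsh(mats)
    if vals.min() < -1e-10 * max(1.0, np.abs(vals).max()):
        raise ConditioningError(
            "covariance of relative displacement is not positive semi-definite"
        )


def dcs_energy(
    osc: OscillatorSet,
    state_dc: GaussianState,
    state_0: GaussianState,
    params: DampingParams | None = None,
    rtol: float = _KERNEL_RTOL,
) -> float:
    """First-order beyond-dipole Coulomb correction E_DCS (Hartree)."""
    return dcs_decomposition(osc, state_dc, state_0, params, rtol).e_dcs


# -- Monte-Carlo oracle ----------------------------------------------------

@dataclass(frozen=True)
class McEstimate:
    mean: float
    stderr: float
    n_samples: int
    seed: int

    def __post_init__(self) -> None:
        if self.stderr < 0:
            raise ValidationError("stderr must be non-negative")


def _vprime_samples(
    osc: OscillatorSet, displacements: np.ndarray, params: DampingParams
) -> np.ndarray:
    """Damped beyond-dipole potential V' per displacement sample."""
    n = osc.n
    total = np.zeros(displacements.shape[0])
    for i in range(n):
        di = displacements[:, 3 * i:3 * i + 3]
        for j in range(i + 1, n):
            dj = displacements[:, 3 * j:3 * j + 3]
            rij = osc.positions[j] - osc.positions[i]
            dist = np.linalg.norm(rij)
            f = fermi_damping(dist, osc.r_vdw[i], osc.r_vdw[j], params)
            q2 = osc.charge[i] * osc.charge[j]
            v_coul = (1.0 / dist
                      - 1.0 / np.linalg.norm(rij + dj, axis=1)
                      - 1.0 / np.linalg.norm(rij - di, axis=1)
                      + 1.0 / np.linalg.norm(rij + dj - di, axis=1))
            v_dip = -np.einsum("sa,ab,sb->s", di, dipole_tensor(rij), dj)
            total += f * q2 * (v_coul - v_dip)
    return total


def mc_expectation(
    osc: OscillatorSet,
    state: GaussianState,
    params: DampingParams | None = None,
    n_samples: int = 10**6,
    seed: int = DEFAULT_MC_SEED,
    chunk: int = 200_000,
) -> McEstimate:
    """Brute-force estimate of <V'> over the state by Gaussian sampling.

    Deterministic for fixed (n_samples, seed); the standard error comes from
    the sample variance.  This is the validation oracle for the quadrature
    path, never a substitute for it.
    """
    if params is None:
        params = DampingParams.dcs()
    if n_samples < 10**3:
        raise ValidationError("mc_expectation needs at least 1000 samples")
    _ = state.cholesky()  # raises ConditioningError early
    rng = np.random.default_rng(seed)
    total = 0.0
    total_sq = 0.0
    done = 0
    while done < n_samples:
        take = min(chunk, n_samples - done)
        values = _vprime_samples(osc, state.sample(take, rng), params)
        total += values.sum()
        total_sq += (values**2).sum()
        done += take
    mean = total / n_samples
    var = max(total_sq / n_samples - mean**2, 0.0)
    return McEstimate(
        mean=float(mean),
        stderr=float(math.sqrt(var / n_samples)),
        n_samples=n_samples,
        seed=seed,
    )
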