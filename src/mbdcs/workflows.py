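"""End-to-end workflows: fragment interaction energies and binding scans.

The interaction energy of guests inside a host follows the subtraction

    E_int = E(host + all guests) + (k - 1) E(host) - sum_g E(host + g),

which for two guests A, B is E(Xe2@host) + E(host) - E(XeA@host) - E(XeB@host)
and reduces to the plain dimer formula E_AB - E_A - E_B when no host is
present.  Every subsystem is re-solved with its own modes and states, but
with the per-atom oscillator parameters of the FULL system, so the
subtraction isolates interaction rather than parametrization drift.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coulomb import DEFAULT_MC_SEED, dcs_decomposition, dcs_energy
from .errors import MbdcsError, PolarizationCatastropheError, ValidationError
from .geometry import Geometry
from .oscillators import (DampingParams, OscillatorSet, coupled_states,
                          mbd_energy, parametrize)
from .reference import FreeAtomReference
from .units import HARTREE_TO_EV, HARTREE_TO_KJMOL

__all__ = ["MethodSettings", "evaluate_methods", "interaction_energy",
           "BindingCurve", "binding_scan", "fit_decay_exponent",
           "energy_report"]

METHODS = ("mbd", "dcs", "mbd+dcs")


@dataclass(frozen=True)
class MethodSettings:
    """Damping configuration shared by all subsystem evaluations."""

    damping_mbd: DampingParams = field(default_factory=DampingParams.mbd)
    damping_dcs: DampingParams = field(default_factory=DampingParams.dcs)


def evaluate_methods(
    osc: OscillatorSet, settings: MethodSettings | None = None
) -> dict[str, float]:
    """E_MBD, E_DCS and their sum for one oscillator set (Hartree)."""
    settings = settings or MethodSettings()
    if osc.n == 1:
        return {"mbd": 0.0, "dcs": 0.0, "mbd+dcs": 0.0}
    e_mbd = mbd_energy(osc, settings.damping_mbd)
    state_dc, state_0 = coupled_states(osc, settings.damping_mbd)
    e_dcs = dcs_energy(osc, state_dc, state_0, settings.damping_dcs)
    return {"mbd": e_mbd, "dcs": e_dcs, "mbd+dcs": e_mbd + e_dcs}


def _alpha_scale_vector(
    geometry: Geometry, alpha_scale: float | Mapping[str, float]
) -> np.ndarray:
    if isinstance(alpha_scale, Mapping):
        if geometry.labels is None:
            raise ValidationError("per-fragment alpha_scale needs fragment labels")
        return np.array([float(alpha_scale.get(lab, 1.0))
                         for lab in geometry.labels])
    return np.full(geometry.n_atoms, float(alpha_scale))


def interaction_energy(
    geometry: Geometry,
    table: FreeAtomReference | None = None,
    host_label: str = "host",
    settings: MethodSettings | None = None,
    alpha_scale: float | Mapping[str, float] = 1.0,
) -> dict[str, float]:
    """Fragment-based interaction energy per method (Hartree).

    The geometry must carry fragment labels.  Guests are all fragments other
    than ``host_label``; a missing host fragment yields the vacuum formula,
    and a single guest inside a host yields the plain host-guest binding
    energy E(complex) - E(host) - E(guest).
    """
    settings = settings or MethodSettings()
    frags = geometry.fragments()
    if not frags:
        raise ValidationError("geometry has no fragment labels")
    guest_labels = [lab for lab in frags if lab != host_label]
    if not guest_labels:
        return dict.fromkeys(METHODS, 0.0)

    full = parametrize(geometry, table,
                       _alpha_scale_vector(geometry, alpha_scale))

    def subsystem(labels: Iterable[str]) -> dict[str, float]:
        idx = np.concatenate([frags[lab] for lab in labels])
        name = "+".join(labels)
        try:
            return evaluate_methods(full.subset(np.sort(idx)), settings)
        except PolarizationCatastropheError as exc:
            raise PolarizationCatastropheError(
                f"subsystem {name!r}: {exc}"
            ) from exc

    has_host = host_label in frags
    e_all = subsystem(list(frags))
    if has_host and len(guest_labels) >= 2:
        # guest-guest interaction inside the host: every reference keeps the
        # host (and one guest), so host polarization cancels consistently
        e_host = subsystem([host_label])
        singles = [subsystem([host_label, g]) for g in guest_labels]
        k = len(guest_labels)
        return {
            m: e_all[m] + (k - 1) * e_host[m] - sum(s[m] for s in singles)
            for m in METHODS
        }
    # plain supermolecular binding: complex minus isolated fragments
    singles = [subsystem([lab]) for lab in frags]
    return {m: e_all[m] - sum(s[m] for s in singles) for m in METHODS}


@dataclass
class BindingCurve:
    """Interaction energies along a separation scan (kJ/mol, R in Angstrom)."""

    separations: np.ndarray
    e_mbd: np.ndarray
    e_dcs: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.separations = np.asarray(self.separations, dtype=float)
        self.e_mbd = np.asarray(self.e_mbd, dtype=float)
        self.e_dcs = np.asarray(self.e_dcs, dtype=float)
        if not (len(self.separations) == len(self.e_mbd) == len(self.e_dcs)):
            raise ValidationError("binding-curve arrays must have equal length")

    @property
    def e_vdw(self) -> np.ndarray:
        return self.e_mbd + self.e_dcs

    @property
    def ratio(self) -> np.ndarray:
        """|E_DCS / E_MBD| (inf -> nan where E_MBD vanishes)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.abs(self.e_dcs / self.e_mbd)
        out[~np.isfinite(out)] = np.nan
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "separation_angstrom": self.separations,
            "e_mbd_kjmol": self.e_mbd,
            "e_dcs_kjmol": self.e_dcs,
            "e_vdw_kjmol": self.e_vdw,
            "ratio_abs": self.ratio,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def binding_scan(
    factory: Callable[[float], Geometry],
    separations: Sequence[float],
    table: FreeAtomReference | None = None,
    host_label: str = "host",
    settings: MethodSettings | None = None,
    alpha_scale: float | Mapping[str, float] = 1.0,
    metadata: dict | None = None,
) -> BindingCurve:
    """Evaluate the interaction energy at every separation of a scan.

    ``factory(R)`` must return the labeled complex at separation R
    (Angstrom).  Points that fail are collected and reported together.
    """
    separations = np.asarray(list(separations), dtype=float)
    if separations.size and np.any(np.diff(separations) <= 0):
        raise ValidationError("separations must be strictly increasing")
    e_mbd, e_dcs, failures = [], [], []
    for r in separations:
        try:
            energies = interaction_energy(factory(float(r)), table, host_label,
                                          settings, alpha_scale)
        except MbdcsError as exc:
            failures.append((float(r), str(exc)))
            continue
        e_mbd.append(energies["mbd"] * HARTREE_TO_KJMOL)
        e_dcs.append(energies["dcs"] * HARTREE_TO_KJMOL)
    if failures:
        failed = ", ".join(f"R={r:g} ({msg})" for r, msg in failures)
        raise ValidationError(f"binding scan failed at: {failed}")
    meta = dict(metadata or {})
    meta.setdefault("alpha_scale", alpha_scale if not isinstance(
        alpha_scale, Mapping) else dict(alpha_scale))
    return BindingCurve(separations, np.asarray(e_mbd), np.asarray(e_dcs),
                        metadata=meta)


def fit_decay_exponent(
    separations: np.ndarray,
    energies: np.ndarray,
    window: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Least-squares slope of log|E| versus log R, with its standard error.

    Requires at least five points of a single sign inside the window; a sign
    change signals that the data do not follow one power law there.
    """
    separations = np.asarray(separations, dtype=float)
    energies = np.asarray(energies, dtype=float)
    if window is not None:
        mask = (separations >= window[0]) & (separations <= window[1])
        separations, energies = separations[mask], energies[mask]
    if len(separations) < 5:
        raise ValidationError("decay fit needs at least 5 points in the window")
    signs = np.sign(energies)
    if np.any(signs == 0) or len(set(signs)) > 1:
        raise ValidationError("energies change sign inside the fit window")
    fit = stats.linregress(np.log(separations), np.log(np.abs(energies)))
    return float(fit.slope), float(fit.stderr)


def energy_report(
    geometry: Geometry,
    table: FreeAtomReference | None = None,
    settings: MethodSettings | None = None,
    alpha_scale: float | Mapping[str, float] = 1.0,
    source_path: str | Path | None = None,
    mc_seed: int = DEFAULT_MC_SEED,
) -> dict:
    """Structured JSON-ready energy report for one geometry.

    Contains totals in Hartree/eV/kJ per mol, the Hartree/correlation split
    of the Coulomb-singles term, the per-pair table, the damping parameters
    and provenance (input-file SHA-256, Monte-Carlo seed convention).
    """
    settings = settings or MethodSettings()
    osc = parametrize(geometry, table, _alpha_scale_vector(geometry, alpha_scale))
    e_mbd = mbd_energy(osc, settings.damping_mbd) if osc.n > 1 else 0.0
    if osc.n > 1:
        state_dc, state_0 = coupled_states(osc, settings.damping_mbd)
        breakdown = dcs_decomposition(osc, state_dc, state_0,
                                      settings.damping_dcs)
    else:
        breakdown = None

    def in_units(value: float) -> dict[str, float]:
        return {"hartree": value, "ev": value * HARTREE_TO_EV,
                "kjmol": value * HARTREE_TO_KJMOL}

    e_dcs = breakdown.e_dcs if breakdown is not None else 0.0
    report = {
        "n_atoms": geometry.n_atoms,
        "totals": {
            "e_mbd": in_units(e_mbd),
            "e_dcs": in_units(e_dcs),
            "e_vdw": in_units(e_mbd + e_dcs),
        },
        "dcs_components": None if breakdown is None else {
            "j_dc": breakdown.j_dc,
            "j_0": breakdown.j_0,
            "e_corr": breakdown.e_corr,
            "e_dip": breakdown.e_dip,
        },
        "per_pair": (None if breakdown is None
                     else breakdown.per_pair.to_dict(orient="records")),
        "damping": {
            "mbd": {"a": settings.damping_mbd.a, "beta": settings.damping_mbd.beta},
            "dcs": {"a": settings.damping_dcs.a, "beta": settings.damping_dcs.beta},
        },
        "provenance": {
            "input_sha256": (hashlib.sha256(
                Path(source_path).read_bytes()).hexdigest()
                if source_path is not None else None),
            "mc_seed": mc_seed,
        },
    }
    # ensure the structure is JSON-serializable now, not at dump time
    json.dumps(report)
    return report
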