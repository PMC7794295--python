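"""Molecular geometries and extended-XYZ I/O.

A :class:`Geometry` stores element symbols, Cartesian coordinates in
Ångström, optional per-atom Hirshfeld volume ratios (atom-in-molecule
volume over free-atom volume, dimensionless) and optional fragment labels
such as ``"host"`` / ``"guestA"``.

The extended-XYZ dialect understood here is the common one: the comment
line may carry a ``Properties=species:S:1:pos:R:3[:hirsh_ratio:R:1][:frag:S:1]``
token describing the per-atom columns.  Files without a ``Properties``
token are parsed positionally (symbol, x, y, z, optional ratio, optional
fragment tag).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .errors import ValidationError
from .units import ANGSTROM_TO_BOHR

__all__ = ["Geometry", "read_xyz", "write_xyz"]


@dataclass
class Geometry:
    elements: list[str]
    coordinates: np.ndarray                      # (N, 3) Angstrom
    hirshfeld_ratios: np.ndarray | None = None   # (N,) dimensionless
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.elements = list(self.elements)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        n = len(self.elements)
        if n < 1:
            raise ValidationError("geometry needs at least one atom")
        if self.coordinates.shape != (n, 3):
            raise ValidationError(
                f"coordinates must have shape ({n}, 3), got {self.coordinates.shape}"
            )
        if n > 1 and pdist(self.coordinates).min() <= 0.0:
            raise ValidationError("geometry contains coincident atoms")
        if self.hirshfeld_ratios is not None:
            self.hirshfeld_ratios = np.asarray(self.hirshfeld_ratios, dtype=float)
            if self.hirshfeld_ratios.shape != (n,):
                raise ValidationError("hirshfeld_ratios must be one value per atom")
            if np.any(self.hirshfeld_ratios <= 0):
                raise ValidationError("hirshfeld_ratios must be strictly positive")
        if self.labels is not None:
            self.labels = list(self.labels)
            if len(self.labels) != n:
                raise ValidationError("labels must be one tag per atom")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def positions_bohr(self) -> np.ndarray:
        return self.coordinates * ANGSTROM_TO_BOHR

    def ratios_or_ones(self) -> np.ndarray:
        if self.hirshfeld_ratios is None:
            return np.ones(self.n_atoms)
        return self.hirshfeld_ratios

    # -- fragment handling -------------------------------------------------
    def fragments(self) -> dict[str, np.ndarray]:
        """Map each fragment label to the array of its atom indices."""
        if self.labels is None:
            raise ValidationError("geometry carries no fragment labels")
        out: dict[str, list[int]] = {}
        for i, lab in enumerate(self.labels):
            out.setdefault(lab, []).append(i)
        return {k: np.asarray(v) for k, v in out.items()}

    def select(self, indices: Sequence[int] | np.ndarray) -> "Geometry":
        idx = np.asarray(indices, dtype=int)
        return Geometry(
            elements=[self.elements[i] for i in idx],
            coordinates=self.coordinates[idx],
            hirshfeld_ratios=None if self.hirshfeld_ratios is None
            else self.hirshfeld_ratios[idx],
            labels=None if self.labels is None else [self.labels[i] for i in idx],
        )

    def subset_by_labels(self, wanted: Iterable[str]) -> "Geometry":
        wanted = set(wanted)
        if self.labels is None:
            raise ValidationError("geometry carries no fragment labels")
        idx = [i for i, lab in enumerate(self.labels) if lab in wanted]
        if not idx:
            raise ValidationError(f"no atoms with labels {sorted(wanted)}")
        return self.select(idx)

    @staticmethod
    def merge(parts: Sequence["Geometry"]) -> "Geometry":
        elements: list[str] = []
        coords: list[np.ndarray] = []
        ratios: list[np.ndarray] = []
        labels: list[str] = []
        any_ratio = any(p.hirshfeld_ratios is not None for p in parts)
        any_label = any(p.labels is not None for p in parts)
        for p in parts:
            elements.extend(p.elements)
            coords.append(p.coordinates)
            ratios.append(p.ratios_or_ones())
            labels.extend(p.labels if p.labels is not None else [""] * p.n_atoms)
        return Geometry(
            elements=elements,
            coordinates=np.vstack(coords),
            hirshfeld_ratios=np.concatenate(ratios) if any_ratio else None,
            labels=labels if any_label else None,
        )


# -- extended XYZ ----------------------------------------------------------

_PROPS_RE = re.compile(r'Properties="?([A-Za-z0-9_:]+)"?')


def _parse_properties(token: str) -> list[tuple[str, str, int]]:
    fields = token.split(":")
    if len(fields) % 3 != 0:
        raise ValidationError(f"malformed Properties token: {token!r}")
    out = []
    for i in range(0, len(fields), 3):
        out.append((fields[i], fields[i + 1], int(fields[i + 2])))
    return out


def read_xyz(path: str | Path) -> Geometry:
    """Read a (possibly extended) XYZ file."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 2:
        raise ValidationError(f"{path}: not an XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValidationError(f"{path}: first line must be the atom count") from None
    comment = lines[1]
    body = [ln.split() for ln in lines[2:2 + n] if ln.strip()]
    if len(body) != n:
        raise ValidationError(f"{path}: expected {n} atom lines, found {len(body)}")

    match = _PROPS_RE.search(comment)
    schema = (_parse_properties(match.group(1)) if match
              else [("species", "S", 1), ("pos", "R", 3)])

    elements: list[str] = []
    coords = np.zeros((n, 3))
    ratios: list[float] = []
    labels: list[str] = []
    ncols = sum(w for _, _, w in schema)
    for i, toks in enumerate(body):
        if len(toks) < ncols:
            raise ValidationError(f"{path}: atom line {i} has too few columns")
        col = 0
        for name, _, width in schema:
            chunk = toks[col:col + width]
            col += width
            if name == "species":
                elements.append(chunk[0])
            elif name == "pos":
                coords[i] = [float(x) for x in chunk]
            elif name == "hirsh_ratio":
                ratios.append(float(chunk[0]))
            elif name == "frag":
                labels.append(chunk[0])
        if not match and len(toks) > col:
            # positional extras: a float -> Hirshfeld ratio, a word -> fragment
            for tok in toks[col:]:
                try:
                    ratios.append(float(tok))
                except ValueError:
                    labels.append(tok)
    return Geometry(
        elements=elements,
        coordinates=coords,
        hirshfeld_ratios=np.asarray(ratios) if len(ratios) == n else None,
        labels=labels if len(labels) == n else None,
    )


def write_xyz(path: str | Path, geometry: Geometry, comment: str = "") -> None:
    """Write a geometry as extended XYZ (with hirsh_ratio / frag columns if set)."""
    props = "species:S:1:pos:R:3"
    if geometry.hirshfeld_ratios is not None:
        props += ":hirsh_ratio:R:1"
    if geometry.labels is not None:
        props += ":frag:S:1"
    lines = [str(geometry.n_atoms), f'Properties={props} {comment}'.rstrip()]
    for i in range(geometry.n_atoms):
        x, y, z = geometry.coordinates[i]
        parts = [f"{geometry.elements[i]:<2s}", f"{x:18.10f}", f"{y:18.10f}",
                 f"{z:18.10f}"]
        if geometry.hirshfeld_ratios is not None:
            parts.append(f"{geometry.hirshfeld_ratios[i]:12.6f}")
        if geometry.labels is not None:
            parts.append(geometry.labels[i])
        lines.append(" ".join(parts))
    Path(path).write_text("\n".join(lines) + "\n")
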