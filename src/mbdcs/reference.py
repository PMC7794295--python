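"""Free-atom reference data.

Each element carries a static dipole polarizability ``alpha`` (Bohr^3), a
homo-atomic dispersion coefficient ``c6`` (Hartree*Bohr^6) and a van der
Waals radius ``r_vdw`` (Bohr).  These are the free-atom quantities that
Hirshfeld volume ratios rescale to atom-in-molecule values.

The shipped table lives in ``data/free_atom.dat``; a user table with the
same plain-text layout can be loaded with :func:`load_table`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

from .errors import ParameterTableError, ValidationError

__all__ = ["FreeAtomEntry", "FreeAtomReference", "load_table", "default_table",
           "ATOMIC_NUMBERS"]

ATOMIC_NUMBERS: Mapping[str, int] = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Br": 35, "Kr": 36,
    "I": 53, "Xe": 54,
}


@dataclass(frozen=True)
class FreeAtomEntry:
    symbol: str
    alpha: float   # Bohr^3
    c6: float      # Hartree * Bohr^6
    r_vdw: float   # Bohr

    def __post_init__(self) -> None:
        if min(self.alpha, self.c6, self.r_vdw) <= 0:
            raise ValidationError(
                f"free-atom entry for {self.symbol!r} must be strictly positive"
            )


class FreeAtomReference:
    """Lookup table of per-element free-atom reference parameters."""

    def __init__(self, entries: Mapping[str, FreeAtomEntry]):
        if not entries:
            raise ValidationError("free-atom table is empty")
        self._entries = dict(entries)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._entries

    def __getitem__(self, symbol: str) -> FreeAtomEntry:
        try:
            return self._entries[symbol]
        except KeyError:
            raise ParameterTableError(
                f"element {symbol!r} not in the free-atom reference table"
            ) from None

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(self._entries)


def load_table(path: str | Path) -> FreeAtomReference:
    """Parse a plain-text free-atom table (symbol, alpha, C6, R_vdw per line)."""
    entries: dict[str, FreeAtomEntry] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 4:
            raise ValidationError(f"malformed free-atom table line: {raw!r}")
        symbol = fields[0]
        alpha, c6, r_vdw = (float(x) for x in fields[1:])
        entries[symbol] = FreeAtomEntry(symbol, alpha, c6, r_vdw)
    return FreeAtomReference(entries)


_DEFAULT: FreeAtomReference | None = None


def default_table() -> FreeAtomReference:
    """The table shipped with the package (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        with resources.as_file(
            resources.files("mbdcs").joinpath("data/free_atom.dat")
        ) as path:
            _DEFAULT = load_table(path)
    return _DEFAULT
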