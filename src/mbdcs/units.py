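"""Unit conversion constants.

All internal arithmetic is done in Hartree atomic units (Hartree, Bohr,
electron mass, elementary charge).  Geometry I/O uses Ångström; energy
reports additionally carry eV and kJ/mol.
"""

BOHR_RADIUS_ANGSTROM = 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_RADIUS_ANGSTROM
BOHR_TO_ANGSTROM = BOHR_RADIUS_ANGSTROM

HARTREE_TO_EV = 27.211386245988
HARTREE_TO_KJMOL = 2625.4996394799
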