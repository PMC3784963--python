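"""Residue-level physical constants.

Average residue masses are the ExPASy/standard values (Da) for amino-acid
*residues*, i.e. the monomer mass minus one water; a free peptide's average
mass is the residue sum plus one water.  Monoisotopic masses used for the
m/z observability window come from :mod:`pyteomics.mass` and are not
duplicated here.
"""

from __future__ import annotations

STANDARD_RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"

#: Average (isotope-abundance-weighted) residue masses, Da.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "G": 57.0519,
    "A": 71.0788,
    "S": 87.0782,
    "P": 97.1167,
    "V": 99.1326,
    "T": 101.1051,
    "C": 103.1388,
    "L": 113.1594,
    "I": 113.1594,
    "N": 114.1038,
    "D": 115.0886,
    "Q": 128.1307,
    "K": 128.1741,
    "E": 129.1155,
    "M": 131.1926,
    "H": 137.1411,
    "F": 147.1766,
    "R": 156.1875,
    "Y": 163.1760,
    "W": 186.2132,
}

#: Average mass of one water molecule, Da (added once per free peptide chain).
WATER_AVERAGE_MASS: float = 18.0153

#: Mean of the 20 average residue masses; used for 'X' in permissive mode.
MEAN_RESIDUE_MASS: float = sum(AVERAGE_RESIDUE_MASS.values()) / 20.0

#: Letters that are legal in some databases but not standard residues.
NONSTANDARD_LETTERS: frozenset[str] = frozenset("BZXUO")
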