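"""In-silico tryptic digestion and the peptide observability window.

emPAI's denominator is the number of peptides an instrument could in
principle have observed for a protein.  We reconstruct it from the
acquisition settings of a typical nanoLC–Orbitrap run on a gel-separated
nucleoid fraction: trypsin/P cleavage (cut after every K or R, no proline
exception) with up to 2 missed cleavages, precursors surveyed between
m/z 350 and m/z 1800 with only 2+ and 3+ charge states selected, and a
conventional minimum identifiable length of 6 residues.  Duplicate peptide
sequences within one protein count once, matching the distinct-peptide
convention of the numerator.
"""

from __future__ import annotations

from dataclasses import dataclass

from pyteomics import mass as _pmass

from .proteome import validate_sequence


@dataclass(frozen=True)
class Peptide:
    """A tryptic fragment located within its parent sequence.

    ``start``/``end`` are 0-based, end-exclusive coordinates in the parent;
    ``missed_cleavages`` counts internal uncut K/R sites.
    """

    sequence: str
    start: int
    end: int
    missed_cleavages: int


@dataclass(frozen=True)
class ObservabilityWindow:
    """Instrument-side constraints deciding which peptides are countable."""

    mz_min: float = 350.0
    mz_max: float = 1800.0
    charges: frozenset[int] = frozenset({2, 3})
    min_length: int = 6
    max_missed_cleavages: int = 2

    def __post_init__(self) -> None:
        if self.mz_min >= self.mz_max:
            raise ValueError("mz_min must be < mz_max")
        if not self.charges:
            raise ValueError("charges must be non-empty")
        object.__setattr__(self, "charges", frozenset(int(z) for z in self.charges))


def cleavage_sites(sequence: str) -> list[int]:
    """Positions after which trypsin/P cuts (index of the residue C-terminal side)."""
    return [i + 1 for i, aa in enumerate(sequence) if aa in "KR"]


def digest(sequence: str, max_missed_cleavages: int = 2) -> list[Peptide]:
    """Enumerate tryptic peptides with 0..max_missed_cleavages internal sites.

    The 0-missed-cleavage fragments partition the parent; peptides are
    returned ordered by (start, end).  An empty sequence yields an empty
    list.
    """
    if max_missed_cleavages < 0:
        raise ValueError("max_missed_cleavages must be >= 0")
    if not sequence:
        return []
    seq = validate_sequence(sequence)
    bounds = [0] + [b for b in cleavage_sites(seq) if b < len(seq)] + [len(seq)]
    peptides: list[Peptide] = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + max_missed_cleavages, len(bounds))):
            start, end = bounds[i], bounds[j]
            peptides.append(Peptide(seq[start:end], start, end, j - i - 1))
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def peptide_mz(peptide_sequence: str, charge: int) -> float:
    """m/z of a peptide at a given positive charge state.

    (monoisotopic neutral mass + charge × proton mass) / charge, with
    monoisotopic residue masses from pyteomics.
    """
    if charge < 1:
        raise ValueError("charge must be >= 1")
    seq = validate_sequence(peptide_sequence)
    return _pmass.fast_mass(seq, charge=charge)


def observable_peptides(sequence: str, window: ObservabilityWindow = ObservabilityWindow()) -> set[str]:
    """Distinct peptide sequences passing length and m/z constraints."""
    out: set[str] = set()
    for pep in digest(sequence, window.max_missed_cleavages):
        if len(pep.sequence) < window.min_length or pep.sequence in out:
            continue
        if any(window.mz_min <= peptide_mz(pep.sequence, z) <= window.mz_max for z in window.charges):
            out.add(pep.sequence)
    return out


def count_observable(sequence: str, window: ObservabilityWindow = ObservabilityWindow()) -> int:
    """Number of distinct observable tryptic peptides — emPAI's denominator."""
    return len(observable_peptides(sequence, window))
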