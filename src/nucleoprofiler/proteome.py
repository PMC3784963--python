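"""Protein records, functional categorisation, and sequence physico-chemistry.

Proteins identified in a nucleoid fraction are binned into five functional
categories, following the convention used for nucleoid surveys:

* ``R`` — 30S/50S ribosomal and ribosome-associated proteins
* ``C`` — chaperones, cold-shock and redox-protective proteins
* ``D`` — annotated DNA-binding proteins (transcriptional regulators)
* ``U`` — proteins of unknown function
* ``E`` — metabolic enzymes, cytosolic and membrane proteins

Category assignment is driven by keyword rules over the free-text protein
description, with an explicit per-accession override table taking precedence
and a default of ``U`` guaranteeing totality.

Molecular weight uses the average residue mass table in
:mod:`nucleoprofiler.constants`; the isoelectric point solves the
Henderson–Hasselbalch net-charge equation by bisection under a named,
configurable pKa set (see ``data/pka_sets.json``).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .constants import (
    AVERAGE_RESIDUE_MASS,
    MEAN_RESIDUE_MASS,
    STANDARD_RESIDUES,
    WATER_AVERAGE_MASS,
)

CATEGORIES = ("R", "C", "D", "U", "E")

#: Default FASTA header grammar: ``>ACCESSION|LOCUS description``.
DEFAULT_HEADER_PATTERN = r"^(?P<accession>[^|\s]+)\|(?P<locus_tag>\S+)\s*(?P<name>.*)$"


class SequenceError(ValueError):
    """Raised for empty sequences or disallowed residue letters."""


@dataclass
class ProteinRecord:
    """One protein: identity, sequence and (optionally) functional category."""

    accession: str
    locus_tag: str = ""
    name: str = ""
    sequence: str = ""
    category: str | None = None

    def __post_init__(self) -> None:
        if self.category is not None and self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}, got {self.category!r}")


@dataclass(frozen=True)
class CategoryRule:
    """Keyword/regex rule over the protein description; lower priority wins."""

    pattern: str
    category: str
    priority: int

    def matches(self, description: str) -> bool:
        return re.search(self.pattern, description, flags=re.IGNORECASE) is not None


def validate_sequence(sequence: str, *, permissive: bool = False) -> str:
    """Upper-case and check a residue string.

    By default any letter outside the 20 standard residues raises
    :class:`SequenceError` — silently guessing masses would corrupt
    observable-peptide counts downstream.  In permissive mode ``X`` is
    tolerated (it is mapped to the mean residue mass for MW and excluded
    from composition features); the ambiguity codes B/Z/U/O always raise.
    """
    seq = sequence.upper()
    if not seq:
        raise SequenceError("empty sequence")
    allowed = set(STANDARD_RESIDUES) | ({"X"} if permissive else set())
    bad = sorted(set(seq) - allowed)
    if bad:
        raise SequenceError(f"nonstandard residue letter(s): {''.join(bad)}")
    return seq


def read_fasta(path: str | Path, header_pattern: str = DEFAULT_HEADER_PATTERN) -> list[ProteinRecord]:
    """Read a protein FASTA into records (category unset).

    The header grammar is a regex with named groups ``accession``,
    ``locus_tag`` (optional) and ``name`` (optional); the default handles
    ``>ACC|LOCUS description`` headers.  Duplicate accessions are an error.
    """
    rx = re.compile(header_pattern)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        header = entry.description
        m = rx.match(header)
        if m is None:
            raise ValueError(f"FASTA header does not match the header grammar: >{header}")
        groups = m.groupdict()
        accession = groups["accession"]
        if accession in seen:
            raise ValueError(f"duplicate accession in FASTA: {accession}")
        seen.add(accession)
        records.append(
            ProteinRecord(
                accession=accession,
                locus_tag=groups.get("locus_tag") or "",
                name=(groups.get("name") or "").strip(),
                sequence=validate_sequence(str(entry.seq)),
            )
        )
    return records


def load_category_rules(path: str | Path) -> list[CategoryRule]:
    """Load a TSV of (pattern, category, priority) rules."""
    df = pd.read_csv(path, sep="\t", dtype={"pattern": str, "category": str, "priority": int})
    for col in ("pattern", "category", "priority"):
        if col not in df.columns:
            raise ValueError(f"category-rule file is missing column {col!r}")
    return [CategoryRule(r.pattern, r.category, int(r.priority)) for r in df.itertuples()]


def default_category_rules() -> list[CategoryRule]:
    """The keyword rules shipped with the package (see data/category_rules.tsv)."""
    with resources.files("nucleoprofiler.data").joinpath("category_rules.tsv").open("rb") as fh:
        df = pd.read_csv(fh, sep="\t")
    return [CategoryRule(r.pattern, r.category, int(r.priority)) for r in df.itertuples()]


def assign_categories(
    records: Iterable[ProteinRecord],
    rules: Sequence[CategoryRule],
    overrides: Mapping[str, str] | None = None,
) -> list[ProteinRecord]:
    """Assign every record exactly one category.

    Per-accession ``overrides`` beat pattern rules; among pattern rules the
    lowest priority wins; a protein matching nothing falls to ``U``.  The
    operation is total and idempotent.
    """
    if not rules:
        raise ValueError("rules must be non-empty")
    overrides = overrides or {}
    ordered = sorted(rules, key=lambda r: r.priority)
    out: list[ProteinRecord] = []
    for rec in records:
        if rec.accession in overrides:
            cat = overrides[rec.accession]
        else:
            cat = next((r.category for r in ordered if r.matches(rec.name)), "U")
        out.append(replace(rec, category=cat))
    return out


def load_annotations(path: str | Path) -> pd.DataFrame:
    """Read an annotation TSV (accession, locus_tag, description, category_override).

    ``category_override`` may be empty; non-empty values must be one of the
    five category letters.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("accession", "locus_tag", "description", "category_override"):
        if col not in df.columns:
            raise ValueError(f"annotation file is missing column {col!r}")
    bad = df.loc[~df.category_override.isin(list(CATEGORIES) + [""]), "category_override"]
    if len(bad):
        raise ValueError(f"invalid category_override value(s): {sorted(set(bad))}")
    return df


# ---------------------------------------------------------------------------
# Physico-chemical features


def molecular_weight(sequence: str, *, permissive: bool = False) -> float:
    """Average molecular weight of the chain in kDa.

    Sum of average residue masses plus one water.  In permissive mode ``X``
    contributes the mean residue mass.
    """
    seq = validate_sequence(sequence, permissive=permissive)
    dalton = WATER_AVERAGE_MASS + sum(
        MEAN_RESIDUE_MASS if aa == "X" else AVERAGE_RESIDUE_MASS[aa] for aa in seq
    )
    return dalton / 1000.0


def load_pka_set(name: str = "bjellqvist") -> dict:
    """Load one of the named pKa configurations shipped with the package."""
    with resources.files("nucleoprofiler.data").joinpath("pka_sets.json").open() as fh:
        sets = json.load(fh)
    if name not in sets:
        raise KeyError(f"unknown pKa set {name!r}; available: {sorted(sets)}")
    return sets[name]


def net_charge(sequence: str, ph: float, pka: Mapping | None = None) -> float:
    """Henderson–Hasselbalch net charge of the chain at a given pH."""
    pka = pka or load_pka_set()
    seq = validate_sequence(sequence, permissive=True)
    charge = 1.0 / (1.0 + 10.0 ** (ph - pka["n_term"]))
    charge -= 1.0 / (1.0 + 10.0 ** (pka["c_term"] - ph))
    for aa, pk in pka["positive"].items():
        charge += seq.count(aa) / (1.0 + 10.0 ** (ph - pk))
    for aa, pk in pka["negative"].items():
        charge -= seq.count(aa) / (1.0 + 10.0 ** (pk - ph))
    return charge


def isoelectric_point(sequence: str, pka_set: str | Mapping = "bjellqvist", tol: float = 1e-4) -> float:
    """pH at which the modelled net charge is zero, by bisection on [0, 14].

    The charge is strictly decreasing in pH, so the root is unique; the
    bracket endpoints are expanded in the (theoretical) case of a root
    outside [0, 14].
    """
    pka = load_pka_set(pka_set) if isinstance(pka_set, str) else pka_set
    lo, hi = 0.0, 14.0
    # charge(0) > 0 > charge(14) for every valid sequence under these sets.
    # Iterate past the pH tolerance until the *charge* residual is also small:
    # the charge slope grows with the number of ionisable groups, so a fixed
    # pH interval alone would not bound the residual.
    for _ in range(64):
        mid = (lo + hi) / 2.0
        c = net_charge(sequence, mid, pka)
        if hi - lo < tol and abs(c) < tol:
            break
        if c > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0
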