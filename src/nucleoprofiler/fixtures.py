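"""Loaders for the small curated datasets shipped with the package.

``sco_nucleoid_candidates.tsv`` transcribes the published 24-protein
candidate table from a label-free LC–MS/MS survey of isolated
*Streptomyces coelicolor* nucleoids: per-replicate emPAI scores and ranks,
externally computed composition-based DNA-binder scores for the
uncharacterised rows, molecular weight, pI and the experimentally verified
NAP/GR flags.  It serves as the in-study reference dataset for the
selection procedure — published emPAI values go in, the 24-row candidate
list should come out.

``known_naps.tsv`` is the curated list of candidates with prior
experimental support (HupA, HupS, sIHF, Lsr2, BldD, CRP); it is data, not
code, because the flags cite external studies rather than a computation.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _read(name: str, **kw) -> pd.DataFrame:
    with resources.files("nucleoprofiler.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh, sep="\t", **kw)


def load_study_table() -> pd.DataFrame:
    """The published 24-candidate table (wide, one row per protein)."""
    df = _read("sco_nucleoid_candidates.tsv")
    df["known_nap"] = df["known_nap"].astype(bool)
    return df


def load_known_naps() -> set[str]:
    """Accessions of candidates with prior experimental verification."""
    return set(_read("known_naps.tsv")["accession"])


def study_abundance() -> pd.DataFrame:
    """Long-format abundance records built from the published emPAI columns.

    Returns columns accession, replicate, empai, category — the shape the
    selection step consumes.  Peptide counts are not printed in the source
    table, so only emPAI is carried.
    """
    wide = load_study_table()
    rows = []
    for rep in ("rep1", "rep2"):
        col = f"empai_{rep}"
        for r in wide.itertuples():
            rows.append((r.accession, rep, float(getattr(r, col)), r.category))
    return pd.DataFrame(rows, columns=["accession", "replicate", "empai", "category"])


def study_binding_scores() -> dict[str, float]:
    """Published composition-based binder scores (uncharacterised rows only)."""
    wide = load_study_table()
    u = wide.loc[wide["dnabinder_score"].notna()]
    return dict(zip(u["accession"], u["dnabinder_score"].astype(float)))


def study_physchem() -> pd.DataFrame:
    """Published MW (kDa) and pI columns, keyed by accession."""
    wide = load_study_table()
    return wide[["accession", "mw_kda", "pi"]].copy()
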