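"""emPAI quantification from peptide-identification evidence.

The exponentially modified protein abundance index estimates relative
protein abundance from peptide coverage alone:

    PAI   = N_observed / N_observable
    emPAI = 10**PAI - 1

where ``N_observed`` is the number of distinct identified peptide sequences
for the protein in one replicate (gel slices merged, expect-value filtered)
and ``N_observable`` is the in-silico count from
:func:`nucleoprofiler.digest.count_observable`.  emPAI values are not
comparable across samples, so within-sample rank accompanies every score.

Evidence rows emulate a search-engine peptide export with columns
``accession, peptide, expect, replicate, slice``; extra columns are ignored.
"""

from __future__ import annotations

from typing import Callable, Mapping

import pandas as pd

from .digest import ObservabilityWindow, count_observable
from .proteome import ProteinRecord

EVIDENCE_COLUMNS = ("accession", "peptide", "expect", "replicate", "slice")

#: Default per-peptide expect-value significance cut-off.
DEFAULT_EXPECT_THRESHOLD = 0.05


def read_evidence(path) -> pd.DataFrame:
    """Read a peptide-evidence TSV; extra columns are dropped."""
    df = pd.read_csv(path, sep="\t", dtype={"accession": str, "peptide": str,
                                            "replicate": str, "slice": str})
    missing = [c for c in EVIDENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"evidence file is missing column(s): {', '.join(missing)}")
    df = df.loc[:, list(EVIDENCE_COLUMNS)].copy()
    df["expect"] = df["expect"].astype(float)
    if (df["expect"] < 0).any():
        raise ValueError("expect values must be >= 0")
    if (df["peptide"].str.len() == 0).any() or df["peptide"].isna().any():
        raise ValueError("peptide sequences must be non-empty")
    return df


def filter_evidence(evidence: pd.DataFrame, expect_threshold: float = DEFAULT_EXPECT_THRESHOLD) -> pd.DataFrame:
    """Keep rows with expect <= threshold and merge gel slices within a replicate.

    The boundary is inclusive (a peptide at exactly the threshold is kept).
    The slice label is dropped; a peptide seen in several slices of one
    replicate will still contribute once to the distinct-peptide count.
    """
    if expect_threshold <= 0:
        raise ValueError("expect_threshold must be > 0")
    kept = evidence.loc[evidence["expect"] <= expect_threshold]
    return kept.drop(columns="slice").reset_index(drop=True)


def compute_empai(
    evidence: pd.DataFrame,
    proteome: Mapping[str, ProteinRecord],
    window: ObservabilityWindow = ObservabilityWindow(),
    observable_counts: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per (accession, replicate) abundance records.

    Returns a DataFrame with columns accession, replicate, n_observed,
    n_observable, pai, empai.  Proteins with no evidence in a replicate are
    absent from that replicate's records (emPAI undefined, not zero).
    ``observable_counts`` lets callers supply pre-computed denominators
    (e.g. cached across replicates).
    """
    unknown = sorted(set(evidence["accession"]) - set(proteome))
    if unknown:
        raise KeyError(f"evidence accessions missing from proteome: {', '.join(unknown)}")
    counts = dict(observable_counts or {})
    rows = []
    grouped = evidence.groupby(["accession", "replicate"], sort=True)["peptide"].nunique()
    for (acc, rep), n_obs in grouped.items():
        if acc not in counts:
            counts[acc] = count_observable(proteome[acc].sequence, window)
        n_observable = counts[acc]
        if n_observable < 1:
            raise ValueError(
                f"protein {acc} has identified peptides but zero observable peptides; "
                "check the observability window"
            )
        pai = n_obs / n_observable
        rows.append((acc, rep, int(n_obs), int(n_observable), pai, 10.0 ** pai - 1.0))
    return pd.DataFrame(rows, columns=["accession", "replicate", "n_observed",
                                       "n_observable", "pai", "empai"])


def rank_by_empai(
    records: pd.DataFrame,
    scope: Callable[[pd.Series], bool] | None = None,
) -> pd.DataFrame:
    """Rank records by descending emPAI within each replicate.

    ``scope`` is an optional row predicate (e.g. restrict to category D);
    rows outside scope are dropped.  Ranks are 1-based and, with ties broken
    by ascending accession, form a permutation of 1..n within each
    replicate — a deterministic, reproducible ordering.
    """
    df = records if scope is None else records.loc[records.apply(scope, axis=1)]
    df = df.sort_values(["replicate", "empai", "accession"],
                        ascending=[True, False, True], kind="mergesort").copy()
    df["rank"] = df.groupby("replicate").cumcount() + 1
    return df.reset_index(drop=True)


def composition_summary(records: pd.DataFrame, categories: Mapping[str, str]) -> pd.DataFrame:
    """Summed emPAI per functional category, as a percentage of the total.

    ``categories`` maps accession -> category letter; detected proteins
    missing from the map default to U (incompletely annotated genomes are
    the norm, not an error).  Returns one row per (replicate, category)
    with columns replicate, category, summed_empai, percent; percentages
    within a replicate sum to 100.
    """
    df = records.copy()
    df["category"] = df["accession"].map(lambda a: categories.get(a, "U"))
    sums = (df.groupby(["replicate", "category"], sort=True)["empai"]
              .sum().rename("summed_empai").reset_index())
    totals = sums.groupby("replicate")["summed_empai"].transform("sum")
    sums["percent"] = 100.0 * sums["summed_empai"] / totals
    return sums
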