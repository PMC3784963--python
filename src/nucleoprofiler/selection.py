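"""Candidate NAP/GR selection: the "ruling in" screen.

Nucleoid fractions contain genuine nucleoid-associated proteins and global
regulators mixed with abundant contaminants (ribosomes, chaperones,
metabolic enzymes).  Rather than subtracting other subcellular fractions —
which is known to discard bona-fide NAPs — the screen *rules in* the most
promising candidates from the detected list as it stands:

1. within each replicate, keep the ``top_n_d`` most abundant annotated
   DNA-binding proteins (category D) by emPAI;
2. take the emPAI of the last protein kept as that replicate's abundance
   threshold, and screen every *uncharacterised* (category U) protein with
   emPAI strictly above it through the composition-based binding score —
   scores strictly above zero pass;
3. intersect the per-replicate selected sets: a protein seen in only one
   replicate is treated as a possible contaminant and dropped;
4. report the surviving D ∪ U set, re-ranked by emPAI over the merged
   candidate pool within each replicate ("amalgamated rank").

The per-replicate cut followed by a both-replicates intersection is the
strictest reading of the procedure and is the default; it is deliberately
explicit rather than configurable magic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .empai import rank_by_empai
from .proteome import ProteinRecord, isoelectric_point, molecular_weight


@dataclass(frozen=True)
class SelectionConfig:
    """Knobs of the selection procedure."""

    top_n_d: int = 30
    binder_threshold: float = 0.0
    require_both_replicates: bool = True

    def __post_init__(self) -> None:
        if self.top_n_d < 1:
            raise ValueError("top_n_d must be >= 1")


def abundance_threshold(
    d_records: pd.DataFrame, top_n_d: int = 30
) -> dict[str, tuple[set[str], float]]:
    """Top-``top_n_d`` category-D proteins and the threshold emPAI, per replicate.

    ``d_records`` holds the category-D abundance rows (accession, replicate,
    empai).  The threshold is the emPAI of the rank-``top_n_d`` protein;
    with fewer than ``top_n_d`` proteins, all are selected, the threshold is
    the minimum, and a warning is emitted.
    """
    if top_n_d < 1:
        raise ValueError("top_n_d must be >= 1")
    ranked = rank_by_empai(d_records)
    out: dict[str, tuple[set[str], float]] = {}
    for rep, grp in ranked.groupby("replicate"):
        if len(grp) < top_n_d:
            warnings.warn(
                f"replicate {rep}: only {len(grp)} category-D proteins for top_n_d={top_n_d}; "
                "selecting all", stacklevel=2)
        kept = grp.loc[grp["rank"] <= top_n_d]
        out[str(rep)] = (set(kept["accession"]), float(kept["empai"].min()))
    return out


def screen_uncharacterised(
    u_records: pd.DataFrame,
    thresholds: Mapping[str, float],
    scores: Mapping[str, float],
    binder_threshold: float = 0.0,
) -> dict[str, set[str]]:
    """Category-U proteins passing both the abundance cut and the binding screen.

    A protein passes in a replicate when its emPAI is *strictly* greater
    than that replicate's threshold and its binding score is strictly above
    ``binder_threshold``.  A missing score for an above-threshold protein is
    an error (the screen cannot silently pass or fail it).
    """
    out: dict[str, set[str]] = {}
    for rep, grp in u_records.groupby("replicate"):
        rep = str(rep)
        thr = thresholds[rep]
        above = grp.loc[grp["empai"] > thr]
        missing = sorted(set(above["accession"]) - set(scores))
        if missing:
            raise KeyError(
                f"replicate {rep}: no binding score for above-threshold "
                f"uncharacterised protein(s): {', '.join(missing)}")
        out[rep] = {a for a in above["accession"] if scores[a] > binder_threshold}
    return out


def intersect_replicates(per_replicate_sets: Mapping[str, set[str]]) -> set[str]:
    """Proteins selected in every replicate (contaminant guard)."""
    if len(per_replicate_sets) < 2:
        raise ValueError("replicate intersection needs at least 2 replicates")
    sets = list(per_replicate_sets.values())
    out = set(sets[0])
    for s in sets[1:]:
        out &= s
    return out


def build_candidate_table(
    selected_d: set[str],
    selected_u: set[str],
    abundance: pd.DataFrame,
    proteome: Mapping[str, ProteinRecord] | None = None,
    known_naps: set[str] | None = None,
    binding_scores: Mapping[str, float] | None = None,
    physchem: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Merged candidate table, one row per candidate.

    The table mirrors a publishable candidate list: identity, category,
    known-NAP flag, binding score (uncharacterised proteins only), MW (kDa),
    pI, and per-replicate emPAI plus *amalgamated rank* — the 1-based rank
    recomputed by emPAI over the merged D+U candidate pool within each
    replicate.  Rows are sorted by the first replicate's amalgamated rank.

    MW/pI come from ``proteome`` sequences when available, otherwise from a
    ``physchem`` table (accession, mw_kda, pi) — useful when consuming a
    published table without its sequences.
    """
    clash = selected_d & selected_u
    if clash:
        raise ValueError(f"accession(s) in both D and U selections: {', '.join(sorted(clash))}")
    known_naps = known_naps or set()
    binding_scores = binding_scores or {}
    merged = selected_d | selected_u
    if not merged:
        return _empty_candidates(abundance)

    pool = abundance.loc[abundance["accession"].isin(merged)]
    ranked = rank_by_empai(pool)
    reps = sorted(ranked["replicate"].unique())
    wide = ranked.pivot(index="accession", columns="replicate", values=["empai", "rank"])

    phys = {}
    if physchem is not None:
        phys = physchem.set_index("accession")[["mw_kda", "pi"]].to_dict("index")

    rows = []
    for acc in sorted(merged):
        cat = "D" if acc in selected_d else "U"
        rec = (proteome or {}).get(acc)
        if rec is not None and rec.sequence:
            mw, pi = molecular_weight(rec.sequence), isoelectric_point(rec.sequence)
        elif acc in phys:
            mw, pi = float(phys[acc]["mw_kda"]), float(phys[acc]["pi"])
        else:
            mw, pi = np.nan, np.nan
        row = {
            "accession": acc,
            "locus_tag": rec.locus_tag if rec else "",
            "name": rec.name if rec else "",
            "category": cat,
            "known_nap": acc in known_naps,
            "binding_score": binding_scores.get(acc, np.nan) if cat == "U" else np.nan,
            "mw_kda": mw,
            "pi": pi,
        }
        for rep in reps:
            row[f"empai_{rep}"] = float(wide.loc[acc, ("empai", rep)])
            row[f"rank_{rep}"] = int(wide.loc[acc, ("rank", rep)])
        rows.append(row)
    table = pd.DataFrame(rows).sort_values(f"rank_{reps[0]}").reset_index(drop=True)
    return table


def _empty_candidates(abundance: pd.DataFrame) -> pd.DataFrame:
    reps = sorted(abundance["replicate"].unique())
    cols = ["accession", "locus_tag", "name", "category", "known_nap",
            "binding_score", "mw_kda", "pi"]
    for rep in reps:
        cols += [f"empai_{rep}", f"rank_{rep}"]
    return pd.DataFrame(columns=cols)


@dataclass
class SelectionResult:
    """Everything the screen computed, for reporting and inspection."""

    candidates: pd.DataFrame
    d_sets: dict[str, set[str]]
    u_sets: dict[str, set[str]]
    thresholds: dict[str, float]
    config: SelectionConfig


def select_candidates(
    abundance: pd.DataFrame,
    config: SelectionConfig = SelectionConfig(),
    binding_scores: Mapping[str, float] | None = None,
    proteome: Mapping[str, ProteinRecord] | None = None,
    known_naps: set[str] | None = None,
    physchem: pd.DataFrame | None = None,
) -> SelectionResult:
    """Run the full screen on an abundance table with a ``category`` column."""
    if "category" not in abundance.columns:
        raise ValueError("abundance table needs a 'category' column")
    binding_scores = binding_scores or {}
    d_records = abundance.loc[abundance["category"] == "D"]
    u_records = abundance.loc[abundance["category"] == "U"]
    d_result = abundance_threshold(d_records, config.top_n_d)
    thresholds = {rep: thr for rep, (_, thr) in d_result.items()}
    u_sets = screen_uncharacterised(u_records, thresholds, binding_scores,
                                    config.binder_threshold) if len(u_records) else \
        {rep: set() for rep in thresholds}
    per_rep = {rep: d_result[rep][0] | u_sets.get(rep, set()) for rep in d_result}
    if config.require_both_replicates:
        final = intersect_replicates(per_rep)
    else:
        final = set().union(*per_rep.values()) if per_rep else set()
    sel_d = {a for a in final if any(a in d_result[r][0] for r in d_result)}
    sel_u = final - sel_d
    table = build_candidate_table(sel_d, sel_u, abundance, proteome, known_naps,
                                  binding_scores, physchem)
    return SelectionResult(candidates=table, d_sets={r: s for r, (s, _) in d_result.items()},
                           u_sets=u_sets, thresholds=thresholds, config=config)


def write_report(result: SelectionResult, outdir: str | Path,
                 composition: pd.DataFrame | None = None) -> dict[str, Path]:
    """Write candidates.tsv and a human-readable summary.txt.

    Output is byte-identical across runs on identical input (fixed float
    formatting, fixed column order).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cand_path = outdir / "candidates.tsv"
    result.candidates.to_csv(cand_path, sep="\t", index=False, float_format="%.6g")

    lines = ["Candidate NAP/GR selection summary", "=" * 34, ""]
    lines.append(f"top_n_d: {result.config.top_n_d}")
    lines.append(f"binder_threshold: {result.config.binder_threshold:g}")
    lines.append(f"require_both_replicates: {result.config.require_both_replicates}")
    lines.append("")
    for rep in sorted(result.thresholds):
        lines.append(f"replicate {rep}: abundance threshold emPAI = "
                     f"{result.thresholds[rep]:.6g}; "
                     f"{len(result.d_sets[rep])} D selected, "
                     f"{len(result.u_sets.get(rep, set()))} U passed the screen")
    n = len(result.candidates)
    n_d = int((result.candidates["category"] == "D").sum()) if n else 0
    lines.append("")
    lines.append(f"final candidates: {n} ({n_d} category D, {n - n_d} category U)")
    if n:
        lines.append(f"known NAPs/GRs among candidates: {int(result.candidates['known_nap'].sum())}")
    if composition is not None and len(composition):
        lines.append("")
        lines.append("summed-emPAI composition (% of total):")
        for rep, grp in composition.groupby("replicate"):
            parts = ", ".join(f"{r.category} {r.percent:.1f}%" for r in grp.itertuples())
            lines.append(f"  {rep}: {parts}")
    summary_path = outdir / "summary.txt"
    summary_path.write_text("\n".join(lines) + "\n")
    return {"candidates": cand_path, "summary": summary_path}
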