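"""End-to-end orchestration: digest → quantify → screen → select → report.

A run is driven by a YAML config (flat keys, documented in
``validate_config``) plus input paths; it writes ``abundance.tsv``,
``composition.tsv``, ``candidates.tsv``, ``summary.txt`` and a
``run_log.json`` manifest (config snapshot, input checksums, package
version, seed, timestamp) sufficient to reproduce the run.  Outputs are
confined to the output directory and inputs are never mutated.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .binding import BindingModel, default_model, score_sequence
from .digest import ObservabilityWindow
from .empai import (DEFAULT_EXPECT_THRESHOLD, composition_summary, compute_empai,
                    filter_evidence, rank_by_empai, read_evidence)
from .fixtures import load_known_naps
from .proteome import (assign_categories, default_category_rules, load_annotations,
                       load_category_rules, read_fasta)
from .selection import SelectionConfig, select_candidates, write_report

# key -> (expected type(s), range check, description)
_SCHEMA: dict[str, tuple] = {
    "expect_threshold": ((int, float), lambda v: v > 0, "must be > 0"),
    "top_n_d": (int, lambda v: v >= 1, "must be >= 1"),
    "binder_threshold": ((int, float), lambda v: True, ""),
    "require_both_replicates": (bool, lambda v: True, ""),
    "seed": (int, lambda v: True, ""),
    "mz_min": ((int, float), lambda v: v > 0, "must be > 0"),
    "mz_max": ((int, float), lambda v: v > 0, "must be > 0"),
    "charges": (list, lambda v: len(v) > 0 and all(isinstance(z, int) and z >= 1 for z in v),
                "must be a non-empty list of positive integers"),
    "min_length": (int, lambda v: v >= 1, "must be >= 1"),
    "max_missed_cleavages": (int, lambda v: v >= 0, "must be >= 0"),
    "proteome": (str, lambda v: True, ""),
    "evidence": ((str, list), lambda v: True, ""),
    "annotations": (str, lambda v: True, ""),
    "category_rules": (str, lambda v: True, ""),
    "binding_model": (str, lambda v: True, ""),
    "binding_scores": (str, lambda v: True, ""),
}

DEFAULT_CONFIG: dict[str, Any] = {
    "expect_threshold": DEFAULT_EXPECT_THRESHOLD,
    "top_n_d": 30,
    "binder_threshold": 0.0,
    "require_both_replicates": True,
    "seed": 0,
    "mz_min": 350.0,
    "mz_max": 1800.0,
    "charges": [2, 3],
    "min_length": 6,
    "max_missed_cleavages": 2,
}


class ConfigError(ValueError):
    """Raised with one line per offending key."""


def validate_config(config: Mapping[str, Any] | str | Path) -> dict[str, Any]:
    """Validate a pipeline config and merge it over the defaults.

    Every key is checked for type and range; unknown keys are rejected.
    Accepts a mapping or a path to a YAML file.
    """
    if not isinstance(config, Mapping):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    errors = []
    for key, value in config.items():
        if key not in _SCHEMA:
            errors.append(f"{key}: unknown key")
            continue
        types, check, msg = _SCHEMA[key]
        # bool is an int subclass; keep the two apart
        if isinstance(value, bool) and types is int:
            errors.append(f"{key}: expected int, got bool")
        elif not isinstance(value, types):
            errors.append(f"{key}: expected {types}, got {type(value).__name__}")
        elif not check(value):
            errors.append(f"{key}: {msg}")
    merged = {**DEFAULT_CONFIG, **dict(config)}
    if merged["mz_min"] >= merged["mz_max"]:
        errors.append("mz_min: must be < mz_max")
    if errors:
        raise ConfigError("; ".join(errors))
    return merged


def window_from_config(config: Mapping[str, Any]) -> ObservabilityWindow:
    return ObservabilityWindow(
        mz_min=float(config["mz_min"]), mz_max=float(config["mz_max"]),
        charges=frozenset(config["charges"]), min_length=int(config["min_length"]),
        max_missed_cleavages=int(config["max_missed_cleavages"]))


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written once per run."""

    config: dict
    input_checksums: dict[str, str]
    package_version: str
    seed: int
    started: str

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True) + "\n")


def run_pipeline(
    config: Mapping[str, Any] | str | Path,
    out: str | Path,
    proteome: str | Path | None = None,
    evidence: Sequence[str | Path] | None = None,
    annotations: str | Path | None = None,
) -> Path:
    """Run the whole screen and write all outputs under ``out``.

    Input paths may live in the config or be passed explicitly (explicit
    wins).  Returns the output directory.
    """
    cfg = validate_config(config)
    proteome_path = Path(proteome or cfg.get("proteome", ""))
    ann_path = Path(annotations or cfg.get("annotations", ""))
    ev = evidence if evidence is not None else cfg.get("evidence")
    if ev is None:
        raise ConfigError("evidence: no evidence file(s) given")
    ev_paths = [Path(p) for p in ([ev] if isinstance(ev, (str, Path)) else ev)]
    if not proteome_path.name or not ann_path.name:
        raise ConfigError("proteome/annotations: input paths are required")

    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=dict(cfg), package_version=__version__, seed=int(cfg["seed"]),
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
        input_checksums={str(p): _sha256(p) for p in [proteome_path, ann_path, *ev_paths]})

    # --- proteome & categories
    records = read_fasta(proteome_path)
    ann = load_annotations(ann_path)
    overrides = {r.accession: r.category_override for r in ann.itertuples()
                 if r.category_override}
    desc = dict(zip(ann["accession"], ann["description"]))
    for rec in records:
        if not rec.name and rec.accession in desc:
            rec.name = desc[rec.accession]
    rules = (load_category_rules(cfg["category_rules"]) if "category_rules" in cfg
             else default_category_rules())
    records = assign_categories(records, rules, overrides)
    proteins = {r.accession: r for r in records}
    categories = {r.accession: r.category for r in records}

    # --- evidence -> emPAI
    window = window_from_config(cfg)
    evidence_df = pd.concat([read_evidence(p) for p in ev_paths], ignore_index=True)
    filtered = filter_evidence(evidence_df, float(cfg["expect_threshold"]))
    abundance = compute_empai(filtered, proteins, window)
    abundance["category"] = abundance["accession"].map(categories)
    ranked_all = rank_by_empai(abundance)
    ranked_all["locus_tag"] = ranked_all["accession"].map(
        lambda a: proteins[a].locus_tag)
    cols = ["accession", "locus_tag", "category", "replicate",
            "n_observed", "n_observable", "pai", "empai", "rank"]
    ranked_all[cols].to_csv(outdir / "abundance.tsv", sep="\t", index=False,
                            float_format="%.6g")

    comp = composition_summary(abundance, categories)
    comp.to_csv(outdir / "composition.tsv", sep="\t", index=False, float_format="%.6g")

    # --- binding scores: pass-through file wins over the model
    model: BindingModel = (BindingModel.load(cfg["binding_model"])
                           if "binding_model" in cfg else default_model())
    scores = {acc: score_sequence(rec.sequence, model)
              for acc, rec in proteins.items() if rec.category == "U" and rec.sequence}
    if "binding_scores" in cfg:
        ext = pd.read_csv(cfg["binding_scores"], sep="\t")
        scores.update(dict(zip(ext["accession"], ext["score"].astype(float))))

    sel_cfg = SelectionConfig(top_n_d=int(cfg["top_n_d"]),
                              binder_threshold=float(cfg["binder_threshold"]),
                              require_both_replicates=bool(cfg["require_both_replicates"]))
    result = select_candidates(abundance, sel_cfg, scores, proteins,
                               known_naps=load_known_naps())
    write_report(result, outdir, composition=comp)
    manifest.write(outdir / "run_log.json")
    return outdir
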