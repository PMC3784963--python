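"""Synthetic nucleoid-proteomics experiments with ground truth.

Emulates the statistical shape of a label-free LC–MS/MS survey of a
bacterial nucleoid fraction well enough to exercise the whole pipeline:

* a proteome of random sequences with a handful of *planted NAPs* —
  lysine/arginine/glutamate-enriched, basic-pI proteins standing in for
  HU/IHF-like nucleoid proteins — scattered among ribosomal, chaperone,
  enzymatic and uncharacterised background proteins;
* power-law true abundances (rank ``r`` gets abundance proportional to
  ``r**-alpha``), with planted NAPs biased toward the abundant end;
* two biological replicates whose abundances agree up to lognormal noise,
  calibrated analytically so the between-replicate Spearman rank
  correlation matches a configured target;
* peptide-level evidence in which each observable tryptic peptide of a
  protein is detected independently with probability ``1 - exp(-c * a)``
  — the simplest saturating observation model, reproducing the emPAI
  compression seen for very abundant proteins — with ``c`` calibrated by
  bisection so the expected number of peptide observations per replicate
  matches ``detection_capacity``; evidence is split over three gel-slice
  labels by peptide-mass tertile;
* a linearly separable labelled composition set for training the binding
  model, with a margin knob to make the classes overlap.

Every output is a deterministic function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass

from .constants import STANDARD_RESIDUES
from .digest import ObservabilityWindow, observable_peptides
from .proteome import ProteinRecord

# Approximate residue background frequencies of a bacterial proteome
# (UniProt-wide averages, renormalised over the 20 standard letters).
BACKGROUND_FREQS = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0138,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}

#: Multiplicative composition bias of planted NAPs (basic, K/R/E-enriched).
NAP_BIAS = {"K": 2.5, "R": 2.2, "E": 1.6, "D": 0.6, "L": 0.7, "I": 0.7, "V": 0.7, "F": 0.6}

#: Bias of synthetic non-binders (acidic / hydrophobic).
NONBINDER_BIAS = {"D": 1.8, "E": 1.3, "L": 1.4, "V": 1.3, "A": 1.3, "F": 1.3, "K": 0.4, "R": 0.4}

_CATEGORY_NAMES = {
    "R": "50S ribosomal protein (synthetic)",
    "C": "molecular chaperone (synthetic)",
    "D": "putative transcriptional regulator (synthetic)",
    "U": "uncharacterised protein (synthetic)",
    "E": "metabolic enzyme (synthetic)",
}


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic experiment."""

    n_proteins: int = 500
    n_planted_naps: int = 20
    category_proportions: dict[str, float] = field(
        default_factory=lambda: {"R": 0.08, "C": 0.07, "D": 0.10, "U": 0.25, "E": 0.50})
    power_law_exponent: float = 1.0
    replicate_correlation: float = 0.8
    detection_capacity: float = 5000.0
    seed: int = 0
    min_length: int = 60
    max_length: int = 400
    #: fraction of planted ranks drawn from — planted NAPs land in the top
    #: quarter of the abundance ranking (some, legitimately, below the decile)
    planted_rank_fraction: float = 0.25
    #: fraction of detected peptides given an expect value above 0.05
    expect_fail_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.n_planted_naps > self.n_proteins:
            raise ValueError("n_planted_naps must be <= n_proteins")
        if set(self.category_proportions) != set("RCDUE"):
            raise ValueError("category_proportions must cover exactly R, C, D, U, E")
        total = sum(self.category_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category proportions must sum to 1, got {total}")
        if self.power_law_exponent <= 0:
            raise ValueError("power_law_exponent must be > 0")
        if not 0.0 <= self.replicate_correlation <= 1.0:
            raise ValueError("replicate_correlation must be in [0, 1]")


def _biased_freqs(bias: dict[str, float], strength: float = 1.0) -> np.ndarray:
    """Background frequencies multiplied by per-residue biases, renormalised.

    ``strength`` interpolates the *log* bias between none (0) and full (1).
    """
    f = np.array([BACKGROUND_FREQS[aa] * (bias.get(aa, 1.0) ** strength)
                  for aa in STANDARD_RESIDUES])
    return f / f.sum()


def _random_sequence(rng: np.random.Generator, length: int, freqs: np.ndarray) -> str:
    return "".join(rng.choice(list(STANDARD_RESIDUES), size=length, p=freqs))


def generate_proteome(config: GeneratorConfig) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Random proteome plus a ground-truth table.

    Returns (records, truth) where truth has one row per protein with
    columns ``accession, locus_tag, category, is_planted_nap, is_binder``.
    Planted NAPs get category D or U and a K/R/E-shifted composition.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    cats = list("RCDUE")
    probs = np.array([config.category_proportions[c] for c in cats])
    categories = rng.choice(cats, size=n, p=probs)
    planted = np.zeros(n, dtype=bool)
    planted_idx = rng.choice(n, size=config.n_planted_naps, replace=False)
    planted[planted_idx] = True
    # planted NAPs sit in D or U (an unannotated NAP is the interesting case)
    categories[planted_idx] = rng.choice(["D", "U"], size=config.n_planted_naps, p=[0.6, 0.4])

    bg = _biased_freqs({}, 0.0)
    nap = _biased_freqs(NAP_BIAS)
    records, rows = [], []
    for i in range(n):
        length = int(rng.integers(config.min_length, config.max_length + 1))
        if planted[i]:
            length = int(rng.integers(config.min_length, min(150, config.max_length) + 1))
        seq = _random_sequence(rng, length, nap if planted[i] else bg)
        acc = f"SY{i:04d}"
        rec = ProteinRecord(accession=acc, locus_tag=f"SYL{i:04d}",
                            name=_CATEGORY_NAMES[categories[i]], sequence=seq,
                            category=categories[i])
        records.append(rec)
        rows.append((acc, rec.locus_tag, categories[i], bool(planted[i]), bool(planted[i])))
    truth = pd.DataFrame(rows, columns=["accession", "locus_tag", "category",
                                        "is_planted_nap", "is_binder"])
    return records, truth


def generate_abundances(truth: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Power-law abundances for two replicates.

    Abundance of rank ``r`` is ``r**-alpha``; planted NAPs receive ranks
    drawn from the top ``planted_rank_fraction`` of the list.  Replicate 1
    is the base; replicate 2 multiplies it by lognormal noise whose scale
    sigma is calibrated by bisection so that the Spearman rank correlation
    between the replicates matches ``replicate_correlation`` in
    expectation (estimated over a small set of noise draws held fixed
    across the bisection, so the whole procedure is deterministic given
    the seed).
    """
    rng = np.random.default_rng(config.seed + 1)
    n = len(truth)
    planted = truth["is_planted_nap"].to_numpy()
    top = max(int(np.floor(config.planted_rank_fraction * n)), planted.sum())
    ranks = np.empty(n, dtype=int)
    top_ranks = rng.choice(np.arange(1, top + 1), size=planted.sum(), replace=False)
    ranks[planted] = top_ranks
    rest = np.setdiff1d(np.arange(1, n + 1), top_ranks)
    rng.shuffle(rest)
    ranks[~planted] = rest
    base = ranks.astype(float) ** -config.power_law_exponent

    rho_s = config.replicate_correlation
    if rho_s >= 1.0:
        noise = np.ones(n)
    else:
        sigma = _calibrate_noise_scale(np.log(base), rho_s, config.seed)
        noise = np.exp(rng.normal(0.0, sigma, size=n))
    out = truth[["accession"]].copy()
    out["true_rank"] = ranks
    out["abundance_rep1"] = base
    out["abundance_rep2"] = base * noise
    return out


def _calibrate_noise_scale(log_base: np.ndarray, rho_s: float, seed: int,
                           n_draws: int = 8, n_iter: int = 30) -> float:
    """Noise sigma such that Spearman(log_base, log_base + sigma*W) ~= rho_s.

    The expected Spearman is estimated as the mean over ``n_draws`` standard
    normal draws, which are held fixed while sigma is bisected — the target
    function is then smooth and (to estimator noise) decreasing in sigma.
    """
    from scipy.stats import spearmanr

    if rho_s <= 0.0:
        # uncorrelated replicates: huge noise swamps the signal
        return 50.0 * max(np.std(log_base), 1.0)
    cal_rng = np.random.default_rng(seed + 101)
    W = cal_rng.standard_normal((n_draws, log_base.size))

    def mean_spearman(sigma: float) -> float:
        return float(np.mean([spearmanr(log_base, log_base + sigma * w).statistic
                              for w in W]))

    lo, hi = 0.0, np.std(log_base)
    while mean_spearman(hi) > rho_s:
        hi *= 2.0
        if hi > 1e3 * np.std(log_base):
            break
    for _ in range(n_iter):
        mid = (lo + hi) / 2.0
        if mean_spearman(mid) > rho_s:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def _calibrate_capacity(n_observable: np.ndarray, abundance: np.ndarray,
                        capacity: float) -> float:
    """Bisection for c in  sum_i n_i (1 - exp(-c a_i)) = capacity."""
    total = n_observable.sum()
    if capacity >= total:
        return 1e9 / max(abundance.min(), 1e-300)  # everything saturates

    def expected(c: float) -> float:
        return float(np.sum(n_observable * (1.0 - np.exp(-c * abundance))))

    lo, hi = 0.0, 1.0
    while expected(hi) < capacity:
        hi *= 2.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if expected(mid) < capacity:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def generate_evidence(
    records: list[ProteinRecord],
    abundances: pd.DataFrame,
    window: ObservabilityWindow = ObservabilityWindow(),
    config: GeneratorConfig = GeneratorConfig(),
) -> dict[str, pd.DataFrame]:
    """Peptide evidence tables keyed by replicate label ('rep1', 'rep2').

    Each observable peptide of each protein is detected independently with
    probability ``1 - exp(-c * abundance)``; detected peptides receive an
    expect value (a configurable fraction falls above the 0.05 cut) and a
    gel-slice label by monoisotopic-mass tertile.
    """
    rng = np.random.default_rng(config.seed + 2)
    peptides = {rec.accession: sorted(observable_peptides(rec.sequence, window))
                for rec in records}
    n_obs = np.array([len(peptides[a]) for a in abundances["accession"]])
    all_masses = np.array([_pmass.fast_mass(p)
                           for a in abundances["accession"] for p in peptides[a]])
    if all_masses.size == 0:
        return {"rep1": _empty_evidence(), "rep2": _empty_evidence()}
    t1, t2 = np.quantile(all_masses, [1 / 3, 2 / 3])

    out: dict[str, pd.DataFrame] = {}
    for rep in ("rep1", "rep2"):
        ab = abundances[f"abundance_{rep}"].to_numpy()
        c = _calibrate_capacity(n_obs, ab, config.detection_capacity)
        rows = []
        for acc, a in zip(abundances["accession"], ab):
            peps = peptides[acc]
            if not peps or a <= 0:
                continue
            p_detect = 1.0 - np.exp(-c * a)
            detected = rng.random(len(peps)) < p_detect
            for pep, hit in zip(peps, detected):
                if not hit:
                    continue
                if rng.random() < config.expect_fail_fraction:
                    expect = rng.uniform(0.0501, 1.0)
                else:
                    expect = rng.uniform(1e-4, 0.05)
                m = _pmass.fast_mass(pep)
                slice_label = "S1" if m <= t1 else ("S2" if m <= t2 else "S3")
                rows.append((acc, pep, expect, rep, slice_label))
        out[rep] = pd.DataFrame(rows, columns=["accession", "peptide", "expect",
                                               "replicate", "slice"]) if rows else _empty_evidence(rep)
    return out


def _empty_evidence(rep: str = "rep1") -> pd.DataFrame:
    return pd.DataFrame(columns=["accession", "peptide", "expect", "replicate", "slice"])


def generate_binding_fixture(
    config: GeneratorConfig = GeneratorConfig(),
    n_per_class: int = 60,
    margin: float = 1.0,
    length_range: tuple[int, int] = (80, 200),
) -> pd.DataFrame:
    """Labelled composition training set (accession, sequence, label).

    Binders draw residues from the K/R/E-enriched NAP distribution,
    non-binders from an acidic/hydrophobic one; ``margin`` interpolates
    both class distributions toward the shared background (0 = identical
    classes, 1 = full separation).
    """
    rng = np.random.default_rng(config.seed + 3)
    f_bind = _biased_freqs(NAP_BIAS, margin)
    f_non = _biased_freqs(NONBINDER_BIAS, margin)
    rows = []
    for i in range(n_per_class):
        for label, freqs, tag in ((1, f_bind, "BIND"), (0, f_non, "NONB")):
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            rows.append((f"{tag}{i:03d}", _random_sequence(rng, length, freqs), label))
    return pd.DataFrame(rows, columns=["accession", "sequence", "label"])


def write_experiment(config: GeneratorConfig, outdir: str | Path,
                     window: ObservabilityWindow = ObservabilityWindow()) -> dict[str, Path]:
    """Generate a full experiment and write it as plain-text files.

    Emits proteome.fasta, annotations.tsv, evidence_rep1.tsv,
    evidence_rep2.tsv, truth.tsv and binding_fixture.tsv under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, truth = generate_proteome(config)
    abundances = generate_abundances(truth, config)
    evidence = generate_evidence(records, abundances, window, config)
    fixture = generate_binding_fixture(config)

    paths = {}
    fasta = outdir / "proteome.fasta"
    with fasta.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.accession}|{rec.locus_tag} {rec.name}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i:i + 60] + "\n")
    paths["proteome"] = fasta

    ann = truth[["accession", "locus_tag"]].copy()
    ann["description"] = [r.name for r in records]
    ann["category_override"] = truth["category"]
    ann_path = outdir / "annotations.tsv"
    ann.to_csv(ann_path, sep="\t", index=False)
    paths["annotations"] = ann_path

    for rep, df in evidence.items():
        p = outdir / f"evidence_{rep}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[f"evidence_{rep}"] = p

    truth_full = truth.merge(abundances, on="accession")
    truth_path = outdir / "truth.tsv"
    truth_full.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path

    fix_path = outdir / "binding_fixture.tsv"
    fixture.to_csv(fix_path, sep="\t", index=False)
    paths["binding_fixture"] = fix_path
    return paths
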