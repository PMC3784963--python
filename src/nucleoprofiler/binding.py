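"""Nucleic-acid-binding propensity from amino-acid composition.

Nucleic-acid-binding proteins carry an excess of residues that contact the
phosphate backbone and bases — lysine and arginine above all, with glutamic
acid also over-represented in the composition statistics of known binders.
A linear model on the 20 composition fractions captures this signal well
enough to triage candidates: scores above zero flag a high predicted
likelihood of binding DNA or RNA (the two cannot be separated from
composition alone).

The model is a plain affine function ``score = w · composition + bias``.
:func:`train` fits it as a linear-kernel maximum-margin classifier
(scikit-learn ``LinearSVC``) on labelled composition vectors and freezes
the weights into a serialisable :class:`BindingModel`.  Users who scored
their proteins with an external tool can bypass the model entirely and
feed those scores straight into the selection step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import LinearSVC

from .constants import STANDARD_RESIDUES
from .proteome import validate_sequence


def composition(sequence: str) -> np.ndarray:
    """Fraction of each standard residue (alphabetical order), summing to 1.

    In permissive mode upstream, ``X`` residues are excluded from both the
    counts and the length normalisation.
    """
    seq = validate_sequence(sequence, permissive=True).replace("X", "")
    if not seq:
        raise ValueError("sequence has no standard residues")
    counts = np.array([seq.count(aa) for aa in STANDARD_RESIDUES], dtype=float)
    return counts / counts.sum()


@dataclass
class BindingModel:
    """Affine composition scorer: ``score = weights · x + bias``."""

    weights: dict[str, float]
    bias: float
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = set(STANDARD_RESIDUES) - set(self.weights)
        if missing:
            raise ValueError(f"weights missing residues: {''.join(sorted(missing))}")
        vals = list(self.weights.values()) + [self.bias]
        if not np.all(np.isfinite(vals)):
            raise ValueError("model weights must be finite")

    @property
    def weight_vector(self) -> np.ndarray:
        return np.array([self.weights[aa] for aa in STANDARD_RESIDUES])

    def save(self, path: str | Path) -> None:
        payload = {"weights": self.weights, "bias": self.bias, "provenance": self.provenance}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "BindingModel":
        payload = json.loads(Path(path).read_text())
        return cls(weights=payload["weights"], bias=float(payload["bias"]),
                   provenance=payload.get("provenance", ""))


def score(vector: np.ndarray, model: BindingModel) -> float:
    """Affine score of one composition vector."""
    return float(np.dot(model.weight_vector, np.asarray(vector, dtype=float)) + model.bias)


def score_sequence(sequence: str, model: BindingModel) -> float:
    return score(composition(sequence), model)


def is_binder(score_value: float, threshold: float = 0.0) -> bool:
    """Strictly above-threshold scores are called binders (0 itself is not)."""
    return score_value > threshold


def train(labelled: pd.DataFrame, seed: int = 0, C: float = 1.0) -> BindingModel:
    """Fit a linear maximum-margin separator on composition vectors.

    ``labelled`` needs columns ``sequence`` and ``label`` (1 = binder,
    0 = non-binder), with at least two examples of each class.  Training is
    deterministic given ``seed``.
    """
    labels = labelled["label"].astype(int)
    for cls_val in (0, 1):
        if (labels == cls_val).sum() < 2:
            raise ValueError("need at least 2 examples of each class")
    X = np.vstack([composition(s) for s in labelled["sequence"]])
    clf = LinearSVC(C=C, random_state=seed, max_iter=20000)
    clf.fit(X, labels.to_numpy())
    weights = {aa: float(w) for aa, w in zip(STANDARD_RESIDUES, clf.coef_[0])}
    return BindingModel(weights=weights, bias=float(clf.intercept_[0]),
                        provenance=f"LinearSVC(C={C}, seed={seed}) on {len(labelled)} labelled compositions")


def load_labelled(path: str | Path) -> pd.DataFrame:
    """Read a labelled training TSV (accession, sequence, label in {0, 1})."""
    df = pd.read_csv(path, sep="\t", dtype={"accession": str, "sequence": str})
    for col in ("accession", "sequence", "label"):
        if col not in df.columns:
            raise ValueError(f"training file is missing column {col!r}")
    if not set(df["label"].astype(int)) <= {0, 1}:
        raise ValueError("labels must be 0 or 1")
    return df


_DEFAULT_MODEL: BindingModel | None = None


def default_model() -> BindingModel:
    """Model trained (lazily, deterministically) on the packaged synthetic fixture.

    The fixture (``data/binding_training_synthetic.tsv``) is a synthetic
    labelled set: binder sequences enriched in K/R/E against acidic or
    hydrophobic non-binders.  See the synthetic-data module for its
    construction.
    """
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        with resources.files("nucleoprofiler.data").joinpath(
                "binding_training_synthetic.tsv").open("rb") as fh:
            labelled = pd.read_csv(fh, sep="\t")
        _DEFAULT_MODEL = train(labelled, seed=0)
    return _DEFAULT_MODEL
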