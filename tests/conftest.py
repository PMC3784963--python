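import numpy as np
import pandas as pd
import pytest

from nucleoprofiler.proteome import ProteinRecord


@pytest.fixture
def write_fasta(tmp_path):
    """Write a FASTA from (header, sequence) pairs and return its path."""

    def _write(entries, name="test.fasta"):
        path = tmp_path / name
        with path.open("w") as fh:
            for header, seq in entries:
                fh.write(f">{header}\n{seq}\n")
        return path

    return _write


@pytest.fixture
def small_proteome():
    """Four proteins with tryptic-friendly sequences."""
    seqs = {
        "A0001": "MSTAQELKSTAQEIRGVVDALKNPTTGEIRAAAQELK",
        "A0002": "MKVLITDEIRAAGSTPELKQQWDALRNPTTGEIK",
        "A0003": "MAEQLTPEERLVAQGSGSKLDDFFARPTTGELK",
        "A0004": "MKKRLLASTGEIRQQDDALKNPVVGEIRAAAQELK",
    }
    return {acc: ProteinRecord(accession=acc, locus_tag=f"L{acc}", sequence=s)
            for acc, s in seqs.items()}


@pytest.fixture
def random_sequences():
    """200 seeded random sequences of length 5..100 for oracle comparisons."""
    rng = np.random.default_rng(42)
    letters = list("ACDEFGHIKLMNPQRSTVWY")
    return ["".join(rng.choice(letters, size=rng.integers(5, 101)))
            for _ in range(200)]


def make_evidence(rows):
    """Evidence DataFrame from (accession, peptide, expect, replicate, slice) tuples."""
    return pd.DataFrame(rows, columns=["accession", "peptide", "expect",
                                       "replicate", "slice"])
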