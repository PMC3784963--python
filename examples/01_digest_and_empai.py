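"""Tryptic digestion, the observability window, and one emPAI score.

Digests a short protein in silico, counts which peptides a typical
Orbitrap acquisition could have observed, and turns a toy set of
identified peptides into an emPAI abundance estimate.
"""

import pandas as pd

from nucleoprofiler import (ObservabilityWindow, compute_empai, count_observable,
                            digest, filter_evidence)
from nucleoprofiler.proteome import ProteinRecord

SEQ = ("MSKAAQELKSTAQEIRGVVDALKNPTTGEIRAAAQELKVLITDEIRAAGSTPELK"
       "QQWDALRNPTTGEIKAEQLTPEERLVAQGSGSKLDDFFARPTTGELK")

protein = ProteinRecord(accession="DEMO1", sequence=SEQ)

peptides = digest(SEQ, max_missed_cleavages=2)
window = ObservabilityWindow()  # m/z 350-1800, charges {2,3}, length >= 6
n_observable = count_observable(SEQ, window)
print(f"protein length {len(SEQ)} aa")
print(f"tryptic peptides (<=2 missed cleavages): {len(peptides)}")
print(f"observable peptides (distinct, in-window): {n_observable}")

# pretend the search engine identified 4 of them in replicate 1
evidence = pd.DataFrame({
    "accession": "DEMO1",
    "peptide": ["STAQEIR", "NPTTGEIR", "VLITDEIR", "QQWDALR"],
    "expect": [0.001, 0.02, 0.04, 0.03],
    "replicate": "rep1",
    "slice": ["S1", "S1", "S2", "S2"],
})
abundance = compute_empai(filter_evidence(evidence), {"DEMO1": protein}, window)
row = abundance.iloc[0]
print(f"n_observed={row.n_observed}, n_observable={row.n_observable}, "
      f"PAI={row.pai:.3f}, emPAI={row.empai:.3f}")
print("emPAI = 10^PAI - 1: higher coverage of the observable peptides "
      "means exponentially higher estimated abundance.")
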