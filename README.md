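# nucleoprofiler

Candidate nucleoid-associated protein (NAP) screening from label-free
proteomics of bacterial nucleoid fractions.

## The problem

NAPs — HU, IHF, H-NS, Lsr2, sIHF and their relatives — are small, highly
abundant, low-specificity DNA-binding proteins that shape the bacterial
chromosome and the global transcriptional programme. Outside the
Enterobacteriaceae the catalogue is incomplete, and NAPs resist discovery by
homology or genetic screens: they share no common fold and no screenable
phenotype. A direct biochemical route is to isolate intact nucleoids by
gentle lysis and sucrose-gradient centrifugation, identify everything in the
fraction by LC–MS/MS, and then *rule in* the most promising candidates —
high abundance plus predicted nucleic-acid-binding ability — rather than
subtracting comparison fractions (which is known to discard bona-fide NAPs
such as H-NS and Hfq).

`nucleoprofiler` implements that analysis as a reusable pipeline for anyone
working from a protein FASTA plus a search-engine peptide export: protein
quantification by emPAI, functional categorisation, a composition-based
binding score, and the abundance-threshold candidate screen. A synthetic-data
module generates fully ground-truthed experiments so every stage — and the
end-to-end screen — is benchmarkable without any raw mass-spectrometry data.

## The method

**Quantification (emPAI).** For each protein and replicate,

    PAI = N_observed / N_observable,      emPAI = 10^PAI − 1

where `N_observed` counts distinct identified peptides (expect ≤ 0.05, gel
slices merged) and `N_observable` counts distinct in-silico tryptic peptides
(trypsin/P, ≤ 2 missed cleavages) of length ≥ 6 with a 2+ or 3+ charge state
inside the m/z 350–1800 survey window. emPAI is not comparable across
samples, so within-sample rank accompanies every score.

**Categories.** Proteins are binned by annotated function: ribosomal (R),
chaperone/redox (C), DNA-binding (D), unknown (U), enzyme/cytosolic/membrane
(E), via keyword rules plus per-accession overrides.

**Binding score.** A linear model on the 20 amino-acid composition fractions,
`score = w·x + b`, trained as a maximum-margin classifier; binders are
enriched in K, R and E, and a score strictly above zero calls a binder.
Externally computed scores can be passed through instead.

**Selection.** Per replicate: keep the top-30 category-D proteins by emPAI;
screen every category-U protein with emPAI strictly above the 30th-D
threshold through the binding score. Intersect the per-replicate selections
(a protein seen in one replicate is a suspected contaminant), merge D ∪ U,
and re-rank over the merged pool.

## Worked example

The package ships the published candidate table from a nucleoid survey of
*Streptomyces coelicolor* (per-replicate emPAI, binder scores, annotations).
Feeding the published numbers back through the screen regenerates the list:

```
$ python examples/02_published_candidate_table.py
candidates: 24 (18 category D, 6 category U)
with prior experimental support: 6
replicate-1 abundance threshold (emPAI): 0.49

accession category  known_nap  empai_rep1  rank_rep1
   Q9X7Z9        D      False        4.47          1
   Q9KXR9        D       True        3.49          2
   Q9F2U7        D      False        3.40          3
   P0A3H5        D       True        3.24          4
   O69959        U      False        2.95          5
   P0A4Q4        D      False        2.69          6
...
```

24 candidates: 18 annotated DNA-binding proteins plus 6 uncharacterised
proteins that passed the composition screen, among them the 6 experimentally
verified NAPs/GRs (HupA, HupS, sIHF, Lsr2, BldD, CRP) — sIHF at rank 2 and
HupA at rank 4, exactly where known major nucleoid proteins should surface.

Other examples: `examples/01_digest_and_empai.py` (digestion, observability,
one emPAI score), `examples/03_synthetic_benchmark.py` (ground-truthed
simulation and recovery), `examples/04_binding_model.py` (training and using
the binding scorer).

There is also a thin CLI:

```
nucleoprofiler simulate --out sim --seed 42
nucleoprofiler select --proteome sim/proteome.fasta \
    --evidence sim/evidence_rep1.tsv --evidence sim/evidence_rep2.tsv \
    --annotations sim/annotations.tsv --out results
```

which writes `abundance.tsv`, `composition.tsv`, `candidates.tsv`,
`summary.txt` and a `run_log.json` manifest.

## Layout

- `src/nucleoprofiler/` — the library (`proteome`, `digest`, `empai`,
  `binding`, `selection`, `synthetic`, `pipeline`, `cli`, `fixtures`)
- `src/nucleoprofiler/data/` — packaged datasets: the published candidate
  table, the curated known-NAP list, category keyword rules, pKa sets, the
  synthetic binding-training fixture, the default config
- `examples/` — narrative scripts, one per capability
- `docs/methods.md` — models, assumptions, parameter choices, limitations
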