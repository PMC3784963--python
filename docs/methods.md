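# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and the
numerical choices a maintainer would otherwise have to reverse-engineer.

## emPAI quantification

emPAI estimates relative protein abundance from peptide coverage:
`PAI = N_observed / N_observable`, `emPAI = 10^PAI − 1`. The numerator is
the number of *distinct* peptide sequences identified for the protein in
one replicate after filtering to peptide expect values ≤ 0.05 (inclusive
boundary) and merging gel slices — a peptide found in several slices of one
replicate counts once. The denominator is reconstructed in silico:

- **Digestion**: trypsin/P — cleavage after every K or R with *no* proline
  exception — with up to 2 missed cleavages. Peptides are enumerated with
  explicit coordinates; the 0-missed-cleavage fragments partition the parent.
- **Observability**: a peptide counts if it has ≥ 6 residues and at least
  one of charges {2+, 3+} puts its monoisotopic m/z inside [350, 1800] —
  the survey window and precursor-selection rule of a typical
  nanoLC–Orbitrap acquisition. Duplicate peptide sequences within one
  protein count once, matching the distinct-peptide numerator. The length
  cut-off of 6 is the conventional minimum identifiable tryptic length; it
  is configurable, as is every window parameter.

Monoisotopic masses (pyteomics) are used for the observability window,
because instruments select monoisotopic precursors; average masses are used
only for the reported MW column. A protein with identified peptides but
zero observable peptides is an error, not a silent division by zero.

emPAI saturates for very abundant proteins (PAI → 1 gives emPAI ≤ 9 when
every observable peptide is seen once). No saturation correction is applied;
the synthetic observation model reproduces the effect instead, so that
downstream code is exercised under realistic compression.

Protein inference is exact accession match: no peptide-to-protein
apportionment or grouping, because the pipeline consumes a protein-level
search-engine report where that resolution has already happened.

**Ranking**: 1-based ranks by descending emPAI within a scope (all proteins,
or one category) and replicate; ties are broken by ascending accession, so
ranks are a deterministic permutation of 1..n.

## Physico-chemical features

- **MW**: sum of average residue masses plus one water, in kDa; the residue
  mass table is in `constants.py`. Nonstandard letters are rejected by
  default; a permissive mode maps X to the mean residue mass and excludes it
  from composition features (B/Z/U/O always raise). Silent guessing would
  corrupt observable-peptide counts, hence reject-by-default.
- **pI**: root of the Henderson–Hasselbalch net-charge model, found by
  bisection on pH ∈ [0, 14]. The charge is strictly decreasing in pH so the
  root is unique; bisection continues past the pH tolerance until the charge
  residual itself is below 1e-4, since the charge slope grows with the
  number of ionisable groups. The default pKa set is a Bjellqvist-style set
  with fixed terminal pKas, shipped in `data/pka_sets.json` along with an
  EMBOSS-style alternative; sets with residue-dependent terminal pKas (e.g.
  Biopython's) differ by up to ~0.5 pH on ordinary sequences and more on
  extreme acidic ones, so published pI values are matched only to ±0.5.

## Binding score

An affine function of the 20 composition fractions. The trainer fits a
linear-kernel SVM (scikit-learn `LinearSVC`, fixed `random_state`, so
training is deterministic) and freezes coefficients into a JSON-serialisable
`BindingModel`. Features are raw composition fractions only — no dipeptide
or profile features — because composition is the signal the screen relies
on: nucleic-acid binders are enriched in K, R and E. No attempt is made to
distinguish DNA from RNA binding; composition cannot resolve the two.

The packaged default model is trained lazily on the shipped synthetic
fixture (`data/binding_training_synthetic.tsv`, generated by the synthetic
module at a fixed seed: K/R/E-enriched binders vs acidic/hydrophobic
non-binders, labelled as synthetic in name and provenance). The published
scores in the study table were produced by an external composition-SVM web
tool whose trained weights are not recoverable, so the package reproduces
the *role* of that scorer and additionally accepts externally computed
scores as a pass-through column; the packaged published scores are consumed
that way. The decision threshold is strictly greater than zero — a score of
exactly 0 is not a binder.

## Candidate selection

Per replicate: the top `top_n_d` (default 30) category-D proteins by emPAI
are kept and the emPAI of the last kept protein becomes the replicate's
abundance threshold; category-U proteins with emPAI *strictly* above the
threshold and binding score strictly above `binder_threshold` (default 0)
pass the screen. If fewer than `top_n_d` D proteins exist, all are kept,
the threshold is the minimum, and a warning is emitted. The per-replicate
selections (D ∪ U) are then intersected; requiring a candidate to pass in
*every* replicate before the merge is the strictest of the defensible
orderings (cut-then-intersect vs intersect-then-cut are not distinguished
by the procedure's description) and is the default. No comparison fractions
are subtracted — this is a ruling-in screen by design.

The final table recomputes rank over the merged D+U candidate pool within
each replicate ("amalgamated rank") rather than carrying over full-list
ranks, and is sorted by the first replicate's rank. Known-NAP flags come
from a curated data file (`data/known_naps.tsv`), not from code: prior
experimental verification is a literature fact, not a computation.

Missing binding scores for U proteins above the abundance cut are an error
naming the accessions; missing scores below the cut are irrelevant and
ignored.

## Synthetic experiments

The generator emulates the statistics the pipeline is sensitive to, with
all outputs deterministic functions of (config, seed):

- **Proteome**: `n_proteins = 500` random sequences of 60–400 residues from
  bacterial background residue frequencies; categories sampled with
  proportions R/C/D/U/E = 0.08/0.07/0.10/0.25/0.50 (a nucleoid fraction is
  dominated by enzymatic/cytosolic contamination, with a sizeable
  uncharacterised class and ~10% annotated DNA-binders). `n_planted_naps =
  20` planted NAPs are drawn with K/R/E-multiplied composition (basic pI
  follows), lengths 60–150 (NAPs are small), and category D or U.
- **Abundance**: rank `r` gets abundance `r^−α` with `α = 1` (power law —
  a few dominant species and a long tail, with no typical abundance).
  Planted NAPs take ranks within the top quarter, so some legitimately fall
  below the top decile — an abundance-threshold screen cannot and should
  not find those. Replicate 2 multiplies the base by lognormal noise whose
  scale is calibrated by bisection so the between-replicate Spearman
  correlation matches `replicate_correlation = 0.8`; the expected Spearman
  is estimated over a small set of standard-normal draws held fixed across
  the bisection, making the calibration smooth and deterministic. (A
  closed-form calibration via the bivariate-normal relation systematically
  undershoots because log power-law abundances are far from Gaussian.)
- **Detection**: each observable peptide of a protein is detected
  independently with probability `1 − exp(−c·abundance)` — the simplest
  saturating observation model, chosen so abundant proteins approach full
  coverage (emPAI → 9) just as real abundant proteins saturate. `c` is
  calibrated by bisection so the expected number of peptide observations
  per replicate equals `detection_capacity = 5000` (a realistic peptide
  yield for a few hundred identifiable proteins in one gel-separated run).
  Ten percent of detected peptides receive expect values above the 0.05
  cut, exercising the filter; evidence is split over three gel-slice labels
  by peptide-mass tertile.
- **Binding fixture**: balanced binder/non-binder sequences from the NAP
  and acidic/hydrophobic distributions; a margin knob interpolates both
  class distributions toward the background (0 = indistinguishable).

What the generator does **not** emulate: real spectra or fragmentation,
retention time, chromatographic co-elution, shared peptides between
homologues, post-translational modifications, protein-length biases of gel
slicing, or annotation noise. Passing the recovery benchmarks therefore
shows the *procedure* is sound under the stated statistical conditions, not
that any particular real protein would be found.

Benchmarks computed by the test suite at default settings (10 seeds):
recovery of planted top-decile NAPs into the final candidate list, Spearman
correlation between true abundance and emPAI, and the log–log linearity
(R²) of emPAI vs rank over the top half of ranks. Problem sizes (500
proteins, 10 seeds) were chosen as the smallest giving stable averages for
these stochastic checks.

## Pipeline and reproducibility

The orchestrated run validates its YAML config against an explicit schema
(types, ranges, unknown keys rejected; flat keys `mz_min`, `mz_max`,
`charges`, `min_length`, `max_missed_cleavages`, `expect_threshold`,
`top_n_d`, `binder_threshold`, `require_both_replicates`, `seed`), writes
`abundance.tsv`, `composition.tsv`, `candidates.tsv`, `summary.txt`, and a
`run_log.json` manifest (config snapshot, SHA-256 input checksums, package
version, seed, timestamp). Detected proteins absent from the annotation
table default to category U with the usual incomplete-annotation caveat
rather than failing the run. Table outputs are byte-identical across reruns
on identical inputs (fixed column order and float formatting); the manifest
carries the only timestamp.

## Known limitations

- The emPAI denominator is a principled reconstruction of the instrument's
  observability rules; search engines use their own internal variants, so
  absolute emPAI values from other software will differ (ranks are robust).
- The published study table contains internally inconsistent replicate-2
  ranks (duplicate rank values); only replicate-1 ranks are treated as
  reproducible, and the pipeline always recomputes ranks rather than
  trusting imported ones.
- The binding scorer is a composition-only triage tool. Abundant
  contaminants with basic composition will score above zero; the screen
  prioritises, it does not verify.
- MW/pI for proteins supplied without sequences (published-table mode) are
  pass-through values; pI is model- and pKa-set-dependent everywhere.
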