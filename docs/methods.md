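# Methods

## Problem setting

Celiac-disease (CD) immunogenic peptides are short (here 9–20 residue)
gluten-derived fragments, heavily enriched in proline and glutamine,
that survive gastrointestinal proteolysis and are presented by
HLA-DQ2/DQ8. `cdpep` predicts whether a peptide is CD-associated from
sequence alone, and localizes candidate regions in whole proteins. Three
predictors with increasing machinery — a one-parameter compositional
rule, exact motif matching, and a learned composition classifier — are
combined into a motif-first ensemble.

## PQ-density rule

For window size `w` (3–9; peptides in the target length range always
admit `w ≤ 9`), all `L − w + 1` overlapping windows at step 1 are scored
by their P+Q fraction and the peptide score is the maximum. Step 1 is
implied by exhaustive overlapping enumeration; scores are exact rationals
`k/w`. Classification is `score ≥ threshold` (positive at the boundary).

The threshold is tuned on labeled data over the grid 0.00–1.00 in steps
of 0.01 (the resolution at which such operating points are conventionally
reported). The selected threshold minimizes |sensitivity − specificity|;
ties are broken by maximal accuracy, then by the smallest threshold. Both
choices matter only on coarse/degenerate score distributions; the
tie-break makes tuning deterministic. Peptides shorter than a window are
excluded from that window size's evaluation (with a logged count), not
zero-padded. AUROC of the raw scores is reported alongside as the
threshold-free summary.

On the default synthetic data the tuned `w = 5` threshold lands at 0.41
(two of five residues in some window): positives are so P/Q-dense that
nearly every one has a majority-P/Q window, while background negatives
rarely exceed one P/Q per 5-mer.

## Amino-acid composition and the classifier panel

The composition vector is `AAC_i = 100 · R_i / L` over the 20 standard
residues, in fixed alphabetical column order; rows sum to 100 exactly.
Peptides are not length-normalized further — composition already is.

Eight classifier families run on this 20-feature space with fixed,
deliberately unremarkable hyperparameters (recorded in the saved model
bundle): 500 trees for the random-forest and extra-trees ensembles, `k = 5`
neighbours, RBF SVC, logistic regression with up to 2000 iterations,
XGBoost with 200 depth-4 trees, Gaussian naive Bayes, and a single
decision tree with a 10-sample leaf floor — the floor exists so a lone
tree emits graded class frequencies rather than memorized 0/1 leaves,
which would make its ranking (AUROC) meaningless. No hyperparameter
search is performed; on a 20-dimensional composition space with strongly
separated classes it would buy nothing and cost determinism. Scores are
class-1 probabilities where available; for the SVC the decision value is
min-max scaled to [0, 1] using the training-data range (clipped at
predict time). The deployed default is extra trees.

Evaluation protocol: a stratified 80:20 hold-out (per-class sizes rounded
by the splitter), then five stratified folds partitioning the training
portion (per-class fold sizes differ by ≤ 1). The training report is the
unweighted mean of per-fold metrics at the fixed 0.5 score threshold; the
model is then refit on the full 80% and scored once on the 20%.
Everything is deterministic given (dataset, classifier kind, seed).

Metrics: sensitivity, specificity and accuracy in percent; F1 and MCC as
fractions; MCC is defined as 0 whenever a marginal of the confusion
matrix is zero. AUROC is computed by the rank-sum (Mann–Whitney)
formulation with average ranks, which handles ties exactly and equals
trapezoidal ROC integration (the test suite cross-checks this against an
independent trapezoidal implementation).

## Motif discovery, scanning and coverage

Motifs are ungapped exact substrings, length 3–6 by default. The
published CD motif vocabulary (QPF, QPQ, PYP, PQPQ, …) is entirely
ungapped, so gapped or degenerate pattern classes are deliberately out of
scope. Discovery enumerates every substring in the length band and keeps
those contained in at least `min_positive` positive sequences (default:
1% of the positive set, rounded up) and at most `max_negative` negatives
(default 0 — strict class exclusivity; a small allowance is exposed
because real negative sets show occasional contamination). Counts are
per-sequence, not per-occurrence.

Two redundancy filters follow. First, any candidate containing another
candidate as a proper substring is dropped: the substring occurs in a
superset of the positives and is the more general pattern. Second,
candidates with *identical* positive-coverage sets — typically fragments
of one conserved context, like QPF / PFA / QPFA from "…QPFA…" — are
collapsed to a single canonical representative: the most P/Q-dense
pattern, then the shortest, then the lexicographically smallest. The
P/Q-density preference encodes what the discovery is for; among
support-equivalent fragments the proline/glutamine core is the
biologically interpretable one. Output is sorted by positive support
descending (ties lexicographic), which is also the attribution order
used downstream.

Scanning reports every (overlapping) occurrence with 1-based inclusive
coordinates. The coverage table attributes each positive sequence to the
first listed motif it contains, so percentages partition the positive
set; the residual row is exactly the fraction the ensemble delegates to
the ML tier.

The shipped default motif set is the union of the published pattern
lists, highest-occurrence patterns first; it is configurable per run and
per model.

## Ensemble

The ensemble is an ordered motif list plus a fitted composition
classifier with a 0.5 ML threshold. A motif hit asserts a positive
immediately (provenance "motif", first matching motif in set order);
motifs never assert negatives. Motif-free queries are decided by the ML
score (provenance "ML"). At fit time the motif set is re-ordered by
support on the training positives; passing `motifs="discover"` runs
class-exclusive discovery instead of using a fixed list. For ranking
purposes (`decision_function`) a motif hit maps to score 1.0.

## Protein scanning and analog design

`scan_protein` scores every window of length `window_length` (default 9,
the minimum peptide length in the target range) advancing by `step`
(default 1); row count is `⌊(L − w)/step⌋ + 1`. Any fitted predictor
works: ensemble, composition classifier, or the PQ rule. BED-style
output (0-based half-open) is available from the CLI; everywhere else
coordinates are 1-based inclusive.

`design_analogs` enumerates all `19·L` single-substitution variants
(insertions/deletions and multi-site variants are out of scope), scores
each with the chosen predictor and reports the parent first — the
standard tool for asking which substitutions detoxify a peptide or
which positions carry the prediction.

## Synthetic data generator

The generator emulates the structure of curated CD peptide datasets,
which cannot be redistributed: lengths uniform on 9–20; positive residues
i.i.d. from a stylized disease-peptide composition (P 0.28, Q 0.28,
F 0.08, L 0.08, Y 0.06, remainder uniform); negatives from a
Swiss-Prot-like background (roughly uniform with L/A/S mildly elevated:
L 0.09, A 0.08, S 0.07). A fixed fraction of positives (default 0.8)
receives exactly one planted motif from the pool of eight published
patterns at a random position; the remaining positives and all negatives
are rejection-resampled until motif-free, so the motif-bearing fraction
is exact and class-pure. A `negative_motif_leak` option plants motifs
into a fraction of negatives to emulate the slight contamination seen in
real negative sets. Sequences are unique within class (resampling bounded
at 1000 attempts); the dataset is a pure function of the seed, and
`write_fixture` emits a FASTA pair plus a checksummed JSON manifest.

What the generator does **not** emulate: positional conservation within
peptides (real CD epitopes have position-specific residue preferences,
not i.i.d. columns), HLA-restriction structure, homology clusters of
near-duplicate peptides, and deamidation biology. Passing tests on this
data therefore demonstrate that the algorithms recover planted structure
under the method's own assumptions — not field performance on curated
immunological data, whose published headline numbers require those
external datasets.

Default study conditions used by the test suite and the acceptance
script: 500 positives + 500 negatives at seed 42 (unit tests use smaller
sizes, 30–120 per class, where the check is structural rather than
statistical). The fallback model the CLI trains when no model file is
supplied uses 200+200 at seed 42 — enough to saturate validation AUROC
on this data while keeping start-up around a second; it is trained in
memory on demand rather than cached on disk, trading a second of start-up
for having no hidden state.

## Known limitations

- All predictors see composition only (global or windowed); two peptides
  with permuted residues score identically except through the motif tier.
- Strict exclusivity (`max_negative = 0`) makes discovery sensitive to
  single contaminated negatives; raise `max_negative` on noisy data.
- The coverage-collapse rule keeps one representative per coverage class;
  on very small positive sets distinct contexts can coincidentally share
  a coverage set and be merged.
- Thresholds tuned on one dataset (the 0.41 operating point) transfer
  only to data with comparable P/Q background rates.
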