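# Methods

## Problem and model

`pepmat` addresses a pattern-detection problem that defeats alignment-profile
methods: a small set (tens) of short functional peptides (8–36 residues) of
heterogeneous length and no constructable multiple alignment, to be
discriminated from matched control sequences. The motivating system is the
tooth enamel pellicle — salivary peptides that adsorb to hydroxyapatite —
where the functional signal is a diffuse chemistry-level pattern (adjacent
carboxyl/amide residues, alternating hydroxyls, proline runs) rather than a
positional motif.

The model is a 20×20 integer amino-acid substitution matrix *M*, with
`M[q][t]` the score for aligning query residue *q* against dataset residue
*t*, entries clamped to [−19, 19]. Similarity between two peptides is their
Needleman–Wunsch global alignment score under *M* with affine gap penalties
(a gap of length *L* costs `open + (L−1)·extend`, terminal gaps penalized),
divided by the arithmetic mean of the two lengths. The total similarity
score between two sets, TSS(A, B), is the mean of this quantity over all
ordered cross pairs; when A and B are the same set, self pairs are excluded
so that self-alignment cannot inflate within-set similarity.

Training maximizes a set-discrimination objective over matrix space. Writing
F for the functional set and N for the controls, the four objectives are

* `diff2` = TSS(F,F) − TSS(F,N)
* `diff4` = TSS(F,F) + TSS(N,N) − TSS(F,N) − TSS(N,F)  *(default)*
* `quotient` = TSS(F,F)·TSS(N,N) / (TSS(F,N)·TSS(N,F))
* `margin3` = difference between the 3rd-lowest functional and 3rd-highest
  control per-peptide score (order statistics tolerate outliers), computed on
  min-max-normalized leave-one-protein-out scores.

`diff4` is the default because the four-term difference uses the control
set's internal structure as well; the quotient variant is retained but is the
least stable (it is undefined when a cross term is zero and in practice
trains poorly).

## Training procedure

1. **Gap grid.** Gap penalties are fixed once by exhaustive search over the
   128 integer combinations open ∈ [−16, −1] × extend ∈ [−8, −1], before any
   matrix perturbation (they are volatile if re-trained during refinement).
   Ties break toward the smallest magnitudes.
2. **Greedy columns, then rows.** A column move adds ±1 to all 20 entries of
   one dataset-residue column (clamped); a row move does the same for a query
   residue. Each iteration evaluates all 40 candidate moves on the axis and
   applies the single best strictly-improving one, until none improves.
   Starting with columns is the default; row/column moves are distinct
   operations because the matrix is allowed to become asymmetric (query and
   dataset residue play different roles).
3. **Monte Carlo columns, then rows.** Each attempt shifts one random axis
   element by a random signed integer magnitude in [1, D−1], where D is the
   current matrix's max−min spread (1 when D ≤ 1), then locally maximizes
   with one greedy pass on the same axis, and keeps the combined step only if
   the objective strictly improved over its pre-shift value. The stage stops
   after `patience` (default 5) consecutive rejections.

Cell-wise stages (`greedy_cells`, `mc_cells`) are implemented and
constructible but excluded from the default stage order; single-cell Monte
Carlo moves carry too little signal per evaluation to be worth their cost and
are emitted with a warning from the CLI. All stochastic behavior flows
through one seeded generator (default seed 1837); traces log every candidate
acceptance decision with objective values, so runs are auditable and
bit-reproducible.

Background sets (extra presumed-non-functional peptides, e.g. random
UniProt-composition sequences or fragments of other secreted proteins) may be
appended to the control side of the objective during training. They never
enter assessment.

## Assessment

Evaluation is leave-one-protein-out: scoring any peptide removes all records
(functional and control) sharing its source protein from both comparison
sets, so information never leaks between peptides of one protein. The
per-peptide score is TSS(query, F′) − TSS(query, N′). Pooled scores are
min-max normalized (constant tables map to 0.5) with functional as the
positive class and summarized as:

* ROC curve and rank-based (Mann–Whitney) AUC, ties counting ½; the
  trapezoidal area under the curve equals the rank formulation to 1e−9.
* Precision–recall curve.
* MCC across the 101 thresholds 0.00–1.00 (step 0.01), predicting positive at
  score ≥ threshold, with MCC defined as 0 whenever a confusion-matrix
  marginal is zero. The curve maximum defines the operational cutoff used
  downstream (network thresholding).
* One-tailed Welch *t*-test (unequal variances, Welch–Satterthwaite df) of
  functional > control, via `scipy.stats`; the degenerate both-samples-
  constant case returns p = 0.5 at equal means.

An amino-acid-content baseline scores a query by the mean log-ratio of
residue proportions in F′ versus N′ (add-one smoothing per residue type,
needed because the sets are small), with the same protein exclusion. It
isolates how much of the discrimination is composition rather than
arrangement.

## Protein scanning and recapture

A whole protein is scanned with windows of either the single lower-median
functional peptide length or all distinct functional lengths; each window is
scored by TSS against the (protein-excluded) functional set, and each residue
aggregates the scores of its covering windows by mean (default) or max.
Terminal residues use only their covering windows — no padding. Window
scores use similarity to the functional set only; a control-subtracted
variant is a scoring choice deliberately not taken here because matched
window-length control scores are not generally available for arbitrary
proteins. Recapture of known functional spans is measured as by-residue ROC
AUC per protein, and pooled over all residues after per-profile min-max
normalization (profiles from proteins of very different score ranges would
otherwise dominate the pool).

## Networks and cluster alignments

All-against-all peptide similarities (alignment score over mean length) are
min-max normalized over the pairs — the same normalization the benchmark
applies to its score table — and thresholded, by default at the benchmark's
best-MCC cutoff. Clusters are the connected components of the thresholded
graph: deterministic and order-independent, unlike force-directed layouts,
and raising the threshold only ever refines the partition. Each cluster is
summarized by a center-star multiple alignment: the member with the highest
summed similarity is the center, every other member is globally aligned to
it with the same trained matrix and gap penalties, and pairwise alignments
merge under once-a-gap-always-a-gap. Center-star alignments are within a
factor of two of optimal pairwise cost and keep the "same substitution
matrix" semantics without an external MSA program; columns involving gap
merges can differ from a progressive aligner's output.

## Synthetic data generator

The generator emulates the structure of a pellicle-style study so every
stage is testable without external data:

* **Functional peptides** — `n_families` (default 3) motif families; a motif
  is a list of position classes, each a set of chemically interchangeable
  residues. The defaults mirror the pattern classes seen in mineral-binding
  peptides: adjacent carboxyl/amide {D,E}/{D,E,N,Q}, alternating hydroxyl
  {S,T,Y}, and proline runs. A peptide tiles its family motif across its
  whole length (uniform in 8–36) at a random phase — the repetitive
  low-complexity texture of real pellicle constituents — and each position is
  replaced by a background draw with probability `substitution_noise`
  (default 0.2).
* **Controls** — i.i.d. draws from a UniProt-like residue composition
  (bundled constant table), length-matched to the functional set.
* **Source proteins** — each functional peptide is embedded between
  background flanks of 20–60 residues with its span recorded, enabling
  decoy sampling and recapture evaluation with the same leave-one-protein-out
  structure (one peptide per synthetic protein by default).

What the generator does *not* emulate: mass-spectrometry observation bias,
shared evolutionary ancestry between peptides of one protein, real
length/composition coupling, and the possibility that controls contain
unobserved functional sequence. Passing the synthetic recovery tests
therefore shows that the machinery can find planted, chemically structured
signal at realistic sizes and noise — not that any particular biological
dataset contains such signal.

## Numerical choices and degenerate inputs

* All alignment arithmetic is integer; the DP kernel is numba-compiled and a
  pure-Python traceback variant produces the aligned strings (scores agree by
  construction and by test).
* Traceback tie-breaking prefers diagonal, then gap-in-target, then
  gap-in-query; scores are unaffected.
* Greedy ties break by alphabet order, then the positive direction; gap-grid
  ties toward smallest |open|, then smallest |extend|.
* Min-max normalization of a constant vector returns 0.5 everywhere.
* Nonstandard residues (B, Z, X, U, J, O) map to a wildcard scored 0 against
  everything; AAindex matrices with real-valued entries are rounded to the
  nearest integer and clamped to [−19, 19] (a comparability caveat when
  reproducing results derived from unrounded matrices); missing AAindex
  values are filled with 0 under a warning.
* Fragment merging is exact coordinate arithmetic on 0-based half-open
  spans: overlapping or abutting records from one protein merge into the
  union span, and disagreeing overlaps are an error rather than a vote.

## Problem sizes

The bundled study conditions — 3 families, 20 functional + 20 control
peptides, noise 0.2, lengths 8–36 — train in a few minutes on one core and
are the sizes used by the test suite and the acceptance script. Larger sets
scale as (set size)² alignments per objective evaluation.

## Known limitations

* Training is a local search; different stage orders or seeds can end in
  different local optima. The trace and the L1 matrix distance quantify how
  far training moved.
* The training objectives are contrasts (differences of TSS terms), so they
  are nearly indifferent to large uniform offsets on whole columns or rows;
  the Monte Carlo stage can push columns toward the ±19 clamp without
  changing discrimination. Those arbitrary absolute offsets do matter for
  protein scanning, where windows are compared to the functional set alone:
  with small training sets the trained matrix's recapture can be much worse
  (even inverted) relative to its untrained start, whose absolute scale is
  still meaningful. The acceptance script reports recapture under both
  matrices for this reason; for scanning work, benchmark the trained matrix's
  recapture before trusting its profiles.
* The quotient objective is undefined when either cross-set TSS is zero.
* With matched window lengths the scan cannot localize signal finer than the
  shortest functional peptide.
* The per-peptide discrimination score uses the difference form
  (functional-minus-control similarity); raw similarity-to-functional is a
  one-line change but alters normalization and thresholds.
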