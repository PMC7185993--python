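# Methods

## Scope and data model

The package operates on *core alignments*: protein domain sequences aligned
over a fixed set of match columns (231 for the GT-A common core), with
insertions bookkept separately at their anchor columns.  The A2M dialect is
used on disk — uppercase and `-` are match states, lowercase runs are
inserts anchored between the two flanking match columns, and lowercase runs
before the first or after the last match column are treated as N-/C-terminal
flanks rather than domain inserts (this distinction matters for the
minimal-domain filter, which bounds inserts and flanks separately).  Column
identifiers are 1-based throughout, matching the aligned-position numbering
used for the GT-A core (G-loop glycine at 151, C-terminal histidine at 207).

## Conservation scoring

Per-column conservation is the gap-weighted Jensen–Shannon divergence:
`score = (1 − gap_fraction) · JSD(p_col, background)` with
`JSD(p,q) = λ KL(p‖m) + (1−λ) KL(q‖m)`, `m = λp + (1−λ)q`, logs base 2 and
λ = 0.5, so scores lie in [0, 1].  The column distribution is estimated from
non-gap states with a tiny smoothing pseudocount (1e-7, the value used by
the reference implementation of this estimator), so a gap-free column whose
empirical distribution equals the background scores 0 exactly to numerical
precision.  The default background is the BLOSUM62 marginal frequency
vector; a uniform background is provided for analytic checks.  No sequence
weighting or window smoothing is applied.  Ranked conserved positions break
ties deterministically (score descending, column id ascending).

## Pattern contrast (family-characteristic positions)

Family-specific conservation is scored by a frequentist
foreground/background contrast, a deliberate surrogate for Bayesian
pattern-partitioning methods (the hierarchical partitioning itself is out of
scope; family labels are an input).  At a column, candidate patterns are the
nested prefixes of residues ordered by pseudocounted foreground/background
frequency ratio (pseudocount 0.5); the reported pattern minimizes the
hypergeometric tail probability of its foreground occupancy, and the score
carries a base-2 log-odds.

**Calibration caveat (a deliberate design decision).**  Because the pattern
is *selected on the same data*, its raw hypergeometric tail is
anti-conservative as a hypothesis test (we measured ~99% of pure-background
columns below p = 0.05).  The raw tail is nevertheless exactly the
hypergeometric probability of the reported pattern, and it orders columns
correctly — which is what `family_characteristic_positions` needs to rank
candidate positions per family (Benjamini–Hochberg adjustment across
columns is applied per family for a consistent ranking scale).  For
calibrated inference, `pattern_contrast(..., n_permutations=n)` replaces the
nominal value with a label-permutation p-value, which is finite-sample valid
(super-uniform) by construction.  Users should treat nominal p-values as
comparative scores, not error rates.

## Distances, neighbor joining, bootstrap

Sequence distances are computed over shared non-gap columns: p-distance or
Poisson-corrected `−ln(1 − p)` (p capped at 1 − 1e-9 so saturated bootstrap
replicates stay finite).  Family-profile distances are the mean column-wise
JSD between per-family residue distributions — a transparent surrogate for
HMM-profile distance scores, with the same qualitative behavior (0 for
identical profiles, 1 for disjoint ones).

Neighbor joining follows the Saitou–Nei Q-criterion with two determinism
rules: ties in Q are broken by the lexicographically smallest pair of
subtree labels (a subtree is labelled by its smallest leaf), and negative
branch lengths are clamped to zero and recorded on the tree object.  On
additive matrices the algorithm recovers the generating topology and branch
lengths exactly; this is verified against an independent Robinson–Foulds
oracle (dendropy) on random trees.  Maximum-likelihood tree search is
intentionally not reimplemented — the distance/NJ path is the package's
tree-building strategy.

Bootstrap support resamples core columns with replacement, rebuilds the NJ
tree per replicate, and maps per-bipartition frequencies (percent) onto the
full-data tree; runs are bit-reproducible for a fixed seed.  Support bands
follow the printed rule exactly: >90 well, >75 moderate, <50 unresolved.
The 50–75 band is not characterized by that rule and is labelled "low"
explicitly rather than guessing intent.

## Feature encoding and CFS

Each kept column (after the strict >15% gap filter) contributes five
features per sequence: net charge at pH 7, Grantham polarity,
Kyte–Doolittle hydrophobicity, average accessible surface area, and
side-chain van der Waals volume.  The exact scales behind the five published
property names are not recoverable; these widely used defaults ship as an
editable, versioned table (`PropertyTable`), and results obtained with them
are reimplementation values, never presented as the original study's.  Gaps
are imputed with the column's non-gap mean per property, which keeps imputed
values inside the observed range.

Feature selection is correlation-based (CFS): features are discretized by
the Fayyad–Irani MDL criterion, associations are symmetrical uncertainties,
and a greedy best-first forward search maximizes Hall's merit
`M_S = k r̄_cf / sqrt(k + k(k−1) r̄_ff)` with the standard termination rule
(stop after 5 consecutive non-improving additions, improvement threshold
1e-5).  Selection runs inside each of 5 stratified CV folds; the final set
is the majority vote (≥3 of 5 folds).  This aggregation is a documented
choice — per-fold selections are also returned.  Because the merit
penalizes redundancy, CFS deliberately returns a *non-redundant informative
subset*: sibling features of the same column (five properties of one
residue) are mutually highly associated, so typically 3–4 of the five are
kept per informative column.  Closed-loop recovery should be read with that
in mind: column-level recovery of planted signal is complete in our tests,
while feature-level recovery saturates around three quarters.

## Donor-specificity models

The multiclass classifier is a gradient-boosted decision-tree ensemble with
the published hyperparameters as immutable defaults (learning_rate 0.1,
n_estimators 1600, min_samples_split 25, min_samples_leaf 7, max_depth 4,
max_features 18, subsample 0.75, random_state 10); `max_features` degrades
to the actual feature count when fewer are supplied.  Evaluation is
stratified 10-fold cross-validation (fold count falls back to the smallest
class size, with a warning).  The "239 informative features" of the
original analysis is treated as a data-dependent CFS output, not a
constant — the selected count is recomputed and reported.

Confidence categories follow the printed rule with p₁ ≥ p₂ the two largest
class probabilities: *high* iff p₁ > 4 p₂; else *moderate* iff
p₁ − p₂ > 2·(1/6); else *low*.  Boundary cases belong to the lower band
(p₁ = 4 p₂ is not high; p₁ − p₂ = 1/3 is not moderate).  The
grammatically ambiguous alternative reading ("the probability for the first
class exceeds 2·(1/6)") is available as `rule="absolute"`.  An exact
probability tie resolves to the first class in training order and, by the
rule, is low confidence.

Feature importances are normalized impurity importances of the fitted
ensemble, ranked descending; ranks 1–10 are flagged "high" and 11–20
"moderate".  Per-donor importances retrain one-vs-rest binary ensembles
with the same configuration and are joined with the full-model ranks.  The
random-forest baseline is capped (300 trees, 100 terminal nodes) and can be
restricted to a user-supplied descriptor subset; the donor-binding residue
list is an input (the motif columns — DxD, G-loop, xED, C-His, αC positions
65–72 — are the documented starting set), since no canonical 25-feature
list ships with the package.

## Synthetic data: what it emulates, and what it does not

The generator emulates the statistical structure of a GT-A core alignment:
a 231-column core over a BLOSUM62-marginal background; 20 globally
conserved columns; family-specific conserved columns; donor-determining
columns whose residue composition differs by class; per-column gap rates
spanning the 15% threshold (planted columns are kept gap-free, as
class-determining positions in real enzymes are rarely gapped); and inserts
at three HV anchor columns (60, 120, 225), with one family carrying a
32-residue HV2 insert so the >28 rule fires.  Default donor conditions are
six classes × 120 sequences (the published training set has >70 per class),
four determining columns per class, and 5% substitution noise; determining
residues rotate over R/D/E/K/H — charged, mutually distinct residues across
all five property scales — chosen so that *every* property of a determining
column carries class information.  Half of each class's determining columns
are flagged "donor-site" so restricted-feature baselines can be contrasted
with the full model.  The Bayes-optimal accuracy of any planted scheme is
estimated by Monte Carlo from the exact generative likelihood
(`bayes_rate`), giving an absolute yardstick for classifier accuracy
(~99.9% under the default conditions).

Tree-structured simulation (`evolve_along_tree`) uses an independent-site
20-state Jukes–Cantor-style substitution process; it supports the NJ
recovery tests but makes no claim of realism (no indels, no rate
heterogeneity, no profile structure).  Passing closed-loop tests therefore
demonstrates the *algorithms* recover planted structure under i.i.d.
noise — not that real alignments satisfy those assumptions.

## Numerical and procedural choices

* Consensus ties: lexicographic by one-letter code, recorded per column;
  all-gap columns yield `-` and are recorded.
* Prototype selection: normalized BLOSUM62 similarity to the consensus over
  shared non-gap columns (matrix configurable) — same ordering objective as
  a BLAST search against the consensus without the external tool.
* Redundancy filter identity: matches / shared non-gap columns; greedy in
  input order (the clustering procedure behind the published 70%/50%
  filtering is not defined; this is the simplest deterministic choice).
* Minimal-domain ("ancient") filter: "aligned positions" counts non-gap
  match states (the published criterion does not say whether gaps count);
  strict/inclusive bounds exactly as printed (>140, <20, ≤100, ≤200), and
  each rejection reports the first failing rule in that order.
* Similarity network: gapless Karlin–Altschul E-values
  `E = K·m·n·exp(−λS)` with standard ungapped BLOSUM62 parameters
  (λ = 0.3176 nats, K = 0.134) on core-only alignment scores — an
  approximation of an all-vs-all BLAST network at the same 0.05 cutoff.
* Poisson distances cap p at 1 − 1e-9; NJ clamps negative branch lengths at
  0 and flags them.
* All stochastic stages take explicit seeds; CLI runs write a manifest
  (input hashes, parameters, package version) sufficient to reproduce the
  artifacts bit-for-bit.

## Problem sizes used in the test and acceptance runs

Closed-loop checks run at the study conditions where those are stated
(6 × 120 sequences, 231 columns, 5% noise, 10-fold CV, 5-fold CFS); Monte
Carlo sample sizes (50 000 for Bayes rates), bootstrap replicate counts in
unit tests (25–100), permutation counts (99–200) and random-tree trial
counts (20 in unit tests, 100 in the acceptance checks) were chosen as the
smallest sizes at which the binomial uncertainty of the checked quantity is
well below the asserted margin.

## Evaluating on the published datasets

The curated training (713 sequences), validation (64 sequences) and
model-organism prediction sets are not distributed with this package.  To
evaluate against them, download the study's deposited data (Dryad
doi:10.5061/dryad.v15dv41sh) and export, under `data/paper/`:
`fig6_training_alignment.fasta` + `fig6_training_labels.tsv`,
`fig6_validation_alignment.fasta` + `fig6_validation_labels.tsv`,
`fig6_prediction_alignment.fasta`, and `donor_binding_columns.txt` (one
aligned column id per line).  The corresponding checks in
`tests/test_acceptance.py` run the full pipeline on those files; with the
files absent they fail with an explanatory message rather than silently
skipping.  Because the property scales and the CFS variant are
reimplementations, agreement with the published accuracies is expected only
within a few percentage points.

## Known limitations

* The Bayesian pattern-partitioning clustering itself (sub-family
  discovery) is out of scope; only per-partition pattern scoring given
  labels is provided.
* Nominal pattern-contrast p-values are selection-biased (see above); use
  the permutation mode for calibrated inference.
* The similarity network approximates BLAST statistics with gapless
  Karlin–Altschul parameters; absolute E-values differ from BLAST's,
  though edges at the 0.05 cutoff agree for clearly related/unrelated
  pairs.
* The synthetic generator draws columns independently; it does not emulate
  phylogenetic autocorrelation between sequences within a family beyond
  shared planted columns, so family-pattern recovery on real data may be
  harder than on synthetic data.
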