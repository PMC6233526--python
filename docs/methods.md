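# Methods

## Problem setting

Given a table of (target, compound, activity) observations with binary
activity labels, the package builds one binary classifier per target
and exposes the panel as a *target profile* predictor: a query molecule
receives, for every target, a pair of conformal p-values (p_A, p_N),
a prediction set at a chosen confidence, and a prediction confidence
1 − min(p_A, p_N). Conformal prediction is used precisely because a
profile of point predictions without calibrated uncertainty is hard to
act on: under the exchangeability assumption the prediction sets cover
the true label at any user-chosen rate.

## Signature descriptors

A height-*h* signature rooted at atom *r* encodes the induced subgraph
of all heavy atoms within graph distance *h* of *r*. Heights {1, 2, 3}
are generated by default; every atom roots exactly one signature per
height, so per-height signature counts always sum to the heavy-atom
count (a cheap full-vector sanity invariant).

Canonical form: the subgraph is serialized by rooted DFS — atom label =
element symbol (lower-case if aromatic) plus formal charge; bond labels
`-`, `=`, `#`, `:`; ring closures written as `@k` back-references to the
DFS visit index of the earlier endpoint — and the canonical string is
the lexicographic minimum over all DFS serializations. For acyclic
subgraphs this minimum factorizes: each branch is minimized
independently and branches are ordered with the pairwise concatenation
comparator (plain lexicographic sorting of branch strings is *wrong*
when one serialization is a prefix of another). Cyclic subgraphs use a
pruned exhaustive search over child orderings; height-limited subgraphs
are small, so the search is cheap in practice. The test-suite checks the
implementation against a brute-force enumeration of all DFS
serializations on every generated molecule with ≤ 8 heavy atoms.

Signatures are tagged with their height, so identical strings arising
at different heights are distinct features. A frozen signature
dictionary fixes the column layout; signatures unseen at predict time
are dropped (a linear model has no weight for them) with a debug-level
count. Hydrogens are implicit; stereochemistry and tautomerism are out
of scope. No claim is made that these strings coincide with any other
signature implementation's grammar — only internal consistency and the
minimality property are guaranteed.

## Dataset preparation

Cleaning follows fixed, order-insensitive rules:

1. **Conflict removal** — every row of a (target, SMILES) key observed
   with both labels is removed; conflicting evidence is discarded, not
   voted on.
2. **Deduplication** — one row per (target, SMILES, activity), keeping
   the first-seen entry ID. SMILES are compared after RDKit
   canonicalization by default (a raw-string switch exists), since two
   different strings for the same molecule placed in training and test
   would leak. An `include_entry_id` switch gives the stricter
   identical-row reading.
3. **Target filter** — targets need at least `min_actives` (default
   100) actives and `min_nonactives` (default 100) non-actives; excluded
   targets are reported with counts and reasons.
4. **Assumed-non-active augmentation** — targets with fewer than
   10,000 known non-actives are topped up with compounds never reported
   active for that target, drawn uniformly without replacement, until
   non-actives reach `nonactive_ratio` (default 2.0) times the actives:
   exactly max(0, ⌈ratio·n_A⌉ − n_N) additions (ceiling guarantees "at
   least"). The 1:2 ratio errs toward more presumed negatives because
   they come from a broader chemical space than the curated actives.
   Augmented records are flagged and **never** enter calibration sets or
   CV test folds — presumed negatives with atypical chemistry may
   sharpen the decision surface, but letting them calibrate the
   p-values would distort the very quantity the user relies on.
5. **External holdout** — an ID list (entry ID or SMILES keyed) moves
   matching records into an external validation partition; the
   partition is exact.

## Conformal machinery

Each inductive conformal predictor (ICP) uses a stratified
proper/calibration split with calibration fraction 0.2 (a conventional
choice; exposed in `SplitConfig`). The underlying model is an
L2-regularized linear SVM with hinge loss (scikit-learn `LinearSVC`,
i.e. LIBLINEAR), cost = inverse regularization, uniform class weights —
Mondrian calibration already delivers class-conditional validity, so no
resampling is needed. Nonconformity is the signed decision value
oriented by hypothesis (α = −d for "A", +d for "N"); decision values are
used raw, since only their ranking matters. The p-value is the
unsmoothed rank statistic (#{α_j ≥ α} + 1)/(n + 1) — deterministic and
slightly conservative; a tie-randomized smoothed variant exists for
exact-validity experiments. Ten ICPs on independent splits are
aggregated by the arithmetic mean of p-values (median available). The
signature dictionary is built once from all training structures (labels
play no role, so nothing leaks) and shared across the ensemble so
feature columns line up.

Models serialize to a single zip archive (manifest JSON, dictionary
TSV, per-ICP weight/calibration arrays); a save → load → predict round
trip is bit-identical. A format-version field makes future layout
changes fail loudly.

### Numerical and degenerate-input choices

* Prediction-set membership is strict (p > ε), consistent with
  p ∈ (0, 1]; ties on the boundary stay out.
* Calibration-size arithmetic: n_cal = ⌊fraction · n_class⌋ clamped to
  [1, n_class − 1]; a class with < 2 non-assumed examples is a fatal
  error (nothing to calibrate on).
* A single-class proper set is a fatal error.
* SVM solver: tol 1e-4, max_iter 20,000, fixed per-ICP random_state
  derived from the split seed; convergence warnings are suppressed as
  the dual solver's residual tolerance is immaterial to rank-based
  p-values.
* RNG discipline: every stochastic unit (split, fold, replicate,
  sampling) draws from `numpy` SeedSequence streams keyed by
  (master seed, unit indices), so any unit reruns identically in
  isolation.

## Hyper-parameter selection

The only swept parameter is the SVM cost, over {1, 10, 100}, by 10-fold
stratified cross-validation with a full ACP trained inside each fold.
Fold predictions are pooled before computing observed fuzziness
(pooling weights every prediction equally; the alternative,
mean-of-fold-OFs, differs only at unequal fold sizes), and the cost with
minimal pooled OF wins, ties to the smaller cost (more regularization,
deterministic). CAOF and MC are reported for information but never
drive selection. Replicate runs repeat the sweep on derived RNG streams
and report per-metric medians.

## Evaluation metrics

With test labels y_i and p-values p_i^A, p_i^N:

* OF = (Σ_{y=A} p^N + Σ_{y=N} p^A) / (m_A + m_N) — mean wrong-class
  p-value, lower is sharper.
* CAOF = Σ_{y=A} p^N / m_A + Σ_{y=N} p^A / m_N — class-averaged form;
  equals 2·OF exactly when classes are balanced, and stops a dominant
  class from hiding minority-class fuzziness.
* MC(ε) — fraction of prediction sets of size 2 ("Both") at
  significance ε; reported on the standard grid rather than at a single
  level, since a single-ε summary hides the trade-off.
* Calibration curve — accuracy (fraction of sets containing the truth)
  at confidences 0.05 … 0.95, step 0.05 (19 points).
* Label-set confusion — counts of observed label × predicted set in
  {{A}, {N}, Both, Null} at confidences 0.8 and 0.9; rows sum to class
  counts. Raising confidence can only grow Both and shrink Null
  (nestedness of conformal sets), which the suite asserts.

All three scalar metrics are tested against naive re-summation oracles
to 1e−12.

## Synthetic data generator

The generator emulates the *statistical shape* of a multi-target binary
activity extract, not its chemistry. Molecules are grown from a small
grammar — an alkyl chain (length 3–8), an optional phenyl substituent
(probability 0.4), up to two decorations from {methyl, hydroxyl,
fluoro} — and each target is tied to a functional-group motif
(carboxylic acid, nitro, nitrile, CF₃, sulfonamide, chlorophenyl,
primary amine). Actives carry the motif, non-actives are verified by
substructure search not to; observed labels are then flipped with
probability `label_noise`, with ground truth recorded, so the task's
Bayes error is known (no predictor can beat error ≈ noise). Default
condition for validity experiments: 1000 + 1000 training molecules,
10% label noise.

One subtlety matters for validity testing: molecules within one
generator call are forced distinct, i.e. sampled *without* replacement
from a fairly concentrated discrete distribution. Two independent calls
are therefore each tilted away from the high-probability molecules and
are **not** exchangeable with each other — enough to break per-class
validity measurably. `generate_train_test` fixes this by drawing the
union once and splitting it uniformly at random, which restores
exchangeability by construction; all validity experiments use it.

The table generator can inject exact duplicate rows and opposite-label
conflict rows (kept disjoint from each other), returning an exact
ledger so the cleaning stages can be verified row-for-row.

What passing tests on this generator do *not* show: robustness to real
assay heterogeneity, activity-cliff chemistry, covariate shift between
data sources, or descriptor behaviour on large druglike molecules —
real extracts violate exchangeability in ways the generator
deliberately does not reproduce.

## Known limitations

* **Mean-aggregated ACPs are not exactly valid.** Averaging positively
  correlated per-ICP p-values concentrates the aggregate toward its
  centre, making the ACP conservative at low significance but
  measurably anti-conservative at high significance (error exceeding
  ε by ~2–3 points at ε ≥ 0.7 under the default conditions). A single
  ICP from the same pipeline passes a per-class 3σ validity band at
  every grid point, which the suite asserts; the aggregated predictor's
  high-ε miscalibration is a property of the aggregation rule itself,
  documented in the conformal-prediction literature. Practical
  confidence levels (0.8, 0.9 — i.e. ε ≤ 0.2) sit in the regime where
  the aggregate is valid-to-conservative.
* The unsmoothed p-value has granularity 1/(n_cal + 1); with small
  calibration sets (e.g. 10 per class) the achievable significance
  levels are coarse.
* Atom contributions use direct linear-weight decomposition onto
  signature root atoms (sum of scores = ensemble decision value minus
  intercept, sign-flipped toward the larger-p class). It is faithful to
  the linear model but attributes a whole neighbourhood's evidence to
  its root atom.
* Conflict removal and deduplication assume the table fits the cleaned
  representation in memory; reading is streaming, cleaning is not.
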