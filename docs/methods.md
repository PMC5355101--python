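# Methods

## Feature construction

A sequence of length L over its molecule alphabet is mapped to a vector
with a composition block and a pseudo block.

**Composition block.** The L − k + 1 overlapping k-mers are counted and
divided by L − k + 1, giving |alphabet|^k frequencies in lexicographic
k-mer order (A < C < G < T, A < C < G < U, amino acids alphabetical).
Defaults: k searched over {2, 3, 4, 5} for DNA/RNA; k = 1 for protein (the
classic 20-dim composition), larger k permitted.

**Correlation unit.** Sequence-order information enters through
physicochemical correlations between *units* at lag j = 1..λ.  For DNA/RNA
the unit is always the dinucleotide (there are L − 1 of them), whatever the
composition-block k; for protein it is the residue.  A sequence yielding n
units admits λ ≤ n − 1, i.e. λ ≤ L − 2 (nucleic acids) or λ ≤ L − 1
(protein); an inadmissible λ is a per-sequence error that names the
sequence and its maximum admissible λ.

**Property standardization.** Each shipped or user-supplied property is
centered and scaled by its *population* SD over the unit alphabet (16
dinucleotides or 20 residues) before any correlation is computed.  A
constant property is rejected.  Standardization makes all downstream
features invariant to the offset and scale of raw property tables, which
the tests exercise directly; it also means the stored table values only
matter up to affine transformation.

Shipped property sets: six DNA dinucleotide helical parameters (Twist,
Tilt, Roll, Shift, Slide, Rise, stored in their published standardized
form), the corresponding six ribodinucleotide geometric parameters, and
the classic protein triple (hydrophobicity, hydrophilicity, side-chain
mass).  Users may substitute any TSV table (symbol column + one column per
property); it passes through the same standardization.

**Correlation modes.**

* *parallel* (type-I, the default): θ_j averages, over all n − j unit
  pairs at lag j, the property-averaged squared difference
  Θ(a,b) = (1/Λ) Σ_ξ [P_ξ(a) − P_ξ(b)]².  θ_j ≥ 0, and a homopolymer
  gives an identically zero pseudo block.
* *series* (type-II, amphiphilic-style): each lag contributes Λ
  per-property product means τ, nested lag-outer/property-inner, so the
  pseudo block has λ·Λ entries and entries may be negative.

**Assembly.** With T the sum of all correlation factors and weight w > 0,
composition components are f_u/(1 + wT) and pseudo components w·c/(1 + wT).
Every vector therefore sums to exactly 1 while 1 + wT > 0.  In series mode
T can be negative enough to make 1 + wT ≤ 0; this is reported as a
degenerate-normalization error rather than silently producing an
unnormalizable vector.  λ = 0 reduces exactly to the k-mer composition.

## Classifier

A C-SVM with RBF kernel exp(−γ‖x−y‖²) is fit by the libsvm engine
(scikit-learn's `SVC`, tolerance 1e-3) on the feature vectors as-is — no
further rescaling, since the sum-to-one normalization already puts all
components on one scale.  Decision values are recomputed from the stored
support-vector expansion with elementwise numpy operations, which makes
scores independent of prediction-batch composition and row order, and
bit-identical across save/load.  The sign of the decision value is the
predicted label; an exact 0 maps to +1.

Models persist as a single zip archive: `metadata.json` (format version,
molecule, feature recipe, standardized property matrix, SVM parameters,
training summary) plus `model.libsvm` in the libsvm c_svc text dialect.
Floats are serialized with shortest round-trip `repr`, so reloading
reproduces every score bit-for-bit; unknown archive members, missing
members or a foreign format version are refused by name.

## Cross-validation and metrics

Folds are stratified by round-robin assignment of each class's shuffled
members, continuing one global fold counter across classes: per-fold class
counts stay within one of proportionality and K = N degenerates to exactly
one sample per fold, so jackknife (leave-one-out, folds in dataset order)
and K-fold at K = N pool identical predictions.  All randomness flows from
one user-visible seed.

Metrics are **pooled**: held-out predictions and decision scores from all
folds are collected and a single report is computed over the union.
Pooling keeps MCC well-defined with tiny folds and makes the result
independent of fold evaluation order.  Acc, Sn, Sp and MCC follow their
closed forms with MCC := 0 whenever a denominator factor vanishes; Sn/Sp
are 0 when their class is absent from the evaluation.  AUC is the
Mann–Whitney rank statistic with ties counted ½ (computed via
scikit-learn), identical to the trapezoidal area under the tie-aware ROC;
curve points are emitted at every distinct threshold.

## Parameter selection

The joint grid over (k, λ, w, mode, C, γ) is evaluated exhaustively, every
candidate on the SAME fold assignment so comparisons are paired.  Defaults:

| parameter | default | rationale |
|---|---|---|
| k | {2,3,4,5} (DNA/RNA), {1} (protein) | k must reach the scale of short motifs for the composition block to resolve them |
| λ | {1..5} | correlation depth; bounded by the shortest sequence |
| w | {0.1, 0.3, 0.5, 0.7, 0.9} | pseudo-block weight |
| mode | parallel | series selectable |
| C | {2⁻², 2⁰, 2², 2⁴, 2⁶} | soft-margin cost |
| γ | {2⁻⁶ .. 2⁶} (powers of 4) | sum-to-one vectors have pairwise squared distances ≪ 1, so useful RBF widths extend well above 1 |

The objective defaults to pooled CV accuracy (AUC and MCC selectable).
Ties break toward the lexicographically earlier candidate — smaller
(k, λ, w, C, γ), i.e. the simpler model.  Candidates inadmissible for the
dataset's shortest sequence are skipped with a logged reason.  After
selection the winner is refit on the full benchmark; the reported metrics
remain the winning candidate's CV metrics, which are model-selection
statistics, not unbiased generalization estimates (no nested CV).

Grid evaluation may be distributed over worker processes (joblib);
candidates are independent, share the fold assignment, and results are
reassembled in grid order, so the outcome is invariant to worker count and
scheduling — the contract the determinism tests pin down.

## Synthetic benchmarks

The generator emulates the simplest signals a benchmark can carry:
i.i.d. uniform background with (a) a fixed motif overwritten at a uniform
random position in positives with a given insertion probability, (b) a
tilted symbol distribution in positives, or (c) no signal at all.
Per-sequence RNG streams are sub-seeded by (class, index) counters, so
enlarging a benchmark never alters existing sequences.  Test and
acceptance runs use 100 sequences per class of length 100 (motif and null
conditions) — large enough for stable pooled-CV metrics, small enough to
keep full runs in seconds — with an 8-bp planted motif; unit fixtures use
a 20-bp motif where a perfectly separable dataset is required.

What passing these benchmarks does *not* show: real genomic background is
not i.i.d. (repeats, GC structure, HMM-like dependence), motif instances
vary, and class balance is rarely exact.  Recovery of a planted uniform
motif is a floor, not a field benchmark.

## Numerical and design notes

* Sum-to-one holds to 1e−9 in tests; correlation factors match a naive
  double-loop oracle to 1e−10.
* Ambiguity codes and gaps are rejected at parse time (optionally whole
  records are dropped and counted) because deleting residues silently
  would shift every correlation lag.  RNA keeps its own alphabet and
  property table — no U→T aliasing.
* The benchmark is supplied as two FASTA files (positives, negatives);
  an independent labeled hold-out is evaluated via `predict
  --truth-pos/--truth-neg` rather than as a CV mode.
* No probability calibration: ROC/AUC rank raw decision values, avoiding
  Platt-scaling nondeterminism.

## Limitations

Binary classification only; RBF kernel only; exhaustive grid (no Bayesian
or random search); CV metrics of the selected candidate carry selection
optimism; shipped property sets are single canonical choices, not curated
collections of the dozens of published indices.
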