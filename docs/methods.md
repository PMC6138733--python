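# Methods

## Problem and model

The classifier decides, from sequence alone, whether a peptide (length
≥ 10, canonical 20-letter alphabet) is anti-angiogenic. The design rests
on two empirical observations about this class: anti-angiogenic peptides
are compositionally biased (Cys, Pro, Ser, Arg, Trp, Thr, Gly enriched;
Ala, Asp, Ile, Leu, Val, Phe depleted), and the bias is
position-specific at the N- and C-termini. The three encoders target
exactly these signals: Bi-profile Bayes captures terminal
position-specific composition, CTD captures global
hydrophobicity/charge composition and ordering, and the DFT power
spectrum captures periodicity of hydrophobicity/hydrophilicity
profiles.

## Encoders

**Bi-profile Bayes (BpB).** Four `m × 20` tables of
`P(residue | position, class)` estimated by add-k smoothing:
`(count + pseudocount) / (n_class + 20·pseudocount)`. Defaults:
`m = 10` (the windows the terminal signal is reported in; also the
minimum benchmark peptide length, so every peptide has both windows) and
`pseudocount = 1`. Smoothing is not strictly required — the posteriors
are used as features, not likelihoods — but keeps all features strictly
inside (0, 1) and stabilises the downstream naïve-Bayes variance
estimates; `pseudocount = 0` is allowed for exact hand checks.
C-terminal window positions are indexed left-to-right (position *i*
reads sequence position `L − m + i`); the orientation is a convention
and any fixed choice is equivalent for learning. Because the tables are
class-conditional training statistics, the encoder is refit on each
training fold by default (`bpb_refit="fold"`); `bpb_refit="full"`
reproduces the simpler fit-once workflow, which leaks held-out labels
into the encoding and is therefore mildly optimistic.

**CTD.** The four-group hydrophobicity/charge partition (hydrophobic,
polar, positively charged, negatively charged). Distribution marks use
occurrence index `ceil(q·N_i)` with the first mark fixed at occurrence 1
— the dominant CTD convention, and the only one of the ceiling/floor
family that yields a valid index for every `N_i ≥ 1`. Positions are
1-based and divided by `L`, so marks lie in (0, 1]; an absent group
contributes zeros to its composition, transitions and distribution,
keeping the 30-vector total and finite.

**DFT.** `PS(k) = |F(k)|²` with the sum over residue index `n = 1..L`;
this differs from the usual `n = 0..L−1` convention by a unit-modulus
phase per coefficient, so powers are unaffected and the FFT is used
internally (the test oracle evaluates the `n = 1..L` sum directly). Ten
low-frequency components per property, *including* `k = 0` — the DC
term carries the mean property level, which is itself discriminative —
for 2 × 10 = 20 features. Scales default to Kyte–Doolittle
(hydrophobicity) and Hopp–Woods (hydrophilicity), the field-standard
pair; both are overridable from a two-column text table, and results on
real data may shift with the scale choice. Profiles are used raw; an
optional zero-mean centering switch zeroes `PS(0)`.

## Feature selection

Relief runs one deterministic pass over every instance in index order by
default (`n_iter="all"`), making weights an exact function of the data;
seeded random sampling with replacement is available. The `diff` used
both for the neighbour search (through the Euclidean distance) and the
weight update is the per-feature absolute difference on min–max-scaled
values; scaling makes weights invariant to affine rescaling of
individual features. Weights are not clipped to any interval: standard
Relief weights live in [−1, 1], and since ranking is order-based the raw
values are used as-is. Ties — in the neighbour search and in the
ranking — break toward the lowest original index.

IFS evaluates prefixes k = 1..d of the ranking with an injected
evaluator (default: pooled 10-fold cross-validated accuracy of the
configured fusion pair at a fixed seed) and keeps the smallest k
attaining the maximum. Placement of selection relative to
cross-validation is explicit: `selection="full"` ranks and selects once
on the full dataset and then cross-validates on the chosen subset (the
classical protocol for reporting an IFS curve; optimistic because the
test folds influenced the selection), while `selection="nested"`
re-runs Relief + IFS inside every training fold for an honest estimate.

## Classifiers and fusion

*Gaussian NB*: maximum-likelihood per-class means/variances, variances
floored at `1e-9 × max feature variance` (absolute 1e-9 if all zero), so
constant features fall back to the priors; posteriors computed in the
log domain. *Logistic regression*: IRLS maximising the L2-penalised
log-likelihood, ridge `1e-8` on the slopes (near-unpenalised but
bounding the weights on separable data), unpenalised intercept,
convergence when the max weight change drops below 1e-8 or at 100
iterations. *1-NN*: Euclidean, ties to the lowest training index,
hard 0/1 pseudo-probabilities — its ROC is a single point, so its AUC
understates its accuracy.

The fusion pair is (best sensitivity, best specificity) among the
candidates under cross-validation; if one candidate wins both criteria
it is paired with the runner-up on specificity so the pair is distinct.
The fused score is the plain arithmetic mean of the two positive-class
probabilities, thresholded at 0.5 with the boundary mapped to positive.
The default pair is LR (sensitive) + NB (specific), the combination
that wins on BpB features; `classifier_pair="auto"` re-derives the pair
from inner cross-validation.

## Evaluation

Stratified k-fold assignment shuffles each class with a seeded RNG and
deals round-robin, rotating the starting fold between classes so the
remainders spread (107 + 107 at k = 10 gives fold sizes 21–22 with
10–11 positives each). `k` may extend to the sample count
(leave-one-out), where single-sample folds can lack a class. Metrics
come from one confusion matrix pooled over folds (micro-average) —
stable for ~21-sample folds — with per-fold accuracies retained; MCC is
defined as 0, with a warning, when any denominator factor vanishes. ROC
sweeps all distinct pooled scores with ties grouped; trapezoidal AUC,
which equals the Mann–Whitney pair-counting statistic with half credit
for ties (asserted against an independent oracle in the tests). All
randomness in a run derives from one recorded seed.

## Synthetic data

The generator draws residues i.i.d. from a background multinomial
(uniform 1/20 by default, overridable) and plants the class signal by
multiplying the probability mass of the class's enriched residue set —
`{C,P,S,R,W,T,G}` in positives, `{A,D,I,L,V,F}` in negatives — by
`1 + 2·effect` in the sequence body and `1 + 4·effect` inside the first
and last `terminal_window` (default 10) positions, renormalising each
time. The doubled terminal factor creates the position-specific terminal
signal BpB is designed to detect. Defaults mirror the benchmark shape:
107 + 107 peptides, lengths uniform on 10–30. `effect = 0` is an exact
null (classes exchangeable); `effect = 1` produces near-saturated
separation (cross-validated AUC ≈ 1).

What the generator does *not* emulate: residue autocorrelation within a
peptide, realistic background composition, shared motifs/homology
between peptides, or the ~70% identity cap of the curated benchmark.
Passing tests on synthetic data therefore demonstrate correct recovery
of planted compositional/terminal signal under i.i.d. residues — not
the absolute accuracy achievable on real anti-angiogenic peptides,
which also depends on the unpublished fold seeds and toolkit internals
of any reference run.

## Problem sizes and numerical choices

Test and acceptance runs use benchmark-scale problems: 107 + 107
sequences, 40–90 features, 10-fold cross-validation, 20-seed panels for
the null and ranking checks, and ≤ 8-sample instances for the
brute-force Relief oracle — sizes at which every check is exact or
well-powered while the full suite stays fast. Degenerate inputs are
handled explicitly: empty classes, sequences shorter than an encoder's
window, constant features (zero Relief weight, floored NB variance),
absent CTD groups, and one-class score vectors all raise or default as
documented above.

## Known limitations

* Absolute agreement with published benchmark figures cannot be checked
  in-repo: the curated 107 + 107 peptide set is third-party supplementary
  data and is not redistributed here. `tests/test_acceptance.py`
  contains the comparison (accuracy within ±0.05 of 0.832 over 10 fold
  seeds, full-fit protocol) and runs it when the file is supplied at
  `data/benchmark.fasta`.
* The 1-NN base yields degenerate probabilities, limiting its value
  inside the fusion; it is retained as a candidate for completeness.
* Multi-class labels, nucleotide input, redundancy reduction and
  alignment are out of scope.
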