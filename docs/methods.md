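# Methods

## Fusion model

Each base learner emits a row-stochastic decision-score matrix
(samples × classes). For a probability `p` the two fuzzy ranks are
`R1(p) = 1 − tanh((p−1)²/2)` and `R2(p) = 1 − exp(−(p−1)²/2)`. Over
[0, 1] `R1` rises from `1 − tanh(0.5) ≈ 0.53788` to exactly 1 and `R2`
falls from `1 − exp(−0.5) ≈ 0.39347` to exactly 0; the two curves have
opposite concavity, so their product `RS = R1·R2` weights closeness to
and deviation from full confidence simultaneously. `RS` is strictly
decreasing with a maximum of ≈ 0.21166 at `p = 0` and is zero only at
`p = 1`. The fused score of class *k* is the sum of `RS` over learners,
and the class with the smallest fused score wins.

Although the transforms are called ranks, they are pointwise functions
of each probability: no sorting or ordinal ranking occurs. The rank
score is applied per class, `RS_k = R1(P_k)·R2(P_k)`: a reading with a
fixed class subscript would make every class's rank score identical and
is incompatible with the per-class fused sum and the worked example.

Consequences that the test suite verifies rather than assumes:

* a single learner fused alone reproduces its own argmax exactly
  (strict monotonicity of `RS`);
* duplicated learners and an added uniform learner (all rows `1/C`)
  never change a decision;
* fusion is equivariant under consistent class permutation and
  invariant under sample reordering.

Argmin ties are broken toward the lowest class index. Ties are measure-
zero for continuous scores but occur for degenerate inputs (e.g. all-
uniform rows); a deterministic rule keeps reruns reproducible.

## Worked-example bundle

`worked_example_bundle()` packages a 1-sample, 4-class, 3-learner bundle
anchored to the documented walkthrough: learner-1/class-1 probability
0.261, per-learner class-1 rank scores 0.175 / 0.134 / 0.148, class-1
fused score ≈ 0.458, fused winner class 2, with learners 1 and 3
individually favouring class 2 and learner 2 favouring class 1. Only
those quantities are anchored; the remaining probability entries are a
**synthetic reconstruction**, solved numerically (least squares under
row-sum and fused-score constraints, class-1 probabilities obtained by
inverting `RS`), and nothing beyond the anchored quantities is asserted
about them. The walkthrough's 3-decimal prints of the individual ranks at
0.261 (0.735 / 0.238) differ from double-precision recomputation
(0.7335 / 0.2390) by ≈ 0.0015 — rounding of an unprinted intermediate —
so tests anchor the individual ranks at ±0.002 and rely on the product
(0.175) and the final decision, which are stable.

## Baseline fusion rules

* **Majority voting** — each learner votes its argmax. Vote ties are
  broken by the largest probability summed over learners among the tied
  classes, then by lowest index. The tie policy is a package choice; it
  is deterministic and uses information already present.
* **Probability averaging** — unweighted mean of the score matrices,
  argmax winner.
* **Weighted averaging** — convex combination with non-negative weights
  normalised to sum 1. When no weights are supplied they are fitted by
  exhaustive simplex grid search on accuracy (default step 0.1); the
  exact uniform vector is always a candidate, so ties resolve toward
  uniform weighting even when the grid cannot represent it.

## Evaluation conventions

The confusion matrix is oriented rows = predicted, columns = true.
Accuracy is trace/total. Per-class precision is diagonal over row sum,
per-class recall diagonal over column sum, per-class F1 their harmonic
mean; a zero denominator yields 0, keeping every metric defined. The
reported averages are **macro** (unweighted class means) by default:
pooled micro-averaging in single-label multiclass collapses precision,
recall and F1 to the accuracy (an identity the tests assert), so it
cannot produce distinct summary columns; micro and support-weighted
averaging remain available behind a flag.

K-fold evaluation stratifies by class (shuffle within class, round-robin
deal, so fold class counts differ by at most one) from an explicit seed,
and reports per-metric mean and **population** standard deviation
(divisor n; configurable by computing from `per_fold` directly). The
base learners are fixed external score producers, so folds partition
only the evaluation samples; for the weighted-average baseline without
given weights, weights are refitted on each fold's complement so the
fold itself never informs them.

McNemar's paired test counts discordant samples (n01: A correct/B
wrong; n10: the reverse). Below 25 discordant pairs the exact two-sided
binomial is used, `p = min(1, 2·P[X ≤ min(n01,n10)])` with
`X ~ Bin(n01+n10, ½)`; at 25 or more, the chi-square approximation with
continuity correction `(|n01−n10|−1)²/(n01+n10)` on 1 df. The 25-pair
switch is standard practice. Zero discordant pairs returns p = 1 by
definition.

## Synthetic score simulator

The generator emulates softmax outputs of several classifiers on a
shared sample set. Per sample a true class is drawn from the class
proportions (default uniform). Each learner "intends" the true class
with probability `target_accuracy` (default 0.80, a realistic
single-model accuracy for a hard multi-class image problem) and a wrong
class otherwise. `error_correlation` ∈ [0, 1] is the probability that a
sample's miss event and wrong class are shared across learners (a
common latent confusion) rather than drawn independently: at 0 the
learners err independently and an ensemble can correct them; at 1 all
learners predict identically and no fusion rule can beat a single
learner — both regimes are asserted in the tests. The probability row
is a Dirichlet draw with concentration `confidence` (default 6) on the
intended class and 1 elsewhere; the largest component is then swapped
onto the intended class so the realized argmax accuracy is a clean
Binomial draw at the target rate (±2% at n = 10,000). All randomness
descends from one seed via `SeedSequence` spawning (label stream,
shared-confusion stream, one stream per learner), making bundles
bitwise reproducible.

What the simulator does **not** emulate: the clustered, temperature-
miscalibrated confidence profiles of real convolutional networks,
class-dependent confusion structure, or any image content. Passing
tests therefore demonstrate correctness and the qualitative
independent-errors → ensemble-boost mechanism, not performance on real
cytology data. Which fusion rule wins on simulated bundles depends on
the noise model (with symmetric Dirichlet noise, hard voting can edge
out confidence-weighted rules); no claim about relative rule ranking on
real data follows from it.

## Numerical choices and problem sizes

Computation is double precision throughout; user-facing reports print
at full precision and comparisons in tests use explicit tolerances
(1e-12 for algebraic identities, ±0.002 for the walkthrough's printed
values). Score rows whose sums deviate from 1 by ≤ 1e-3 are silently
renormalized (low-precision serialization of softmax outputs); larger
deviations are rejected as corrupt, naming the offending row. Input
probabilities may undershoot/overshoot [0, 1] by 1e-9 before a domain
error is raised, absorbing representation noise.

Default study sizes: monotonicity on a 1,001-point grid; single-learner
equivalence on 1,000 random rows; invariance properties on 100
randomized bundles each; metric oracle agreement on 1,000 random
prediction sets; the ensemble-boost study at n = 10,000 samples, C = 5,
three learners at 0.80 accuracy. These sizes give stable Binomial
margins (±2% at n = 10,000) while the full suite runs in seconds.

## Known limitations

* The fusion rule has no learnable parameters and no alternative rank
  generators; the transforms are fixed by design.
* Weighted-average weight search is exhaustive on a simplex grid and
  scales combinatorially with the number of learners (fine for the
  2–5 learners the tool targets).
* The evaluator covers single-label multiclass only — no multilabel,
  ROC/AUC, or calibration analysis.
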