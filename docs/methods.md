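# Methods

## The classification model

seq-GNPED classifies examinees into binary attribute-mastery profiles from
polytomous item scores without estimating a parametric item response
model. Its ingredients:

**Sequential decomposition.** An item with maximum score S_j is modelled
as S_j ordered steps; scoring h means completing steps 1..h and failing
step h+1. The category-level Q-matrix (Q_c) assigns each step a binary
requirement vector q_jh over the K attributes. Observed scores are
expanded to step indicators y_ijh = 1{X_ij ≥ h}, which are non-increasing
in h by construction and losslessly invertible (X_ij = Σ_h y_ijh).

**Ideal responses.** For each of the 2^K candidate profiles, each (j, h)
cell carries a cumulative conjunctive ideal response (1 iff every
attribute required by steps 1..h is mastered) and a cumulative disjunctive
one (1 iff each of steps 1..h has at least one mastered required
attribute). The conjunctive value never exceeds the disjunctive one, and
both are non-increasing in h. The working ideal response is the convex
combination with a data-estimated weight, so the method adapts between
non-compensatory and compensatory response mechanisms cell by cell.

**Collapsed classes.** Only the attributes required somewhere in steps
1..h can influence the ideal responses at (j, h). We therefore partition
the 2^K profiles by their values on that cumulative union set; each cell
of the partition (collapsed class) shares a single weight. Collapsing on
the union of steps 1..h — rather than on step h's own q-vector alone — is
the weakest collapsing under which the per-class conjunctive and
disjunctive ideals are constants, which the weight estimator requires;
with single-step items the two choices coincide. The table of per-pattern
ideal responses is materialized densely (guarded at K ≤ 15; the intended
regime is K ≤ 8), while weights are stored per class so an update costs
O(#classes) rather than O(2^K).

**Weight estimation.** For class l at cell (j, h) with class ideal
responses (η⁽ᶜ⁾, η⁽ᵈ⁾), the least-squares weight given the examinees
currently assigned to the class is
ŵ = Σ_i (y_ijh − η⁽ᵈ⁾) / (n (η⁽ᶜ⁾ − η⁽ᵈ⁾)). Because η⁽ᶜ⁾ ≤ η⁽ᵈ⁾, the only
non-degenerate configuration is (0, 1), where ŵ = 1 − (class mean
response) — computed literally in that form so the identity is exact in
floating point. Numerical conventions:

- degenerate cells (η⁽ᶜ⁾ = η⁽ᵈ⁾): weight fixed at 1 and flagged; the
  weighted ideal response does not depend on it;
- classes with no currently assigned examinee: the previous iteration's
  weight is retained, or 0.5 (a neutral mixture) on the first pass;
- estimates are clamped to [0, 1] as a guard; the (0,1) closed form
  already lands there;
- an all-zero q-vector row is allowed with a warning: its conjunctive
  ideal is vacuously 1 and its disjunctive ideal 0 (empty-product
  convention), flagging a non-diagnostic step.

**Classification and iteration.** Each examinee receives the profile
minimizing the squared Euclidean distance to the weighted ideal response
vector over all Σ_j S_j cells; ties go to the lowest profile index in the
canonical enumeration (binary counting, attribute 1 the most significant
bit) so that fits are bit-reproducible. Fitting starts from the purely
conjunctive classification, then alternates weight estimation and
reclassification until the fraction of examinees changing profile is
below ε (default 0.001, strict comparison) or `max_iter` (default 100)
passes have run. The final pass's weights are reported. Identical inputs
yield bit-identical results; the loop always terminates.

## Simulators

The generators define the conditions under which the package's accuracy
claims are evaluated.

**Response generation.** Both schemes share a two-stage mechanism. First a
*category walk* determines the examinee's model-implied item score: steps
are attempted in order and the implied score is the last step passed. A
step is passed with probability 1 under full mastery of its required
attributes and 0 under none. Second, an *item-level* slip perturbs the
implied score: it is kept with probability 1 − s and otherwise replaced by
a uniformly chosen different score (each wrong score gets mass s/S_j).
Defining item quality at the item-score level — rather than compounding a
per-step slip — keeps s interpretable across items with different step
counts: a fully mastering examinee earns the implied score with
probability exactly 1 − s whether the item has one step or three. The
quality levels are s ∈ {0.05, 0.10, 0.15} (high/medium/low).

Under the sequential DINA scheme the walk is deterministic (partial
mastery of a step fails it). Under the sequential G-DINA scheme each item
draws a DINA or a saturated link with probability ½; on saturated-link
items a step whose attributes are partially mastered is passed with a
probability drawn from U(0.3, 0.7) — once per (step, reduced partial
pattern) per replication, kept as drawn without a monotonicity repair,
since nested partial patterns carry no ordering constraint here. An
all-DINA link draw makes the two schemes coincide.

**Profile distributions.** Either i.i.d. uniform over the 2^K patterns,
or a higher-order model: latent trait θ_i ~ N(0,1), attribute k mastered
with probability logistic(λ_1k (θ_i − λ_0k)), discriminations
λ_1k ~ U(1, 2), difficulties λ_0k on the equidistant grid over
[−1.5, 1.5]. The higher-order model induces positively correlated
attributes with heterogeneous base rates.

**Design manipulations.**

- *Q-matrix misspecification*: ⌈rate × #rows⌉ category rows are chosen
  without replacement and each replaced by a uniformly drawn different
  nonzero q-vector at Hamming distance ≤ 3. In study cells, data are
  generated under the true matrix and only the fitted matrix is
  corrupted — the only reading under which a "misspecification rate" is
  meaningful.
- *Polytomous proportion*: relative to the bundled 21-item design
  (16 polytomous items), 75% keeps the design, 50% converts 5 randomly
  chosen polytomous items to dichotomous, 25% converts 10. A converted
  item becomes a single step whose q-vector is the union (element-wise OR)
  of its original steps — completing the whole item requires every step's
  attributes — and scoring 1 means what scoring the old maximum did. The
  design matrix is adjusted *before* generation (the converted items are
  dichotomous in the administered test); a post-hoc score-recoding variant
  (`reduce_polytomous_proportion`, score 1 iff the old maximum) is also
  provided for transforming existing data.

## Study runner and problem sizes

A study is the cross-product of factor lists (sample size, slip,
distribution, proportion, misspecification rate) with R replications per
cell (default 100, matching the simulation design the bundled Q_c comes
from). Seeds derive from (master seed, cell index, replication) via
`numpy.random.SeedSequence`, so any cell or replication can be reproduced
in isolation and parallel execution cannot change results. The acceptance
script re-runs six representative cells — N ∈ {30, 100, 200},
s ∈ {0.05, 0.10, 0.15}, both distributions, 75% and 25% proportions — at
R = 100, sizes at which a full run takes seconds on one CPU while the
Monte-Carlo standard error of a cell mean stays below 0.01.

## What the simulations do and do not show

The generators emulate the designed conditions of a diagnostic assessment:
a known, correctly specified (or deliberately corrupted) Q_c, independent
examinees, independent items given the profile, and a single slip
parameter shared by all items. Real classroom data depart from this in
ways the simulations do not probe: item-specific and examinee-specific
quality, local dependence among steps beyond the sequential structure,
rater effects in partial-credit scoring, missingness, and Q-matrices whose
misspecification is systematic rather than random. Passing the simulation
suite therefore certifies the algorithm and its implementation under the
stated generating models, not classification accuracy on any particular
empirical test.

## Known limitations

- The dense 2^K pattern scan makes fitting exponential in K; practical up
  to K ≈ 15, intended for the K ≤ 8 regime of classroom assessment.
- No uncertainty quantification for the classifications (no posterior
  probabilities or standard errors); the method is a point classifier.
- The weight estimator pools examinees by *estimated* class membership,
  so with very small classes (N ≪ 2^{K*}) weights are noisy; empty
  classes fall back to the neutral default.
- Parametric estimation of the sequential G-DINA model (the comparison
  arm of the original simulation studies) is out of scope; only its
  generative side is implemented.
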