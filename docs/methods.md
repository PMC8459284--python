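# Methods

## Model

Fix a restrictor set *A* of size *n* (default 10). A structure is a
length-*n* Boolean vector; bit *i* says whether object *o_i* of *A* is in
the scope set *B*. Structures are indexed lexicographically with False <
True and the leftmost bit most significant (index 0 = all-False, index
2^n − 1 = all-True); every cross-module index uses this one convention. A
quantifier is a truth table over the 2^n structures — the meaning of a
conservative, universe-independent determiner for this fixed *A*. *M′* is a
substructure of *M* iff *M′* is False wherever *M* is False; the relation is
reflexive and partial-orders the structure space as a subset lattice.

## Measures

All degrees have the form 1 − H(1_Q | aux)/H(1_Q) with uniform probability
on structures and base-2 entropies (the ratio makes the base irrelevant;
0·log 0 := 0). The auxiliary variables:

- upward monotonicity: the indicator of a verifying (reflexive)
  substructure; downward: mirror with superstructures. A quantifier scores
  exactly 1 in a direction iff it is monotone in that direction or constant.
- quantity: the count # = |A∩B|. Score exactly 1 iff the quantifier is
  permutation invariant or constant.

**Combination of the two directions.** The overall degree is the maximum of
the four directional degrees obtained from the quantifier *and its
complement* (`combination="complement_max"`; `"max"` and `"mean"` over the
plain pair are selectable alternatives). Including the complement matters
for quantifiers whose own verifying-substructure indicator is constant and
hence uninformative — parity is the exemplar: its upward and downward
degrees are both 0, yet the complement's indicators still carry information
and give the overall degree 0.00098 (≈ 0.001) at n = 10. The maximum
preserves the characterization "degree 1 ⇔ monotone in some direction or
constant", which the test suite checks exhaustively for n ≤ 4. Under this
rule the count window "between 3 and 5" at n = 10 scores 0.7291, driven by
its downward component. Alternative published values for such windows
depend on details of the direction-combination that are not identifiable
from the degree-1 characterization alone; the rule used here is fixed,
documented, and exhaustively cross-checked against an independently coded
entropy oracle.

**Zero-entropy convention.** Constant (degenerate) quantifiers have
H(1_Q) = 0; every degree is then defined as 1 (a constant function is
trivially monotone and quantitative). The convention lives in one constant
(`quantevo.measures.ZERO_ENTROPY_DEGREE`) so the alternative (0) can be
toggled. Note the asymmetry it creates: an *exactly* constant table scores
1 while a nearly constant table scores low, because the measure is highly
sensitive to isolated exceptions.

Indicators are computed by an OR zeta transform over the subset lattice
(O(n·2^n) per quantifier), exact for any n the table itself fits in memory
(n ≤ 24 guarded; the study uses n = 10). Quantitative-class enumeration
works on count tables of length n + 1 and needs no full-table scan.

## Agents

Architecture: input(n) → dense(16) → ReLU → dense(16) → ReLU → batch
normalization → dense(1) → sigmoid. Weights and biases use the
fan-in-scaled uniform initialization U(±1/√fan_in), seeded; batch-norm
starts at gain 1, shift 0. Training is minibatch Adam (lr 1e-3, betas
0.9/0.999, batch size 32, data reshuffled every epoch from the agent's own
stream) on mean binary cross-entropy; the backward pass is implemented
directly in numpy and verified against numerical gradients.

Two placement/mode choices are load-bearing and were decided by their
population-level consequences:

- **Normalization of the rectified activations** (ReLU then batch-norm)
  rather than the pre-activations. With the pre-activation order, an
  untrained agent's output sign is dominated by accumulated bias terms:
  mean degeneracy of generation-0 languages is 0.73 with 18% above 0.9, and
  every chain collapses into the constant-quantifier attractor. Normalizing
  the rectified output centers the scores of an untrained net (mean
  degeneracy 0.61, none above 0.9), and chains instead fix on structured
  monotone languages.
- **Production uses the statistics of the full structure space.** The
  canonical confidences are computed in a single batch over all 2^n
  structures, so normalization statistics come from that fixed reference
  batch rather than from frozen running averages. Production remains
  deterministic (the reference batch never varies), and untrained agents
  speak varied, unstructured languages — the baseline condition the chains
  start from. Running averages are still tracked and checkpointed.

Production rounds the confidence at 0.5, ties (a measure-zero event) going
to 1. Children are always freshly initialized; weights are never inherited.

## Chains

Per generation and child: a cultural parent is drawn uniformly with
replacement; `bottleneck` structures are drawn uniformly with replacement
(a without-replacement dialect is available via `with_replacement=False`,
relevant at bottleneck 1024 = the whole space, where with-replacement still
leaves ~37% of structures unseen); labels are the parent's deterministic
productions; under the shuffling condition every example's bits are
permuted by a fresh uniform permutation (count-preserving, label
unchanged); the child trains for `epochs` epochs. All randomness descends
from one master seed through `numpy.random.SeedSequence` spawning — one
sequence per generation, one per agent within it — so runs are replayable
bit-for-bit.

Defaults follow the study design: n = 10, population 10, 301 generations,
bottleneck ∈ {200, 512, 715, 1024} × epochs ∈ {4, 8}, 20 trials per cell
(`quantevo.experiments.PAPER_GRID`). Measures are computed on the extracted
(rounded) truth tables; raw confidences can be retained per snapshot for
threshold profiles.

## What the simulations show, and at what scale

The test suite runs scaled-down conditions chosen to keep the default
`pytest` run in minutes: 5 chains of 100 generations per experimental
condition at the bottleneck-1024 / 8-epoch cell, against 300-sample
random-quantifier and random-agent baselines. In these conditions the
package reproduces the qualitative regime map: no emergence at bottleneck
200 / 4 epochs; fixation on single-index ultrafilter languages (degenerate
quantifiers a rare minority) without the channel; and, with the permutation
channel, convergence to either nearly degenerate languages or vague
count-threshold languages with jointly high monotonicity and quantity.
Full-grid runs (160 chains × 301 generations per experiment) are what
`quantevo grid` executes and take hours, not minutes.

## Synthetic data and external validity

Everything the model consumes is generated internally: structures are
exhaustively enumerable, "data" are parent productions, and named
quantifiers are fixtures. The generator therefore emulates the *formal*
conditions of the transmission argument — fixed finite restrictor,
noiseless deterministic production, uniform prompting — and none of the
complications of human learning (variable domains, noisy judgments,
communicative pressure, contextual restriction). Passing tests show that
the learnability-plus-transmission mechanism suffices to concentrate a
neural population on monotone (and, under shuffling, quantitative)
meanings in this idealized setting; they do not show that human quantifier
inventories arose this way.

## Numerical notes and limitations

- Entropies use exact integer counts; degrees are clamped to [0, 1] against
  float round-off; oracle agreement is verified to 1e-9 for all 65,536
  quantifiers at n = 4.
- Pattern classification is exact-match only (under the four 0/1 switch
  combinations); noisy near-misses deliberately fall to "other", so pattern
  shares are conservative.
- Threshold-profile dispersion is a standard deviation, a summary choice.
- The learning hyperparameters left open by the architecture (learning
  rate, batch size, initialization scheme) are declared defaults, exposed
  in `AgentConfig`, and logged with every run; population-level outcomes
  (which attractor a chain reaches, and how fast) are sensitive to them.
- Fixed-size structures cannot distinguish cardinal from proportional
  readings of the evolved threshold languages; variable-size structures and
  recurrent agents are out of scope.
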