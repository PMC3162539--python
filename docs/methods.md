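# Methods

## The Bayesian discretization score

A discretization of one continuous predictor X against a categorical target
Z with J classes is a partition of the sorted distinct values of X into W
contiguous intervals, equivalently a set of cut points placed in the gaps
between consecutive distinct values. The score of a discretization M is the
joint probability P(M)·P(D | M); since the evidence P(D) is shared by all
candidates, maximizing this product maximizes the posterior P(M | D).

**Structure prior.** Cut counts are modelled as a Poisson process over the
predictor's observed range [x₁, x_n'] with total mean λ, so the expected
number of cut points over the whole range is λ and the probability of at
least one cut in gap k (width d(k,k+1), range d(1,n')) is

    Prior(k) = 1 − exp(−λ · d(k,k+1) / d(1,n')).

Two virtual boundary gaps — below the smallest and above the largest value —
always carry a cut (Prior = 1): there is always an interval below and above
the data. An interval spanning distinct values b..a contributes
Π_{k=b..a−1} (1 − Prior(k)) · Prior(a); interval priors multiply
independently, and expanding the product shows the prior over all 2^(n'−1)
cut patterns sums to exactly 1 (a property the tests assert numerically).
The proportional-to-width allocation means long empty gaps are cheap places
to cut and dense runs of values are expensive to break — the behaviour one
wants on expression data, where a wide gap often separates biologically
distinct regimes.

**Parameter prior and marginal likelihood.** Within interval i the labels
are i.i.d. multinomial with parameters θ_ij carrying a Dirichlet prior with
hyperparameters α_ij (α_i = Σ_j α_ij). Integrating θ out gives, per
interval,

    Γ(α_i)/Γ(α_i + n_i) · Π_j Γ(α_ij + n_ij)/Γ(α_ij),

which with all α_ij = 1 reduces to (J−1)!/(n_i + J − 1)! · Π_j n_ij!.
The closed form assumes complete data; the table reader rejects missing
cells for this reason. Hyperparameters act as prior counts, so a related
dataset can inform the discretization of another by supplying non-uniform α;
the package accepts a scalar or a per-class vector but provides no
elicitation workflow.

**Defaults.** λ = 0.5 (most expression predictors warrant zero or one cut;
0.5 is the mean of those two) and α = 1 (uniform prior over each interval's
class distribution). Both are exposed on `EBDParams` and every CLI
subcommand.

## Exact search by dynamic programming

Both score factors decompose over intervals, so with V[a] the best log
score of a discretization of the first a distinct values (V[0] = 0),

    V[a] = max_{1≤b≤a} V[b−1] + log prior(b,a) + log marglik(counts of b..a),

and back-pointers recover the global optimum of V[n']. One prefix-optimal
discretization is stored per prefix — n' in total — against a search space
of 2^(n'−1). The implementation evaluates each row of candidates (all b for
fixed a) as vectorized array operations over prefix-sum count matrices and
cumulative gap-prior sums, preserving the O(J·n'²) cell count (asserted via
an operation counter, not wall clock) while keeping the constant small.
Log-gamma is used throughout; log-factorials are exact in this form and the
tests confirm agreement with rational factorial arithmetic to 1e−9 relative
for intervals up to 30 instances.

Numerical choices:

* **Ties.** Composite log scores within 1e−12 are treated as tied;
  preference goes to fewer intervals, then to the candidate whose final
  interval is longer. The brute-force oracle applies the same rule
  (comparing cut tuples from the right), so optimum identity — not just the
  score — is comparable.
* **Duplicates.** Equal predictor values are merged before search with
  summed class counts; cuts are only considered between distinct values.
* **Degenerate inputs.** n' = 1 yields the trivial single-interval model;
  a constant target collapses to one interval for λ ≤ ln 2 because merging
  then dominates both factors.
* **Cut placement.** Cut values are the midpoints of the flanking distinct
  values, stored at full precision and serialized exactly (JSON float
  round-trip).

A value equal to a cut belongs to the upper interval, and values outside
the training range clamp to the terminal intervals — the only convention
that can never fail when train-fold models are applied to test folds.

## The entropy/MDL baseline

The Fayyad–Irani discretizer greedily picks the cut minimizing the
instance-weighted entropy of the two resulting sub-intervals, accepts it if
the information gain exceeds the MDLPC threshold

    Gain > [log2(N−1) + Δ]/N,
    Δ = log2(3^k − 2) − (k·Ent(S) − k_l·Ent(S_l) − k_r·Ent(S_r)),

(k, k_l, k_r = classes present; N = instances in the segment), and recurses
into both halves. Ties among equal-entropy cuts go to the leftmost
candidate. Restricting candidates to class-boundary gaps is available as an
optimization flag and is asserted equivalent on randomized inputs. The
Bayesian log score is not defined for these models; they carry
`log_score = None`.

## Classifier

A discrete naive Bayes classifier scores discretizations end to end:
predictors are interval codes, assumed conditionally independent given the
class, with add-one smoothing on the class prior and every conditional
table. Variables discretized to a single interval are dropped at training
time — discretization acting as variable selection. The cross-validation
harness accepts any object honouring the train / predict-distribution
contract, so an external learner can be plugged in; only naive Bayes ships
with the package.

## Evaluation harness

Seeded stratified F-fold cross-validation repeated R times (defaults
F = R = 10, hence 100 train/test pairs; replicate r shuffles with seed + r).
Per pair, every variable is discretized on the training fold only — the
tests assert that perturbing test-fold values never changes the learned
cuts — and the classifier is trained on the coded training fold. Measures:

* **Accuracy**: fraction of maximum-posterior predictions that are correct;
  posterior ties break toward the lowest class index.
* **AUC**: Mann–Whitney rank form for two classes (ties count ½); for J > 2
  the pairwise-average extension: for each unordered class pair the two
  one-vs-one AUCs are averaged, then averaged over the J(J−1)/2 pairs.
  Reduces exactly to the binary form at J = 2.
* **Robustness**: 100 · test accuracy / training accuracy, computed per
  train/test pair and averaged — an overfitting indicator that can exceed
  100.
* **Stability**: per replicate, the mean over all F(F−1)/2 fold pairs (45
  for F = 10) of the chance-corrected similarity of the selected
  (non-trivially discretized) variable sets,

      Sim(v_i, v_j) = (r − k_i·k_j/n) / (min(k_i,k_j) − max(0, k_i+k_j−n)),

  where r is the overlap, k_i·k_j/n its hypergeometric expectation, and the
  denominator the gap between the largest and smallest overlap the set
  sizes permit — which bounds the index in [−1, 1]. Whenever the index is
  undefined (an empty set, or set sizes that force the overlap, including
  both sets containing every variable) it is taken as 0; in every such case
  the numerator is also 0, so the convention is continuous. Replicate
  stabilities are averaged for the overall value.
* **Interval statistics**: fraction of variables with one interval, mean
  interval count among multi-interval variables (missing when there are
  none), and the overall mean.

Methods are compared per-fold with the paired Wilcoxon signed-rank test:
zero differences discarded, mid-ranks for tied magnitudes, Z from the
normal approximation with tie-corrected variance, two-sided p. The tests
cross-check it against an independent library implementation and against
exhaustive sign-pattern enumeration at small n; the normal approximation is
what makes a Z statistic reportable, at the cost of mild inaccuracy below
about ten non-zero differences (≈0.028 vs the exact 0.031 on six unanimous
differences).

## Synthetic data

The generator emulates the *shape* of high-dimensional expression matrices:
a minority of informative variables whose interval membership predicts the
class at a chosen purity, plus class-independent uniform noise variables.
For an informative variable the class is drawn first, then an interval from
that class's interval distribution, then a value uniformly within the
interval shrunk by a margin on each side touching a true cut — so "the
recovered cut lies in the gap containing the true cut" is a crisp
predicate. All randomness flows from one seed through spawned per-variable
streams, making individual columns independently reproducible. What it does
*not* emulate: correlated co-expression blocks, heavy-tailed or platform-
specific intensity distributions, batch effects, or missingness — so
passing recovery tests demonstrate correctness of the machinery, not
performance claims about real assays. The bundled six-instance example
(`toy_sample`) is the worked fixture used across docs and tests.

Default study conditions used by the recovery checks: two balanced classes,
one true cut at 0.5 in a unit range, margin 0.05, purity 0.95, n = 200,
100 seeded replicates; the noise-only filtering check uses 10 variables,
n = 100, 20 seeds. Test-suite cross-validation examples run at n = 60–120
with up to 10 variables so the full suite stays interactive; the harness
itself has no size assumptions beyond "at least F instances per class".

## Known limitations

* Univariate only: each predictor is discretized independently; interacting
  predictors whose joint distribution carries the signal are out of scope.
* The quadratic exact search is practical to n' of a few thousand; no
  sub-quadratic heuristic variant is provided.
* Unseen target levels at apply time are an error; class identity is fixed
  by the training data.
* The stability index form was chosen for its provable [−1, 1] range; the
  alternative normalization that makes identical sets score exactly 1
  regardless of size violates that range, and the two desiderata cannot be
  met simultaneously (identical sets of k of n variables here score
  (k − k²/n)/k = 1 − k/n < 1).
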