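# bayesdisc

Supervised discretization of continuous predictors for biomedical
classification, built around an exact Bayesian method with a dynamic-
programming search, plus the classic recursive entropy/MDL discretizer as a
baseline and a full cross-validated evaluation harness.

## Who this is for

High-throughput transcriptomic and proteomic studies produce matrices with
thousands of continuous predictors (gene or protein expression) and few
instances, labelled with a categorical phenotype. Many learners — rule
inducers, discrete Bayesian networks, discrete naive Bayes — need those
predictors binned into intervals first, and the binning doubles as variable
selection: a predictor collapsed to a single interval carries no information
about the phenotype and is dropped. `bayesdisc` learns those interval
boundaries from data, one predictor at a time.

## The model

For a predictor X sorted to n' distinct values with per-value class counts
over J phenotype classes, a discretization M = (W, T) with W intervals is
scored by

    P(M, D) = P(M) · P(D | M)

* **Structure prior P(M).** Cut points follow a Poisson process over the
  observed value range with total mean λ (default 0.5, i.e. "expect zero or
  one cut"), allocated to each gap between consecutive distinct values in
  proportion to its width: the probability of a cut in gap k is
  `1 − exp(−λ·d(k,k+1)/d(1,n'))`. Wide empty gaps are therefore the
  preferred places to cut.
* **Marginal likelihood P(D | M).** Within each interval the class labels
  are multinomial with a Dirichlet prior (hyperparameters α, default all 1);
  integrating the parameters out gives the closed form
  `Γ(α_i)/Γ(α_i+n_i) · Π_j Γ(α_ij+n_ij)/Γ(α_ij)` per interval, which for
  α = 1 is the factorial ratio `(J−1)!/(n_i+J−1)! · Π_j n_ij!`.

Both factors decompose over intervals, so the global maximum over all
2^(n'−1) discretizations is found exactly by dynamic programming over
prefixes in O(J·n'²) time, entirely in log space. A brute-force enumerator
doubles as an independent oracle for the optimality guarantee in the tests.

The package also provides: the Fayyad–Irani recursive entropy-minimization
baseline with the MDLPC stopping rule; a discrete naive Bayes classifier
with add-one smoothing; the five evaluation measures (accuracy, Hand–Till
multi-class AUC, robustness, selected-variable stability, interval-count
statistics) under seeded stratified R×F cross-validation with a paired
Wilcoxon signed-rank comparison; and seeded synthetic-data generators with
known ground-truth cut structure.

## Worked example

The six-instance example used throughout the docs: expression values
(1.2, 1.4, 1.6) are healthy (class 0) and (3.7, 3.9, 4.1) diseased
(class 1).

```python
from bayesdisc import EBDParams, ebd_discretize, fi_discretize, toy_sample

sample = toy_sample()
model, state = ebd_discretize(sample, EBDParams(lam=0.5, alpha=1.0), return_state=True)
print(f"intervals:        {model.W}")
print(f"cut points:       {[round(c, 6) for c in model.cut_values]}")
print(f"interval counts:  {model.interval_counts.tolist()}")
print(f"log score:        {model.log_score:.6f}")
print(f"prefix optima:    {state.n_prefix_optima}")
baseline = fi_discretize(sample)
print(f"entropy/MDL cuts: {[round(c, 6) for c in baseline.cut_values]}")
```

prints

```
intervals:        2
cut points:       [2.65]
interval counts:  [[3, 0], [0, 3]]
log score:        -4.102019
prefix optima:    6
entropy/MDL cuts: [2.65]
```

The optimal discretization cuts once, at the midpoint 2.65 of the wide gap
between 1.6 and 3.7, splitting the data into a pure class-0 and a pure
class-1 interval — splitting raises the marginal likelihood by a factor
8.75, which outweighs the prior cost of one cut. Although 2^5 = 32
discretizations exist, the dynamic program only materializes 6
prefix-optimal ones. The entropy/MDL baseline agrees on this example.

A cross-validated method comparison on synthetic data with one informative
variable (90% interval purity) among 8 noise variables:

```python
from bayesdisc import generate_dataset, run_cv, two_class_one_cut

frame, truth = generate_dataset(two_class_one_cut(n=120, purity=0.9, n_noise=8), seed=7)
X, y = frame.drop(columns="target"), frame["target"].to_numpy()
for method in ("ebd", "fi"):
    print(method, run_cv((X, y), method=method, seed=0).summary())
```

reports (rounded) test accuracy 0.917 vs 0.912, test AUC 0.921 vs 0.916,
robustness 100.1% vs 99.5%, stability 0.887 vs 0.889, and mean intervals
per predictor 1.112 vs 1.111 for the Bayesian and entropy/MDL methods
respectively — both reliably keep the informative variable and discard most
noise variables.

The same workflows are available from the shell:

```sh
bayesdisc simulate   --spec spec.yaml --seed 5 --output data.csv --truth-output truth.json
bayesdisc discretize --input data.csv --target target --method ebd --output-model models.json
bayesdisc transform  --input data.csv --model models.json --output coded.csv
bayesdisc evaluate   --input data.csv --target target --methods ebd,fi --seed 1
```

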