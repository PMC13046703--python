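# Methods

## The problem and the data model

The package addresses origin verification of flue-cured tobacco from a
70-component chemical profile. The study design it reproduces covers 13
origin classes — nine Chinese provinces (Yunnan 360, Sichuan 103, Guizhou
157, Chongqing 92, Henan 206, Hunan 103, Fujian 124, Shandong 24,
Heilongjiang 100 samples) and four countries (United States 64, Brazil 129,
Zimbabwe 154, Zambia 101) — 1,717 samples in total. The per-sample table is
not publicly available; what is published are, per country, the mean ± SD of
every component, the per-origin sample counts, and a handful of individual
province means. Those statistics are shipped as CSV fixtures
(`src/chemorigin/data/`) and are the sole empirical anchor of the package.

### Synthetic tables

`generate_dataset` draws each sample of origin r componentwise from

    Normal(country_mean + separation_scale · region_offset, country_sd)

Assumptions and choices:

* **Independent marginals.** Only marginal means and SDs were published, so
  no covariance structure is invented; components are drawn independently. A
  `correlation` hook accepts a user-supplied component correlation matrix
  (applied via its Cholesky factor) for sensitivity studies; the default is
  identity. Real chemical tables are strongly correlated (e.g. total sugar
  vs reducing sugar), so synthetic classification difficulty is not an
  estimate of real difficulty — see Limitations.
* **Region offsets.** For the nine Chinese provinces, only twelve province
  means were published individually (total alkaloids, reducing sugar, total
  sugar, total nitrogen for Hunan/Heilongjiang/Sichuan; Fru-Asn for
  Henan/Hunan; succinic acid for Heilongjiang; rutin for Sichuan). The
  default offsets are `published province mean − country mean` for exactly
  those (region, component) pairs and zero elsewhere. `separation_scale`
  (default 1 = published offsets as-is) multiplies all offsets and is the one
  free knob controlling 13-class difficulty; within-China separation is
  otherwise sampling noise only, which is why scaled-down demonstration runs
  sit far below the published 97.96 % test accuracy.
* **Truncation.** Negative draws are truncated to 0 (concentrations cannot
  be negative) rather than re-sampled, keeping the draw count — and hence
  reproducibility under one seed — independent of parameter values. pH is
  clamped to (0, 14). For a component with mean ≥ 2 SD the induced mean
  inflation is bounded by 0.5 SD (Gaussian truncation bound, checked
  empirically in the tests); the few components with mean < 2 SD (e.g.
  chlorine in China, 0.48 ± 0.39 %) acquire a small positive bias, accepted
  as the price of simplicity.
* **Noise features.** Optional standard-normal columns, drawn independently
  of labels, appended after the 70 real components; used to verify that the
  importance machinery assigns them ≈ 0.

## Screening statistics

* **One-way ANOVA** is the classical fixed-effects decomposition
  F = MSB/MSW with p from the F(k−1, N−k) distribution. If the pooled
  within-group variance is exactly 0 with unequal means the result is
  reported as F = ∞, p = 0 and flagged `degenerate`.
* **Tukey HSD** uses the studentized-range criterion with Tukey–Kramer
  standard errors, required because group sizes span 24–1269:
  pair (i, j) differs when |ȳᵢ − ȳⱼ| / √(MSW/2 · (1/nᵢ + 1/nⱼ)) exceeds the
  upper-α studentized-range quantile q(α; k, N−k). The quantile is computed
  once per (k, df) and cached; the decision rule is identical to the p-value
  formulation (cross-checked against `scipy.stats.tukey_hsd` in the tests)
  but ~100× cheaper over 70 components.
* **Compact letter display** uses insert-and-absorb: start from one set
  containing all groups; for each significant pair split every set containing
  both endpoints into two copies (each lacking one endpoint); absorb subsets;
  assign letters a, b, … ordered by earliest member. The output satisfies
  exactly: two groups share a letter iff they are not significantly
  different (verified exhaustively for every relation on ≤ 6 groups).
* **Significance categories** use right-closed bins: ns (p > 0.05),
  \* (0.01 < p ≤ 0.05), \*\* (0.001 < p ≤ 0.01), \*\*\* (p ≤ 0.001). The
  conventional footnote phrasing is inconsistent at the boundaries; the
  right-closed reading matches the one explicit "≤" in the source convention.
* No multiplicity correction is applied across the 70 components,
  mirroring the original analysis; the per-component table is descriptive.

## Clustering

Origins are compared through per-origin mean profiles (13 × 70). Distance is
1 − Pearson r across components, computed on raw (unstandardized) profiles:
correlation distance is already invariant to affine rescaling of a whole
profile, and the published description standardizes nothing. Because the
units are heterogeneous (%, mg/g, μg/g) the correlation is dominated by the
large-magnitude components (proline, Fru-Pro, Fru-Asn…); an optional
per-component z-scoring of the profile matrix can be applied by the caller
before `pearson_distance` if a unit-free view is wanted. Linkage is
average (UPGMA) by default — the customary choice for correlation distances
— configurable to single or complete; Ward is excluded because it is not
meaningful on a non-Euclidean precomputed distance. Merge ties follow
SciPy's deterministic chaining. Newick export places a node merged at height
h at depth h/2 (ultrametric), so two leaves merged at h get branches of h/2.

## Kernels and classifiers

The five kernel families are linear x₁·x₂′, polynomial (c₁·x₁·x₂′ + c₂)^c₃,
Gaussian exp(−‖x₁−x₂‖²/σ²) (σ² divides the squared distance directly — no
factor 2), sigmoid tanh(a·x₁·x₂′ + c), and the hybrid convex combination
m·linear + n·polynomial + q·Gaussian with m + n + q = 1. The sigmoid is
excluded from the hybrid because it is not positive semi-definite in
general (a `check_psd` guard reports the smallest Gram eigenvalue); the
hybrid of three Mercer kernels with non-negative weights is Mercer. The
polynomial exponent c₃ may be non-integer in [2, 4]; the base is floored at
0 before exponentiation to keep the kernel real.

`KernelSVC` standardizes features on the training split (default on: the
components span four orders of magnitude and the Gaussian width range
σ² ∈ [10, 50] is only meaningful on a z-scored scale), builds the Gram
matrix and solves the soft-margin problem per binary subproblem via libsvm
(`SVC(kernel='precomputed')`). Defaults where the source description is
silent, all echoed in the pipeline manifest: C = 1.0; multiclass = one-vs-one
pairwise voting (the classical kernel-SVM default), with one-vs-rest
available. The MLP baseline enforces the tuning ranges (1–5 hidden layers,
2–40 neurons/layer, learning rate 0.001–0.1) and uses rectified-linear
activations, Adam, early stopping on a 10 % carve-out, ≤ 500 epochs, seeded.
The random forest enforces 50–200 trees and 2–10 minimum samples per leaf.
No class weighting is applied despite the 24-vs-360 imbalance, matching the
original models.

## Particle swarm optimization

Velocities update as v ← w·v + 1.5·r₁⊙(pbest − x) + 1.5·r₂⊙(gbest − x) with
w decayed linearly 0.9 → 0.4 across iterations and r₁, r₂ ~ U[0,1] per
dimension. Positions are clamped to the box, velocities to half the box
width (standard stabilization), integer dimensions rounded, and the hybrid
(m, n, q) group renormalized to sum exactly 1 (re-seeded uniformly if the
sum collapses below 1e-6) — particles fly in the three raw coordinates, the
simplest projection that respects the per-coordinate [0, 1] boxes. Fitness
is the mean stratified 5-fold CV accuracy on the training split; folds are
drawn once per `optimize` call so fitness values are comparable across the
whole run (re-randomizing folds per call would add noise to the gbest
bookkeeping). Swarm budget is unstated in the source description: defaults
are 30 particles × 50 iterations; demonstration and test runs use 10 × 10 on
~300-sample tables. Early stopping on a fitness threshold is available but
off by default — no threshold is invented. The gbest trace is monotone
non-decreasing by construction and asserted in the tests.

## Evaluation

The 80/20 split allocates round-half-up(n_c · 0.2) test samples per class,
then spreads the residue against the global target one sample per class over
the largest classes, keeping every class within one sample of its exact
share (24-sample Shandong contributes 5). Macro-recall and macro-precision
are arithmetic means of per-class recall/precision; macro-F1 is the harmonic
mean of those two macros — not the mean of per-class F1, a distinction that
matters at the fourth decimal. Per-class quantities with zero denominators
(reachable for 5-sample test classes) are defined as 0 with a logged
warning. Multiclass AUC is the arithmetic mean over classes of the
one-vs-rest rank-sum (Mann–Whitney) AUC of that class's score column, with
midrank tie handling; the multiclass AUC definition is not stated in the
source description and macro-OvR was chosen to match its macro-averaging
style elsewhere.

## Permutation importance

Loss = 1 − macro-OvR AUC on an evaluation table. For each component and each
of `repeats` (default 10) rounds, the component's column is shuffled within
the evaluation set and the loss recomputed; importance is the mean Δloss,
reported with its SD, ranked descending with name tie-breaks. The model is
never refit — the statistic measures what the fitted model relies on.
Importance is computed on the held-out test split (avoiding training-set
optimism); computing it on the training split or CV folds is possible by
passing a different table.

## Problem sizes and numerical choices

Default study conditions are the published design (1,717 samples, 70
components, published counts). The test suite and demonstration runs scale
the swarm to 10 × 10 and tables to 20–40 samples per origin so the whole
suite completes in a few minutes on one CPU; these sizes are recorded in
each run's manifest. Numerical tolerances: hybrid-Gram decomposition and
Gram symmetry at 1e-12; simplex sum at 1e-9; PSD tolerance 1e-8 on the
smallest eigenvalue; ANOVA F against the independent oracle at 1e-10
relative. CSV round-trips use `float_precision="round_trip"` so written
tables re-read bit-identically.

## Limitations

* Independent-marginal synthesis cannot reproduce the correlation structure
  of real chemical tables; classification accuracies on synthetic data are
  not estimates of the published accuracies, and the pipeline's Table-style
  outputs should be read as functional demonstrations, not replications.
* Within-China class separation rests on twelve published province means;
  the remaining 618 province × component cells inherit country-level
  marginals, making the synthetic 13-class problem hardest exactly where the
  real data were presumably most informative.
* Whether the original SVM standardized inputs, its C value, its multiclass
  decomposition, the PSO budget, and the PFI data split are all unstated;
  each gap is filled with a documented, configurable default.
* The dendrogram's exact topology depends on the unstated linkage and
  scaling choices; only coarse structure (domestic vs international blocks,
  Yunnan–Sichuan affinity) is expected to be stable.
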