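# Methods

`metabobench` regenerates a simulation-based comparison of seven
classifier families for multiclass phenotype discrimination from
untargeted metabolomics abundance tables. This note records the models
implemented, the defaults chosen where the study design left them open,
the numerical conventions, and what the synthetic data does and does not
emulate.

## Simulated metabolomics data

### Block-correlated abundances

An abundance matrix X (n samples x p metabolites) is generated in K = 40
independent blocks of d = 25 metabolites (p = 1000), each block standing
for one biological process. Block k is drawn multivariate normal,
X_k ~ N(mu_k, Sigma_k), where Sigma_k is a random correlation matrix from
the C-vine construction of Lewandowski, Kurowicka and Joe: partial
correlations rho_{k,i;1..k-1} are drawn layer by layer from a stretched
Beta(beta, beta) on (-1, 1), with beta starting at eta + (d-1)/2 and
decreasing by 1/2 per layer, then inverted to a full correlation matrix
through the partial-correlation recursion. Every matrix so built is
positive definite; at eta = 1 (the default; the original design does not
state eta) the distribution is uniform over valid correlation matrices,
and larger eta shrinks correlations toward zero. A numerical guard
symmetrizes the result and clips eigenvalues below 1e-10 if floating
point leaves the matrix marginally indefinite; matrices with smallest
eigenvalue below -1e-10 raise an internal error (never observed over
10^4 sampled matrices in the test suite).

### Phenotype effects

Three phenotypes are simulated. The reference phenotype has mu_k = 0 for
every block. Each comparator phenotype perturbs a DiscreteUnif(1, 5)
number of randomly chosen blocks; a perturbed block's effect magnitude is
theta_k ~ Exp(rate 1/2) (mean 2, abundance units), its sign flipped with
probability 1/2, and the per-metabolite means inside the block are
N(theta_k, 1). Columns outside perturbed blocks are therefore exactly
null — the ground truth the significance filter is checked against.

### Realistic-scenario artifacts

The realistic scenario layers four artifacts on the baseline, in this
order:

1. **Biological outliers** — per (sample, block) with probability
   p_b = 0.02, the sample's whole block is shifted by +/-4 column SDs.
2. **Technical outliers** — per (sample, metabolite) with probability
   p_t = 0.01, a +/-6 SD single-entry shift.
3. **Non-normal marginals** — per block one shape kappa ~ Unif(-0.4, 0.4)
   is drawn and every metabolite is pushed through the quantile function
   of the zero-location generalized Gaussian distribution (GGD),
   x(u) = (alpha/kappa)(1 - exp(-kappa z(u))) with z the standard-normal
   quantile and scale alpha = 1; kappa = 0 recovers the normal. Ranks are
   taken from the empirical CDF rescaled as rank/(n+1) so u stays inside
   (0, 1). The map is monotone, so within-block rank correlations are
   preserved exactly.
4. **Limit-of-detection missingness** — per metabolite the LOD is the
   pooled 5% quantile and every value strictly below it becomes missing.
   The mechanism is MNAR: missingness is determined by the unobserved
   value itself.

Class sizes in the realistic scenario are Dirichlet(4, 4, 4)-multinomial,
redrawn until each class has at least 10 samples; the baseline scenario
uses balanced classes. The outlier rates, GGD parameter ranges and LOD
quantile are package defaults chosen to produce visibly skewed,
finite-variance marginals and a modest (5%) missing fraction; all are
configurable through `SimulationConfig`.

### Sample size

The original design never states the per-study sample size or split. The
package defaults to N = 120 per study, split 60 train / 60 test: the
granularity of reported misclassification medians (1.7% = 1/60,
8.3% = 5/60, 41.7% = 25/60) implies test sets of 60. This inference is
flagged here deliberately; N is configurable.

### Missing-value handling

Half-minimum imputation is applied identically before every classifier:
a missing entry becomes the column's observed minimum shifted down by
half its magnitude (= half the minimum for positive minima, the standard
below-LOD estimate; the general form keeps the fill below the minimum
for the signed abundances the location-zero GGD produces). Columns with
no observed values are dropped and reported.

## Classifiers

All seven families share one contract:
`fit_predict(X_train, y_train, X_new, seed, **params)` returning a
row-stochastic class-probability matrix.

* **PLS-DA** (from scratch): NIPALS extraction of weight vectors
  maximizing [Cov(Xw, Yc)]^2 against the centered class-indicator
  matrix, convergence at a 1e-8 change in w (max 500 iterations),
  loadings by OLS on the scores, rank-one deflation of X and Y between
  components. Columns are centered and unit-scaled; constant columns
  dropped; the sign of each weight vector fixed so its largest-magnitude
  entry is positive. Classification is nearest centroids in score space;
  probabilities are the softmax of negative squared distances to the
  class centroids.
* **sPLS-DA** (from scratch): per deflation, the weight is the leading
  left singular vector of X_h^T Y_h soft-thresholded entrywise at
  lambda times its largest absolute entry and renormalized, making the
  0.1-0.9 grid scale-free; lambda = 0 reproduces PLS-DA exactly (tested
  to 1e-8).
* **SVM** (delegated to scikit-learn SVC): Gaussian kernel
  K(x,x') = exp(-gamma ||x-x'||^2), one-against-one multiclass with
  pairwise-coupled Platt probabilities, inputs standardized on training
  statistics. Cost c is fixed at 1.0 (only the bandwidth was ever tuned).
* **Random Forest** (delegated to scikit-learn): 1000 fully grown trees,
  bootstrap resampling, random subspace of `mtry` metabolites per split.
  Probabilities are tree-vote fractions (pure leaves make averaged leaf
  distributions identical to votes). Split impurity is Gini rather than
  misclassification error — a documented deviation accepted to avoid
  reimplementing tree induction; the difference is empirically minor.
* **Neural network** (in-house): feedforward net with 1 or 2 logistic
  hidden layers, softmax output, cross-entropy error, trained full-batch
  by iRPROP- (resilient backpropagation: per-weight step sizes adapted
  from gradient signs, steps in [1e-8, 5], eta+ = 1.2, eta- = 0.5, at
  most 300 epochs, early stop on loss stagnation). Inputs standardized,
  targets one-hot. On divergence, training restarts up to three times,
  then uniform probabilities are returned with a warning. No
  pre-installed package provides RPROP training, hence the numpy
  implementation.
* **Naive Bayes** (from scratch): Gaussian class-conditionals with MLE
  means/variances, log-space accumulation, empirical-frequency priors,
  variances floored at 1e-9 times the pooled variance so within-class
  constant metabolites cannot degenerate the density.
* **k-NN** (from scratch): posteriors are class fractions among the k
  Euclidean-nearest training rows; distance ties resolve toward the
  lowest training index for determinism. Zero probabilities are left as
  zero — flooring is the evaluation module's job.

## Significance filtering

A metabolite is kept when any of its G(G-1)/2 pairwise two-sample tests
is significant at raw alpha = 0.025 (no multiplicity correction, by
design): Welch t-tests in the baseline scenario, Wilcoxon rank-sum in
the realistic one. The any-pair rule is deliberate — a metabolite
separating one phenotype pair is informative for multiclass
discrimination. Constant metabolites get p = 1. If nothing clears alpha,
the ten smallest-p metabolites are kept (with a warning) so downstream
fits remain possible. The filter is always fit on training samples only.

## Parameter tuning

Parameters are selected by minimizing expected cross-entropy estimated
by stratified 5-fold cross-validation (fold count unstated in the
original design; 5 is standard for ~60 training samples) over the
published grids: components 1-15 (both PLS variants), lambda 0.1-0.9 by
0.1, SVM bandwidth 1000 log-spaced points in 10^[-5,-1] before filtering
and 10^[-2,0] after, mtry at 25 points spanning [5, p], k = 1-20, and
networks over {1, 2} layers x {15..100 by 5} nodes (two-layer
configurations use equal nodes per layer; the published table lists
axes, not a product rule). The raw loss surface is smoothed by
Nadaraya-Watson regression with a Gaussian kernel per numeric axis
(log10 scale for bandwidth and lambda), bandwidth 1.5x the grid spacing
— declared defaults, since the original smoothing kernel is unspecified.
The smoothed argmin is selected; exact ties resolve to the smallest
parameter values. Smoothing is a convex combination, so smoothed losses
never leave the raw range, and the selection always lies on the grid.

"Coarse" mode subsamples any grid to at most a requested number of
evenly spaced candidates (25 by default from the CLI) to make
desk-scale runs feasible; full grids remain the default.

## Loss functions and protocols

Misclassification rate is the mean 0-1 loss of argmax predictions (ties
to the lowest class index). Cross-entropy is the mean negative natural
log of the floored true-class probability; the floor defaults to 1e-15,
capping a single sample's contribution at about 34.5 nats. Cross-entropy
magnitudes for k-NN and Naive Bayes — which emit exact zeros — are
therefore floor-dependent: with a smaller floor their losses grow
without bound while every other comparison is unchanged. Comparisons
involving those two families should be read ordinally.

Each simulation study splits 60/60 (stratified); tuning happens inside
the training half, losses are computed once on the test half, separately
for the pre-filter and post-filter arms. For real datasets too small to
split, repeated double cross-validation is provided: tuning in inner
folds, error pooled over stratified outer folds, averaged over repeats
(defaults 5 x 5 x 10); filtering, imputation and tuning are refit inside
each outer training part.

Aggregates over studies report mean, SD, median and IQR (Q3 - Q1,
linear-interpolation quantiles) per technique x scenario x filter state,
misclassification on the 0-100% scale; failed cells are excluded
pairwise with counts reported. Pairwise win matrices count the
proportion of studies where one technique's loss is strictly smaller,
ties contributing 0.5 to each side.

## Reproducibility and scale

Every sampling operation takes an explicit `numpy.random.Generator`; a
study is bit-reproducible from its (config, seed) pair, and study b of a
batch uses the b-th spawn of the master `SeedSequence`, so results are
independent of execution order and worker count. The full design (1000
studies per scenario, both filter arms, full grids) is hours of CPU; the
shipped acceptance run uses the realistic scenario's post-filter arm
with grids subsampled to 8 points, 3-fold tuning CV and a small number
of studies — sizes chosen as the package's own desk-scale defaults. The
pre-filter arm is the expensive one (random-subspace search up to
p = 1000 with 1000-tree forests) and is exercised at miniature problem
sizes in the test suite.

## Known limitations

* Simulated blocks are mutually independent; real metabolic processes
  share hubs and cofactors, so cross-block correlation is understated.
* Abundances are location-zero and signed rather than positive
  intensities; rank-based methods are unaffected, and half-minimum
  imputation is generalized accordingly.
* The GGD transform is applied block-wise with a single (kappa, alpha),
  so within a block all marginals share one skew shape.
* Gini impurity stands in for misclassification impurity in the forest.
* Passing benchmarks on these simulations demonstrates correct
  machinery and relative behavior under the stated generative
  assumptions, not classifier performance on any particular platform's
  real data.
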