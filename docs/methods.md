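# Methods

`fedsim` simulates horizontally federated training under a star topology and
compares it with a centralized baseline trained on the pooled data under a
deliberately matched protocol. Everything runs in one process on synthetic
data; the point of the simulation is the *difference* between the two arms,
not absolute performance.

## The federated round and its centralized mirror

One communication round r:

1. the server broadcasts the global parameters W_g;
2. each client i evaluates W_g on its local test shard (acc_i,r);
3. each client runs one local epoch of gradient descent on its training
   shard (X_i, y_i) and returns the updated parameters W_i;
4. the server aggregates and evaluates the new W_g on the concatenation of
   all client test shards.

The centralized arm runs the identical local step on the pooled training
data, one epoch per round, from the same parameter initialization (same
seed), evaluated on the same pooled test set. Rounds and epochs are therefore
in one-to-one correspondence and the two accuracy curves are directly
comparable point by point. All clients participate every round; there is no
client sampling, asynchrony, compression, or privacy mechanism (out of
scope by design).

**Aggregators.**

* *fedAVG*: W_g ← (1/S) Σ_i s_i W_i with s_i the client's training-set size
  and S = Σ s_i. A convex combination, so every coordinate of W_g lies
  within the componentwise min/max over clients.
* *SCAFFOLD*: drift correction through control variates c_i (per client) and
  c_g (global), all zero-initialized. The default local update is

      W_i = W_g − η_l ∇L(X_i, y_i) + (c_g − c_i)
      c_i' = c_i − c_g + (1/η_l)(W_g − W_i)

  and the global update is the *unweighted* mean of deltas,
  W_g ← W_g + (η_g/N) Σ (W_i − W_g), c_g ← c_g + (1/N) Σ (c_i' − c_i).
  The identity c_g = mean_i(c_i) holds at every round from zero
  initialization.

  Note the correction (c_g − c_i) enters the default ("additive") W update
  un-scaled by the learning rate, while the variate update divides by η_l.
  A consequence worth knowing: whenever client gradients disagree
  persistently, the variates grow geometrically at rate ≈ (1 + 1/η_l). The
  mean identity above still holds exactly in real arithmetic, but numerical
  checks must be made relative to the variates' magnitude, and long
  non-IID runs at small η_l will overflow. `scaffold_variant="scaled"`
  selects the alternative form W_i = W_g − η_l(∇L + c_g − c_i), in which the
  variate recursion is stable; the additive form remains the default because
  it is the protocol this framework is defined to study. η_g defaults to
  1.0.

**Losses and reduction.** Linear models use softmax cross-entropy
("logistic") or one-vs-rest hinge; the small networks use softmax
cross-entropy. Reduction over samples is **sum** by default for linear
models: a full-batch sum-loss gradient over pooled data is exactly the sum
of per-client gradients, which is what produces the learning-rate /
client-count relationship below. Mean reduction is selectable; it replaces
that relationship with a different exact identity (with equal client sizes
and full-batch steps, federated and centralized coincide at the *same*
learning rate, since the pooled mean gradient is the mean of client mean
gradients).

**The factor-N relationship.** For a full-batch sum-loss linear model over N
equal-size clients, one federated round at learning rate η takes the step
−(η/N) Σ_i ∇L_i = −(η/N) ∇L_pooled, identical to one centralized epoch at
η/N. The harness's learning-rate sweep recovers this: for each federated
rate it picks the centralized rate (from a fixed grid) minimizing the mean
absolute difference between per-round global accuracy curves, averaged over
seeds; ties go to the smaller rate. With 10 equal IID clients the selected
ratio is 10 and the parameter trajectories agree to ≤1e−9 per round.

**Metrics.** Each run is summarized by its final accuracy and the normalized
trapezoidal area under the accuracy-versus-round curve (a constant curve at
a maps to AUC = a, so the value is on the accuracy scale and bounded by the
curve's extremes). Update divergence is the per-round Euclidean distance
‖W_i − W_g‖ between each client's returned model and the aggregated global
model — the numeric content of a client-drift heatmap.

## Models

All classifiers share one contract: a flat parameter vector plus an
architecture that computes class scores and backpropagates a score-space
gradient analytically (verified against central differences at 1e−5).

* linear (d·C + C parameters) — multinomial logistic regression or
  one-vs-rest linear SVM depending on the loss;
* MLP — two linear layers with one ReLU between them; hidden width 64 by
  default (32 in the batch-effect experiment to keep it light);
* CNN — one 1-D convolution along the feature axis (8 filters, kernel 3),
  ReLU, global average pooling, dense output. It exists as a deeper
  nonconvex model for tabular inputs, not as an image architecture.

Initialization: He-scaled Gaussian weights (scale 0.01 for linear), zero
biases, fully determined by an integer seed. Mini-batch mode shuffles once
per epoch and takes one step per shard; the protocol default is a single
full-batch step per round.

## Sequential federated gradient boosting

Trees cannot be averaged, so the GBDT federates sequentially: in round r
only client r mod N is active. It computes the pseudo-residuals y − p of
the binomial deviance (one-hot minus softmax probabilities for C > 2) under
the current ensemble *on its own data*, fits one depth-3 regression tree per
score dimension to them (`sklearn.tree.DecisionTreeRegressor`, squared-error
criterion), re-fits each leaf with the one-step Newton estimate
Σr / Σp(1−p) (times (C−1)/C for multiclass), and appends the tree with
shrinkage ν = 0.1. The initial raw score is the log-odds prior of the first
active client's labels. Probabilities are clipped at 1e−12.

With a single client this is ordinary gradient boosting: staged raw scores
match `sklearn.ensemble.GradientBoostingClassifier` with the same tree
parameters to machine precision, which is the reference oracle in the tests.
The Newton leaf re-fit is what makes that equivalence exact. Because each
tree reflects one client's class mix, disjoint-class partitions are the
protocol's known failure mode: trees grown without some classes produce
residual structure that misleads subsequent clients, and accuracy degrades
where parameter averaging would be unaffected (reproduced in the acceptance
suite: four-class data, two classes per client, final accuracy drops by
>0.1 versus IID while federated linear models are unchanged).

## Federated PCA and local z-normalization

High-dimensional inputs are reduced to k principal components before
classification. Each client shares only sufficient statistics — sample
count, per-feature sum, and d×d scatter — from which the server assembles
the pooled covariance exactly (population 1/n convention) and
eigendecomposes it. This moment-pooling construction *equals* centralized
PCA on the pooled matrix (principal angles ≤1e−6 in the tests for
well-separated eigenvalues); exactness is the module's contract, and the API
leaves room for an iterative approximate subspace backend if communication
of d×d matrices ever became the constraint. Eigenvector signs are fixed
(largest-magnitude entry positive) for cross-platform reproducibility.

Before the PCA, each client may z-normalize every feature locally (mean 0,
variance 1 on its own training shard; variance floor 1e−8 maps locally
constant features to 0; test-shard data reuse the training statistics).
This is a batch-effect correction: a per-site affine distortion of the
features — different measurement platforms at different sites — is removed
entirely, making the subsequent pooled PCA invariant to per-client
positive-scale affine transforms. It is deliberately *local*: the sites
never compare distributions, which is exactly why a federated analysis must
treat distributed datasets as separate entities rather than as slices of
one dataset.

## Synthetic data

Three generator families stand in for the kinds of real data the framework
targets. They are first-class, tested code; every experiment is runnable
with no downloads.

* **Blobs** (image-digit stand-in): C isotropic unit-variance Gaussian
  clusters with means on a regular simplex scaled so the pairwise mean
  distance equals `separation`, equal class counts (±1). A single knob
  controls difficulty; `separation=3` (moderate overlap, Bayes accuracy
  ≈0.93 at d=20) is used for the learning-rate experiments so accuracy
  curves differ measurably across rates rather than saturating.
* **Expression** (transcriptome stand-in): a rank-k latent factor
  (per-dimension SD `latent_sd`=20) embedded in a random orthonormal
  subspace of d features, carrying a between-class mean displacement of
  total length `class_sep`=40; all other variance is independent
  per-feature noise with lognormal scale heterogeneity,
  sd_j = `noise_sd`·exp(1.8·N(0,1)) — the heavy-tailed per-gene variance
  profile real expression matrices show. The heterogeneity is load-bearing:
  with homoscedastic noise at n=300/d=2000 any subspace that PCA can rank by
  variance is also estimable from the labels directly, and raw-feature
  linear models do fine. With heavy-tailed variances the supervised
  class-direction estimate drowns in the high-variance junk features (raw
  test accuracy ≈0.57, near chance), while local z-normalization followed by
  PCA to 100 components recovers the signal (≈0.85) — the regime that makes
  dimensionality reduction essential.
* **Fingerprints** (molecular-fingerprint stand-in): i.i.d. Bernoulli
  (`density`) bits; a continuous latent activation on the pIC50 scale is a
  random linear read-out of the bits plus noise, shifted so the requested
  fraction of molecules exceeds the activation cutoff, then thresholded at
  6.3 — active strictly above, inactive at or below. The real datasets'
  class proportions are not published; `class_imbalance` is a free
  parameter (the joint class/sample imbalance of the real data can be
  obtained by composing this generator with the partitioners).

Batch effects are affine per-group distortions x ↦ x⊙scale_g + shift_g with
strictly positive scales. `random_batch_effect` sizes shifts at 3× each
feature's marginal SD and draws lognormal scales (log-SD 0.5) — strong
enough that, without correction, the top principal components encode site
identity rather than class signal.

What the generators do **not** emulate: pixel/sequence structure (all data
are tabular), gene–gene correlation beyond the planted low-rank factor,
realistic fingerprint bit correlations, or label noise. Passing tests
therefore demonstrate protocol-level properties (equivalences, robustness
and breakdown patterns), not expected accuracy on any real dataset.

## Partition schemes

* `iid`: per-class round-robin dealing; sizes within ±1, class mix matches
  the global mix exactly up to rounding.
* `si`: linear size ramp, client i's weight 1 + (ratio−1)·i/(N−1), default
  largest:smallest = N:1; stratified per class by largest-remainder
  apportionment. Ramp 1 reduces to IID sizes.
* `ci` (binary): equal sizes, positive-class fraction interpolating linearly
  lo→hi (default 0.1→0.9); per-class quotas rescaled to the samples actually
  available, infeasible demands raise. For C>2 the per-client proportions
  are drawn from a symmetric Dirichlet whose concentration
  α = max((1−w)/w, 0.3) shrinks as the requested width w = hi−lo grows
  (w→0 is the IID limit).
* `ci_aggressive`: client i holds classes {(i·m + t) mod C}, m classes per
  client (default ⌈C/2⌉); coverage of every class is checked, each class's
  samples are split evenly among its holders.

Remainders are dealt round-robin with a rotating start so equal-quota ties
do not pile onto the first client. Every scheme is an exact partition
(multiset equality of row ids is asserted in the tests) and fully
deterministic given its seed. Per-client train/test splitting (default
80/20, sizes round(n·f) and the remainder) is stratified; singleton classes
go to train, and at least one test sample is always retained.

## Experimental protocol constants

Matched between arms and fixed across all experiments unless stated: equal
learning rate between federated and centralized runs (except in the sweep,
whose purpose is to find the matching rate), rounds = epochs, one local
epoch, full-batch steps (n_batches = 1), four model-initialization seeds per
experiment, server-side evaluation on the concatenated test sets. Per-seed
"final accuracy" is the last round's value; no trailing-window averaging.

## Problem sizes

The shipped experiments are sized for a laptop-class single core: the
learning-rate sweep uses n=2000, d=20, 10 clients, 30 rounds, 4 seeds
(≈2 s); the batch-effect experiment n=360, d=500, 3 sites, k=100, 40 rounds;
the boosting-breakdown experiment n=800, d=10, C=4, 24 rounds. These sizes
were chosen so the qualitative patterns are stable across seeds while the
whole suite stays fast; the quantitative equivalences (factor-N, N=1
oracles, PCA exactness) are size-independent identities.

## Known limitations

* The simulation shares one process; it says nothing about wall-clock or
  communication cost of real deployments.
* Divergence (non-finite parameters) is recorded as a run flag, not an
  exception, so sweeps complete; diverged runs keep their last finite
  accuracy prefix.
* Mini-batch shuffling uses a per-(round, client) seed stream; federated and
  centralized arms match seeds, but per-sample visit order necessarily
  differs between a sharded and a pooled pass, so the factor-N relationship
  is exact only in the full-batch case and approximate under mini-batching.
* The multiclass boosting mechanics (one tree per class per round, softmax
  deviance) follow the standard construction; only the binary case has an
  external machine-precision oracle.
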