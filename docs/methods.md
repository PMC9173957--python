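# Methods

`cofsvm` classifies multilabel tabular data — motion-feature vectors from
sports-training or rehabilitation video are the motivating case — with a
fuzzy support vector machine whose training set is organised, graded and
reduced by fuzzy clustering. This note records the model, the numerical
choices, and what the synthetic benchmarks do and do not demonstrate.

## Fuzzy C-means granulation

Classic FCM (`cofsvm.fcm`) minimises

    J(U, c) = Σ_x Σ_y  p_xy^w  ‖i_y − c_x‖²,   Σ_x p_xy = 1,

by alternating the closed-form membership update
`p_xy ∝ d_xy^(−2/(w−1))` with the weighted-mean centre update
`c_x = Σ_y p_xy^w i_y / Σ_y p_xy^w` (the unique stationary point of the
Lagrangian in `c_x`). Defaults: fuzzifier `w = 2` (the ubiquitous choice;
`w → 1⁺` recovers hard k-means, large `w` flattens the partition),
tolerance `ε = 1e−4` on the largest membership change, 300 iterations max.
Centres are initialised as `C` distinct samples drawn without replacement
under the config seed, so runs are bit-reproducible. A sample at distance
zero from `k` coinciding centres receives membership `1/k` at each, keeping
columns stochastic.

## Kernelised clustering and the λ threshold

`cofsvm.kernel_fcm` replaces the Euclidean metric with the kernel-induced
squared distance `d(x,y) = Z(x,x) − 2Z(x,y) + Z(y,y)`. Because the feature
map is implicit, centres are maintained as convex weight vectors `v` over
the samples: `Z(x, q) = Σ_s v_s Z(x, i_s)`, `Z(q, q) = v᾿Kv`, so the whole
iteration runs on the Gram matrix. With a linear kernel the induced
distance is exactly squared Euclidean and the fit coincides with classic
FCM for the same seed — a property the tests check to 1e−8.

The λ threshold (default 0.65) crispifies decisive samples: once a sample's
largest normalised membership reaches λ it is snapped hard to that cluster.
This makes "core" samples identifiable by a high membership cutoff (the
pruning stage relies on it) at the price of a partition that is no longer a
strict descent sequence for the clustering objective; `lam=None` restores
the purely soft update. The membership exponent is `1/(w−1)` applied to
inverse squared distances, consistent between the classic and kernelised
updates.

## Label correlation by information gain

`cofsvm.info_gain` measures pairwise dependence between label indicator
columns as mutual information in bits, computed by both the double-sum and
the entropy-identity routes (they must agree to 1e−9; the released value is
clipped at zero). Probabilities are unsmoothed plug-in estimates; zero
cells contribute nothing. The matrix is reported as a diagnostic and can
optionally order the one-vs-one subproblem list by descending correlation;
no other stage consumes it, since the classifier itself has no natural
injection point for a label-pair weight.

## Membership-weighted SVM

The fuzzy SVM (`cofsvm.fsvm`) scales each training point's slack penalty by
its membership μ ∈ (0, 1]:

    min ½‖m‖² + C Σ μ_x ξ_x   s.t.  j_x(m·i_x + h) ≥ 1 − ξ_x,  ξ_x ≥ 0,

whose dual caps each coefficient at `μ_x C`. A point with low membership
simply cannot pull hard on the hyperplane — that is the entire
noise-robustness mechanism, and the tests verify it directly (a flipped
label with μ = 0.05 tilts the separator measurably less than with μ = 1).

Membership strategies:

* `constant-one` — classical SVM;
* `class-center-linear` (default) — `μ = 1 − (1−δ) r/r_max` with `r` the
  distance to the class mean and floor `δ = 0.1`, so the farthest member of
  a class keeps a small voice rather than vanishing;
* `kfcm-partition` — the sample's dominant-cluster membership from a
  per-class kernel-FCM run.

Mixed (dual-labelled) samples of a pair are graded within their own group:
they form a cluster midway between the two classes, and measuring them
against either single-label class mean would mark precisely the samples
that define the decision band as outliers.

## The dual solver

All machines reduce to one dual template: minimise `½α᾿Qα − p᾿α` under
`y᾿α = 0`, `0 ≤ α_k ≤ c_k`, with per-row margin targets `p` (+1 for
ordinary margins, −1 for mixed-band rows) and caps `c = μ·penalty`.
`cofsvm._qp.solve_svm_dual` is a sequential-minimal-optimisation solver
with second-order working-set selection and exact pairwise line searches.
Under a rank-deficient Gram matrix (linear kernels in low dimension) the
pairwise updates identify the active set quickly but then crawl inside a
nearly singular free block; a periodic projected-conjugate-gradient
minimisation over the free variables, truncated at the box, removes that
tail. Termination is on the maximal KKT violation (default gap 1e−8); the
offset is the mean over margin support vectors, or the midpoint of the
KKT-feasible interval when none are free.

An independent reference solver — Nesterov-accelerated projected gradient
with an exact breakpoint projection onto the box-plus-hyperplane set — is
shipped alongside for cross-checks on small problems and shares nothing
with the SMO path but the problem statement.

## Mixed-class one-vs-one decomposition

A `z`-label problem yields `z(z−1)/2` pairwise machines. Per pair `(w, t)`,
samples with only label `w` are positive, only `t` negative, both — mixed,
neither — excluded. Mixed samples are constrained to the margin band
`−1 ≤ f ≤ 1` with two membership-weighted slacks each; the band constraints
dualise to rows with target −1 in the same template (with no mixed samples
the machine is exactly the binary fuzzy SVM, verified to 1e−5).

At evaluation, `f > 1` claims the first label, `f < −1` the second, and the
closed band `[−1, +1]` claims both ("mixed"), each pair contributing one
vote, split half-and-half on a mixed outcome. A label enters the predicted
set when its votes reach `θ(z−1)`; the top-voted label is always emitted.

Two defaults here deserve their rationale:

* **Linear kernel for the pipeline.** The band rule reads decision values
  as margin-scaled distances from the separator. A strongly local kernel
  (rbf) saturates toward the offset far from the training data, so deep
  interior points of a class read as "mixed"; with a linear kernel the
  decision value grows with distance and the three-way semantics hold
  globally. The binary `fsvm` module keeps the conventional rbf default.
* **θ = 0.75.** Votes are quantised in half-vote steps. At θ = 1/2 the
  threshold coincides exactly with the total an uninvolved label collects
  when all of its pairs return "mixed" (half a vote each), so dual-labelled
  points systematically pick up a spurious third label; at 2/3 a label with
  one stray full vote plus two halves still enters. θ = 0.75 demands a
  clear majority and raised default-benchmark subset accuracy from ~0.3 to
  ~0.9. On dual-labelled points both true labels still clear the bar: the
  own pair contributes ½ + ½ and each remaining pair votes for the label it
  contains.

A knife-edge consequence of the inclusive band: training margin support
vectors evaluate to exactly ±1 and are therefore "mixed" for their own
pair. Their argmax label is still correct; very rarely a second label ties
the threshold on top of such a point.

## Cluster-based pruning

Support vectors live on the class rims; deep-core samples only enlarge the
QP. `cofsvm.pruning` clusters each class with kernel FCM (2 clusters per
class by default, λ = 0.65), flags samples whose dominant membership
reaches τ = 0.95 as interior (reachable only because λ-snapping hardens
decisive samples; τ = 1 with soft partitions prunes nothing by design), and
drops an interior sample only if its kernel distance to the nearest
other-class centre exceeds **both** the class radius (protects overlapping
classes) **and** the class's closest approach to that enemy plus one mean
class spread (protects the margin-facing rim, where the support vectors of
well-separated classes live — with the radius test alone, λ-hardened rim
points of distant classes would be dropped and the hyperplane would move).
At least `keep_min_per_class` samples survive per class, restoring the most
boundary-like drops first. The reduction is deliberately conservative: on
an isotropic unimodal class in high dimension the two within-class
sub-centres converge to the same point, memberships settle near 1/2, no
sample passes the interior test and the class is left whole — pruning can
be a no-op, never a hazard. The audit (kept/dropped indices, memberships,
radii) is serialisable to JSON. On the separated-Gaussian benchmark this
removes ~75% of the samples, zero support vectors, and shifts held-out
decision values by less than 1e−7.

## Synthetic benchmark

The generator (`cofsvm.synthetic_data`) emulates the statistical structure
the method assumes, with full ground truth: `z` isotropic Gaussian modes
placed as a regular simplex at mutual distance `class_separation · σ`
(σ = 1); a `dual_label_fraction` of samples drawn at the midpoint of a
random mode pair and marked with both labels, so the ±1 band is genuinely
populated; and a `noise_fraction` of single-label samples whose label is
flipped — annotation noise with clean features. Defaults are the standard
study condition used throughout the tests: n = 800, d = 16, z = 4,
separation 6σ, 10% dual, 5% noise.

The end-to-end benchmark trains on 600 samples and scores exact label-set
recovery on the held-out 200 **against the uncorrupted truth labels** —
recovering the pre-flip label is the point of a noise-robustness design.
With pipeline defaults the fixed-seed accuracy is ≈ 0.91, and
membership-weighting beats unit memberships on the paired 10-seed mean
(≈ 0.871 vs ≈ 0.848, no seed worse). A useful calibration: replaying the
vote aggregation with oracle machines built from the true generator
geometry caps at ≈ 0.935 on this condition — the inclusive band plus
half-vote aggregation on midpoint duals is the binding constraint, so the
trained pipeline operates near the scheme's ceiling.

What these benchmarks do **not** show: performance on real video features
(no pose/skeleton structure, no temporal correlation, no per-frame
covariance anisotropy), behaviour under heavy class imbalance, or kernels
beyond linear/rbf/polynomial. The mixed-class machinery is exercised only
by midpoint-style dual samples.

## Numerical conventions

* Distances: `d²` is squared Euclidean (or the kernel-induced square);
  membership ratios use exponent `1/(w−1)` on squared distances, equal to
  the textbook `2/(w−1)` on distances.
* Zero distance ⇒ hard assignment, split equally among coinciding centres.
* Decision value exactly 0 predicts +1; band boundaries ±1 are mixed.
* rbf `gamma` defaults to `1/(d · var(X))`, resolved at fit time and
  stored, so serialised models are self-contained.
* Model bundles and audits are JSON; floats survive the round trip
  bit-exactly (shortest-round-trip repr), so reloaded models reproduce
  decision values identically.
* Problem sizes in the test suite (n ≤ 800, 10-seed replications) were
  chosen so every stage, including the paired end-to-end comparison, is
  exercised at the defaults stated above.
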