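# Methods

`fcgraph` implements a complete survey pipeline for extracting weighted
graphs from resting-state fMRI-like volumes and judging which
graph-construction choices best support a probabilistic diagnosis across
three health conditions (healthy control C, mild cognitive impairment MCI,
Alzheimer's disease AD). This note documents the models, the estimators,
the numerical conventions, and the design choices made where the design was
genuinely open — in the spirit of the model documentation of packages such
as msprime or statsmodels.

## 1. Synthetic cohort generator

The generator emulates *preprocessed* resting-state data, not scanner
physics: no motion, physiological noise, drifts, or registration artifacts
are simulated.

Each subject is a 4D array over a voxel grid (default 12 × 12 × 6 = 864
voxels) with 130 time points at TR = 3 s. The grid is partitioned by
recursive coordinate bisection into `n_latent_clusters` contiguous
rectangular blocks. Each block k carries a latent signal z_k: the latents
are independent, stationary, unit-variance AR(1) processes (coefficient
`temporal_smoothing`, default 0.4 — modest autocorrelation at a 3 s
sampling interval) mixed by the Cholesky factor of a condition-specific
coupling matrix, so that corr(s_j, s_k) equals the coupling entry exactly
in expectation. Every voxel of block k observes s_k plus i.i.d. Gaussian
noise (`noise_sd`, default 0.5, i.e. latent-signal SNR 2:1 in amplitude).
Conditions differ *only* through their coupling matrices.

Shipped cohort presets (all with the 26/16/14 per-condition sizes of the
study population being emulated):

| preset | couplings (off-diagonal) | purpose |
|---|---|---|
| `default_config` | C 0.5, MCI 0.35, AD 0.2 | graded connectivity decline |
| `null_config` | all 0.35 | conditions statistically identical |
| `separable_config(gap)` | 0.4 ± gap/2 (default 0.7/0.4/0.1) | strong separation |
| `crossing_config` | C uniform 0.4; AD hub-star 0.55/0.15 | threshold-dependent sign flip |

The hub-star AD matrix of `crossing_config` (hub–leaf 0.55, leaf–leaf
0.15 over six clusters) is the strongest star coupling that remains
positive definite (minimum eigenvalue ≈ 0.03); ring and spanning-tree
designs with strong edges are not valid correlation matrices.

What the generator does **not** emulate: spatially varying
hemodynamics, method-specific information channels (all condition
differences are linear second-order couplings, which every model-free
estimator captures about equally well — see §7), subject-level
covariates, and registration error. Tests passing on these cohorts
therefore validate the *machinery*; they do not predict real-data effect
sizes.

Determinism: a cohort is a pure function of its configuration; per-subject
seeds are drawn from the master seed.

## 2. Parcellation

Three families turn a subject into graph nodes.

**Atlas.** A fixed integer label volume (for synthetic work: the
bisection tiling above) intersected with the subject mask; every subject
shares the same node set.

**Spatially constrained Ward.** Agglomerative minimum-variance merging of
voxel time series restricted to 6-connected (face) neighbours, stopping at
`k` clusters; clusters with fewer than `p` voxels are then discarded and
the survivors re-indexed. The merging is delegated to
scikit-learn's `AgglomerativeClustering` with a grid connectivity matrix,
which is exactly this algorithm. Paper-scale presets ward1–ward4
(k ∈ {5000, 2000}, p ∈ {10, 25}) are shipped; the synthetic-scale presets
(k ∈ {8, 16}, p ∈ {4, 8}) match the default 864-voxel grid.

**Region growing and selection (RGS).** Every masked voxel seeds a
candidate region. At each step, among 6-neighbours whose Pearson
correlation with the current region-mean signal exceeds T (preset 0.75),
the best-correlated one (ties: lexicographic coordinate) is added *if the
merged region stays functionally homogeneous*; homogeneity is re-tested
per added voxel. Selection then repeatedly takes the largest surviving
region (ties: lexicographic centre) and deletes every region whose centre
lies inside it; clusters below `p` voxels are dropped. Selected clusters
may overlap, but no cluster's centre lies inside another. Clusters split
into disconnected pieces by the deletion step are kept, counted and
logged.

**Heterogeneity (broken stick).** For N voxel series, the eigenvalues of
their N × N covariance are scaled to sum to N and compared with the
broken-stick baseline b_n = Σ_{i=n}^{N} 1/i (which also sums to N — this
common normalization is the reason for the eigenvalue scaling; no
normalization is canonical otherwise). n0 counts the leading eigenvalues
above the baseline and estimates the number of independent signals; an
interpolated index h refines it by locating the crossing. Conventions for
degenerate cases: pure-noise spectra never cross the baseline, so n0 is
clamped to ≥ 1; if the curves never cross downward (n0 = N), h is defined
as N; h is clamped to ≥ 1. Note that h evaluates to ≈ 1.9, not 1.0, even
for perfect copies of one signal — the crossing interpolation cannot reach
1 — so the RGS homogeneity gate is *n0 = 1*, not *h = 1*; h is computed
and reported as a descriptive statistic.

## 3. Edge estimators

Sixteen named variants (4 families × directed/undirected × full/windowed)
operate on cluster-mean series. Windowed variants use 50-point windows
advancing by 40 (10-point overlap); per-window weights are averaged
arithmetically (the aggregation is not otherwise determined). Absolute
values are taken; the diagonal is zero; undirected matrices are exactly
symmetric. A constant cluster series zeroes that node's incident edges
with a logged warning rather than failing the subject.

- **corr** — |Pearson|. Directed: maximum over target lags 0..5.
- **H2** — explained-variance fraction of y under a piecewise-linear
  regression of y on x over 10 equal-count bins of x (bins with < 2
  points merge with a neighbour; prediction extrapolates linearly beyond
  the outer bin means). Undirected: the larger of the two directions;
  directed: lag scan. Bounded to [0, 1]; unnormalized toolbox variants
  can exceed 1, this implementation cannot.
- **MIT** — mutual information from a 5 × 5 joint histogram (per-window
  min/max bin edges), normalized as I/√(H_X H_Y) so identical series
  score exactly 1.
- **TE** — binned transfer entropy. The target's next value y_t is
  conditioned on its own past, summarized as the mean of the previous 5
  samples (15 s at TR 3 s); the source enters as the single lagged sample
  x_{t−1−τ}, with τ scanned over 0..5 so the scan covers the source's
  recent 15 s. The statistic is the conditional mutual information
  I(y_t; x_{t−1−τ} | ȳ_past), estimated from a 5×5×5 histogram and
  normalized by H(y_t | ȳ_past) to lie in [0, 1]. Undirected TE is the
  mean of the two directed values. A full joint embedding of 5-sample
  pasts (5^11 cells) is hopeless at 130 samples; summarizing the *source*
  block by an aggregate was also rejected because it dilutes a 1-lag
  coupling by √5 and drops directional detection to ~75–80%, whereas the
  single-lagged-sample form (the standard order-1 embedding with delay
  scan) detects the direction of y(t) = x(t−1) + noise in 100/100
  seeded replicates at an unchanged null level.

Null calibration (500 independent standard-normal pairs, n = 130): 95th
percentiles ≈ 0.16 (corr), 0.12 (H2), 0.07 (MIT), 0.26 (TE). The TE null
mean (~0.23) is finite-sample histogram bias; it is stable, which is what
matters for comparing conditions.

## 4. Graph metrics and the feature vector

All metrics operate on the weighted adjacency; graphs are never binarized.
Thresholding sets weights strictly below w_min to zero (grid
0, 0.1, …, 0.8) and leaves the rest unchanged; analyses are gated on the
thresholded graph remaining connected. The rich club is the induced
subgraph on the ⌈10%⌉ highest weighted-degree nodes (degree ties broken by
ascending node id).

- Weighted degree deg_w(v) = Σ_u w_uv; normalized degree
  deg_n = deg_w/(deg · w_max) ∈ [0, 1] with deg the count of nonzero
  incident edges (isolated nodes: deg_n = 0). Directed graphs use the
  mean of in- and out-quantities so magnitudes match undirected graphs.
- Shortest paths minimize Σ 1/w (strong coupling = short distance),
  computed by Dijkstra; closeness C_w(v) = (n−1)/Σ_u dist(u, v).
- Zhang–Horvath clustering coefficient with weights normalized by the
  graph maximum: cc(v) = (Ŵ³)_vv / ((Σ_i ŵ_vi)² − Σ_i ŵ_vi²); reduces to
  2Δ/(k(k−1)) on binary graphs; nodes of degree < 2 get 0.
- Modularity (undirected only): Newman's Q under the ordered-pair
  convention. For graphs of ≤ 12 nodes the optimal partition is computed
  *exactly* by dynamic programming over node subsets (Q is additive over
  communities, so optimal partitions decompose; O(3^n) submask
  enumeration). Larger graphs use deterministic greedy multilevel
  (Louvain-style) maximization — nodes visited in ascending id, best-gain
  moves, ties to the lowest community id. The exact small-graph path
  exists because greedy multilevel search demonstrably misses the global
  optimum on a few percent of random 6-node weighted graphs (canonical
  implementations included), which would silently bias small-graph
  surveys; at survey scale (hundreds of nodes) the heuristic is the only
  practical option. The returned Q is always re-evaluated exactly on the
  returned partition.

**Feature vector.** For each of five property distributions — edge
weights (nonzero), normalized degree, shortest-path distances (unordered
pairs for undirected graphs, ordered for directed), closeness, clustering
coefficient — the first four moments are reported as mean, standard
deviation, skewness and excess kurtosis (all three shape moments defined
as 0 for degenerate distributions). Node count enters as n/100 so every
feature is of order unity, and undirected graphs append Q: d = 22
(directed: 21, no modularity). No node-level features are used, so
subject-specific parcellations remain comparable; no transform is applied
to restrict feature ranges.

## 5. Diagnostic model and scoring

Working hypothesis (partial exchangeability by sufficiency): the empirical
mean and covariance of previous same-condition patients' feature vectors
suffice to predict a new patient. The conjugate update is

κ = κ0 + n, ν = ν0 + n, δ = (κ0 δ0 + n f̄)/(κ0 + n),
Δ = Δ0 + n Cov(f) + κ0 n/(κ0 + n) (f̄ − δ0)(f̄ − δ0)ᵀ,

with Cov using divisor n, and the predictive is multivariate t with
ν − d + 1 degrees of freedom, location δ and scale
(κ+1)/(κ(ν−d+1)) Δ (density via `scipy.stats.multivariate_t`). Fixed
hyperparameters, reflecting features of order unity: κ0 = 1, δ0 = 0.5 per
component, Δ0 = 2.5 I. ν0 has no canonical value; the default ν0 = d + 2
is the smallest integer giving the predictive a finite covariance, and is
exposed in the configuration because results at small n are sensitive to
it.

Per-condition likelihoods combine with a prior over conditions (default
uniform, 1/3 each) by Bayes' theorem in log space. The score is the
**negative surprise** ln P(true condition): 0 for a sure correct
prediction, ln(1/3) ≈ −1.1 at chance for three equiprobable conditions,
−∞ for a confident error. Evaluation is leave-one-out over all subjects;
the reported quantity is the mean over held-out subjects.

**A caveat that the null-cohort test makes measurable.** With unequal
class sizes, the larger class's predictive is systematically sharper
(both κ and ν grow with n), and at d = 22 the per-dimension density
advantages compound: on a null cohort (identical condition distributions,
26/16/14) the LOO mean surprise settles near −2.9 — below chance — with
held-out subjects pulled toward the largest class. With low-dimensional
features (d ≤ 5) the same machinery recovers ln(1/3) ± 0.05. This is a
property of the fixed-hyperparameter model at small n and large d, not an
implementation artifact, and it is reported as computed rather than
adjusted away. Directed-H2 feature vectors carry a caveat flag in survey
output for the same family of reasons: the model fit for that variant is
questionable.

## 6. Survey, evaluation and comparisons

`run_survey` executes clustering presets × edge presets × thresholds ×
subgraphs, skipping (with a logged reason) any combination whose graph
disconnects for some subject or whose rich club would have fewer than two
nodes, and is resumable per combination when writing to an output
directory. Completed + skipped always equals requested.

Group comparisons use a two-sided F-test at α = 0.05 to choose between
Student's (equal variances) and Welch's t-test, two-sided, per condition
pair; no multiple-testing correction is applied (matching the
per-comparison p < 0.05 usage under study; comparison counts are reported
so users can correct). The significance scan reports, per clustering
family × edge family × property × pair × direction, the fraction of
method variants significant in that direction — on a crossing cohort both
directions appear, which is the central methodological warning this
package operationalizes: the sign of a "significant" group difference can
be an artifact of the threshold choice.

Subject rank profiles order all subjects by a property's per-subject mean
(ties by subject id); profiles are compared by Euclidean distance and
clustered with average linkage (UPGMA; no linkage is otherwise
determined), exportable as Newick. Pairwise classification uses an SVM
with RBF kernel and default regularization, scored by leave-one-out
accuracy, with greedy forward feature selection (strict improvement
required; exact duplicate columns dropped up front so redundant features
cannot change the result). The surprise-vs-accuracy comparison fits a
least-squares line excluding the TE family, which is reported separately.

On a strongly separated synthetic cohort every model-free combination
classifies perfectly, so the surprise–accuracy *correlation* is measured
on a moderately separated cohort (gap 0.3, noise 0.5). Even there the
non-TE accuracy spread is only a few points, because the generator
differentiates conditions through a single linear coupling dial that all
model-free estimators capture equally well; the robust qualitative
signature is the TE contrast (TE combinations far worse on both axes).
Method-dependent real-data structure that would spread the model-free
families apart is outside what this generator emulates.

## 7. Problem sizes and reproducibility

Default test/validation sizes, chosen so every stage is exercised at
meaningful scale: 56-subject cohorts on the 864-voxel grid for end-to-end
runs; 500 null pairs and 100 directional replicates for estimator
calibration; 100 random ≤ 8-node graphs against the exhaustive
shortest-path oracle, 100 binary 10-node graphs against the binary
clustering-coefficient identity, and 60 random 6-node graphs (plus the
two-triangle case) against the 203-partition exhaustive modularity
search; n = 500 for posterior parameter recovery. Every random quantity
derives from an explicit seed; the full survey is bit-reproducible from
its configuration.
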