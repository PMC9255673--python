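# Methods

This note documents the models, numerical choices and open design decisions
behind `connectocca`, and what the synthetic experiments do and do not show.

## Pipeline overview

Stages, in execution order: behavioral imputation → subject split → group
matrices → dendrogram → unique-module catalog → multiscale features →
modality filter → z-score / PCA / CCA with model-order selection → test
evaluation → permutation inference → weight maps. All randomness is drawn
from named seeds (`split_seed`, `perm_seed`, the generator's `seed`), so any
run is exactly reproducible.

## Synthetic cohorts

The generator emulates a resting-state study population at desk scale.

**Geometry.** V nodes are partitioned into a balanced block tree given by
`branching` (default (4, 5, 2) at V = 200: 4 coarse systems, each split in
5, each split in 2, i.e. 40 leaf blocks of 5 nodes). Eight anatomical
macroregion labels are assigned round-robin over the blocks of the
shallowest depth with at least eight blocks — macroregions therefore group
whole tree blocks but, like real anatomy, need not be contiguous subtrees.
Seven resting-state-network labels are assigned round-robin over leaf
blocks, with every eighth leaf block left "unassigned" (standing in for
nodes below the 50% overlap rule implemented in
`network_labels_from_overlap`).

**FC.** Node time series follow a hierarchical factor model,
`z_i = a_i * sum_d sqrt(c_d) G_{b_d(i)} + sqrt(1 - a_i^2 C) eps_i`, with
independent standard-normal block factors G at each depth. Two nodes whose
deepest shared block is at depth s have population correlation
`sum_{d<=s} c_d`; the defaults (0.15, 0.10, 0.05) give within-leaf-block
correlation 0.30 falling to 0.15 across coarse blocks and 0 across systems.
FC is the *finite-sample* correlation of `n_timepoints = 300` simulated
timepoints, so FC estimation noise (sd ≈ (1−r²)/√T) is present, as in real
resting-state scans of a few hundred retained volumes.

**SC.** Streamline counts are Poisson with mean `sc_rate_by_depth[s]` at
shared depth s (defaults 2, 6, 15, 30): non-negative integers whose rate
decays with tree distance. Poisson is the minimal count law; real tractography
counts are over-dispersed and distance-biased, which we do not model.

**Planted association.** A per-subject standard-normal latent trait η
modulates the shared-factor amplitude of the nodes of each designated signal
module: `a² = 1 + γ·η/C` (η clipped at ±3σ; γ = `fc_signal_strength`,
default 0.08), so within-signal-module correlation becomes `C + γ·η` — a
**zero-mean** modulation. The zero mean matters: a planting mechanism that
raises the average within-module correlation makes the signal module an
artificially tight cluster that fine-scale tree cuts never split, hiding the
trait from all but one catalog module; the multiplicative form leaves the
group tree unbiased and expresses η in the signal module and every module
nested in it. On the SC side, Poisson rates within signal modules are scaled
by `exp(γ_sc·η)` (γ_sc = 0.25). The behavioral latent is the standardized
sum of z-scored *realized* within-module features (mean |FC|, mean SC) of the
signal modules; score 1 is `rho_true·z(latent) + sqrt(1−rho_true²)·noise`,
and the remaining scores mix score 1 with fresh noise at coefficient 0.3.
Consequences used by the tests: (a) the correlation between the designated
module feature and score 1 converges to `rho_true`; (b) score 1 alone is the
optimal behavioral direction (the other scores add no information about the
latent beyond score 1), so the recovered first column of B should align with
the first coordinate axis; (c) two signal modules carry the *same* trait, so
deleting either one alone leaves a redundant copy — the compensation
phenomenon the lesion scan is designed to reveal.

**Missingness** is injected completely at random at `missing_rate`, never
emptying a row and keeping every column at least half observed. The scores'
joint covariance is a declared mixing design, not an estimate of any real
battery's structure.

**What passing does not show.** The generator has exchangeable, equally
sized nodes, Gaussian signals, a single latent behavioral trait and
block-constant connectivity. Success here demonstrates the pipeline's
statistical correctness (calibration, recovery, discrimination), not that
real acquisition artifacts, head motion, parcellation error or multi-trait
behavior are handled.

## Hierarchy

Node profiles are each node's FC row concatenated with its SC row, each
modality standardized over all its entries first; SC is log(1+x)-transformed
for clustering only (features use raw counts), because heavy-tailed counts
would otherwise dominate the profile distance. Distance/linkage are
correlation distance with average linkage (overridable; euclidean/ward are
accepted). Group matrices are element-wise means over **training** subjects
only, so the tree never sees validation/test subjects. Cuts use the
merge-reversal rule (undo the last m−1 merges), which guarantees exactly m
modules and that finer cuts refine coarser ones; the catalog is the union of
all grid-level cuts deduplicated by exact node-set equality, singletons
discarded, ordered by first appearance then smallest node index. Default
desk-scale grid: M = 10…100 step 10 (the full-scale study shape, 20…1,000
step 20, is available and validated arithmetically). When a lesion reduces V
below `m_max`, the grid is capped to the largest sub-grid fitting V
(`auto_cap_grid`); a no-op deletion leaves V unchanged and hence the exact
same grid.

## Association

**Imputation** is k-nearest-neighbors (k = 5): distances are RMS differences
over z-scored jointly observed columns, neighbors must observe the target
column, ties break by row order. This is written out (≈40 lines) instead of
delegating to a library imputer because the distance definition above is the
package's contract and is what the brute-force oracle in the tests checks.

**CCA** is the classical formulation: economy QR of the centered blocks and
SVD of Qx'Qy; singular values are the canonical correlations, so the
realized corr(U1, V1) equals R exactly. Inputs must satisfy N > D + Q and be
full rank (relative diagonal tolerance 1e−9); the canonical pair count is
K = min(D, Q). Sign convention: each B column is oriented to a positive
leading coefficient (flipping A jointly), and transferred correlations are
reported as magnitudes, since a canonical pair's sign is arbitrary.

**Model order.** z-scoring of X and Y is learned on the training set
(zero-variance columns dropped with a warning); PCA is fitted once at the
largest feasible order and truncated per candidate D (principal components
are nested). For each D in the grid (default 2…150 step 2, capped at
min(F, N_train − Q − 1)), the validation R is computed with the training
mixes; D* maximizes that curve, ties to the smallest D. Ve is the training
explained-variance fraction at D*.

**Inference.** The default permutation scheme permutes the *test-set* score
rows with the trained model fixed — this tests exactly the reported
transferred statistic, and is exact under exchangeability because permuting
Y's rows permutes V1's rows. p uses the add-one rule
`(1 + #{R_perm ≥ R_test}) / (1 + n_perm)` with n_perm = 2,000 by default.
An alternative scheme that refits the CCA on permuted training scores is
available (`perm_mode="refit"`).

## Maps and lesions

The first canonical direction is projected to feature space (W = W_PCA·a1,
absolute values), z-scored across features as one vector (the map is
thresholded as a whole, default Z > 2). Surviving weights are **summed** per
module (sum chosen over mean/max so module weight scales with how much of
the map it carries). Network overlap is the percentage of all nodes that lie
in a surviving module and carry each network label — the normalization is a
documented package decision. The per-scale modality balance attributes each
feature's weight to every scale its module appears at and permutes modality
labels within a scale for a two-sided imbalance test.

Lesions delete every node of a label, rebuild matrices, and rerun the full
pipeline — tree rebuilt, catalog re-enumerated, model order reselected — with
identical subjects, split and seeds, so rho isolates the deletion. Model
order *is* reselected per deletion by default (rebuilding is the honest
"recompute everything in its absence" semantics); `frozen_tree` restricts
the intact catalog to the surviving nodes instead, for the cheaper variant.

## Problem sizes in the test suite

The statistical acceptance checks run at desk scale, chosen once: null
calibration uses 200 independent cohorts of N = 300, V = 100 with 199
permutations at α = 0.05; recovery uses 20 cohorts of N = 500, V = 200 with
rho_true = 0.6; lesion discrimination 20 seeds and compensation 5 seeds at
N = 300, V = 100 (8 one-block macroregions); multimodal-vs-unimodal 10 seeds
at N = 400. The catalog oracle enumerates all cuts of random trees up to
V = 12. The compensation thresholds (median single-deletion rho ≥ 0.75,
median double-deletion rho < 0.5) were fixed a priori from the generative
analysis above: a redundant copy retains cos² ≈ 0.97 of the latent's
variance, while the double deletion leaves only noise-level association.

## Known limitations

- Poisson SC has no over-dispersion; FC clipping at ±1 is a no-op in
  practice but matters for adversarial inputs.
- The paper-scale feature count (thousands) is not exercised by default;
  the pipeline is vectorized but tree building is O(V²) memory.
- The lesion ratio divides by an *estimate* of R²(all present); at weak
  associations its sampling noise makes individual rho values disperse
  around 1 (visible in the examples), which is why the tests compare
  signal vs intact regions within a run rather than asserting rho = 1
  numerically.
- Only the first canonical mode is interpreted and reported, by design.
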