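# connectocca

Multiscale, multimodal connectome-to-behavior association analysis:
hierarchical module features from structural (SC) and functional (FC) brain
networks, PCA + canonical correlation analysis (CCA) with three-cohort
model-order selection and permutation inference, brain-map projection of the
solution, and virtual-lesion quantification of regional importance.

The package is aimed at network-neuroscience researchers who want to ask,
with proper train/validation/test hygiene: *how strongly do multiscale
connectivity features predict multidomain behavioral performance, which
modality (structure, function, or both) carries that association, and which
brain structures are indispensable for it?* Because the motivating data
(large human neuroimaging cohorts) are access-restricted, the package ships a
first-class synthetic-cohort generator that plants a known association, so
every stage of the pipeline is testable end to end without any download.

## The model

Each subject contributes a functional connectivity matrix (pairwise Pearson
correlations of node time series) and a structural connectivity matrix
(streamline counts) over a common set of V nodes. A single group dendrogram
is built by average-linkage clustering of the concatenated, standardized
FC+SC connectivity profiles; cutting it at a grid of levels M and
deduplicating the resulting node sets yields the *unique modules*. For every
module and subject, four features are computed:

- **FIC / FEC** — mean absolute FC weight over links within the module / links
  leaving the module;
- **SIC / SEC** — the same link sets averaged on raw SC weights.

Stacked over modules and scales this gives the feature matrix X (N x F).
After z-scoring (parameters learned on the training set) and PCA to D
components, CCA finds mixes A and B maximizing the first-mode canonical
correlation

    R = corr(U1, V1),  U = PC·A,  V = Y·B,

where Y holds the Q behavioral scores. The model order D is selected by
maximizing the *validation*-set R computed with the *training* mixes
(A_train, B_train); the reported statistic T = R_test is the transferred
correlation on the held-out test set, with significance from permuting the
test-set score rows (add-one rule, 2,000 permutations by default). The
solution is projected back to feature space as W = W_PCA·W_CCA, |W| is
z-scored and thresholded at Z > 2, and summarized per module, per
resting-state network, and per scale/modality.

Regional importance is quantified by virtual deletions: all nodes of a
macroregion (or network) are removed, connectivity matrices rebuilt, the
*entire* pipeline rerun with identical subjects and seeds, and the ratio

    rho_i = R²(region i absent) / R²(all present)

reported — rho ~ 1 marks an irrelevant (or compensated) region, rho < 1 a
constructive one.

## Worked example

```python
import connectocca as cc

module = cc.signal_module_for_macroregion(100, (8, 2), "frontal")
spec = cc.SynthSpec(n_subjects=300, n_nodes=100, branching=(8, 2),
                    fc_within_minus_between=(0.15, 0.10),
                    sc_rate_by_depth=(2.0, 8.0, 20.0),
                    rho_true=0.6, signal_modules=(module,), seed=3)
cohort = cc.generate_cohort(spec)
cfg = cc.PipelineConfig(grid=cc.ScaleGrid(4, 72, 4),
                        d_grid=tuple(range(2, 61, 2)), n_perm=2000)
res = cc.run_pipeline(cohort, cfg)
rep = res.report
print(rep["model_order"], rep["explained_variance"], rep["r_test"], rep["p_value"])
```

prints `14 0.38 0.390 0.002499`: the validation curve selected D = 14
principal components (explaining 38% of the training feature variance), the
transferred test-set canonical correlation is T = 0.39 for a planted
association of 0.6 at this desk-scale sample, and none of 2,000 permutations
beat it (p ≈ 0.0025). Running the lesion scan on the same cohort
(`cc.lesion_scan(cohort, "macroregion", cfg)`) gives rho = 0.08 for the
region carrying the planted signal and rho ≈ 0.8–1.8 for the others — the
deletion of the signal-bearing region collapses the association, the rest do
not. The `examples/` directory walks through each capability
(`01_simulate_cohort.py` … `05_brain_maps.py`); a thin CLI mirrors the
stages (`connectocca simulate|hierarchy|features|fit|lesion|map|run-all`).

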