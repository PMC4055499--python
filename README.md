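# mpmri

Multiparametric MRI connectomics for two-group cohort studies (autism
spectrum disorder vs. typically developing controls): small-world network
efficiency from functional and structural-covariance connectivity,
quantitative resting-state fcMRI features, PCA+mRMR feature integration,
machine-learning classification, and phenotype prediction — exercised end
to end on synthetic cohorts with planted effects, so every stage is
testable without any imaging download.

## Who this is for

Researchers analyzing *post-preprocessing* tabular neuroimaging data:
per-subject regional cortical thickness (148 regions), regional volumes,
and ROI time series (112 regions × 180 volumes at TR = 2 s). Image-space
preprocessing (realignment, smoothing, nuisance regression, segmentation)
is assumed done and out of scope.

## The models at the core

**Small-world efficiency.** A connectivity matrix `R` (Pearson correlation
of ROI time courses within a subject, or of a regional anatomical measure
across the subjects of a group) is binarized at sparsity `s` by keeping the
`⌊s·n(n−1)/2⌋` strongest positive correlations. On the resulting graph,

- global efficiency  `E_glob = (1/(n(n−1))) Σ_{i≠j} 1/d_ij`  (1/∞ = 0),
- local efficiency  `E_loc = (1/n) Σ_i E_glob(G_i)` with `G_i` the subgraph
  induced by the neighbors of node `i`,

and *relative* efficiency divides each by its mean over degree-preserving
random graphs (Maslov–Sneppen double edge swaps). Group differences are
tested per sparsity with two-sample t-tests (subject-level functional
networks) or a label-permutation test with bootstrap error bars
(group-level structural covariance networks).

**Quantitative fcMRI features.** For each seed network the connectivity
map is summarized by `N` (regions with standardized Fisher z
`atanh(r)·√(T−3)` above 2.3) and `Z` (their mean); homotopic connectivity
(VMHC) applies the same summary to mirrored left/right ROI pairs; fALFF is
the fraction of spectral amplitude in 0.01–0.08 Hz.

**Feature integration.** The 22-feature table (9 supratentorially
normalized subcortical volumes, 8 seed N/Z summaries, 3 fALFF means,
2 VMHC summaries) is variance-normalized; the SVD of its covariance fixes
the number `k` of components holding 95% (or 99%) of the variance; greedy
mRMR (plug-in mutual information on μ±σ three-bin discretized features,
difference criterion `MI(f;y) − mean_g MI(f;g)`) selects `k` features.

**Learners.** A randomized decision tree (random `⌈√d⌉` feature subsets,
information-gain splits, grown to purity) classifies ASD vs. TD under
full-dataset / stratified k-fold / percentage-split protocols with margin
curves; an entropic instance-based (K*-style) regressor — Gaussian-kernel
weighted average with a per-query bandwidth solving an effective-neighbor
constraint — predicts clinical scores (ADOS, ADI-R, IQ, SRS, VABS),
reported as Pearson r and observed~fitted slope.

## Worked example

```python
from mpmri import (CohortConfig, simulate_cohort, compute_feature_table,
                   mrmr_select, evaluate, predict_phenotype)

cfg = CohortConfig(n_per_group=60, seed=2014)
cohort = simulate_cohort(cfg)                      # 120 subjects, planted effects
table = compute_feature_table(cohort)              # 120 x 22 features
labels = (table.groups == "ASD").astype(int).to_numpy()
sel = mrmr_select(table, labels, 6)
print(sel.selected)

X = table.data[sel.selected].to_numpy()
print(evaluate(X, labels, "kfold", 10, seed=2014).accuracy)

ados = cohort.phenotype_frame()["ados_module"]
_, r, slope = predict_phenotype(table, sel, ados, seed=2014)
print(round(r, 3), round(slope, 3))
```

prints

```
['fc_ifg_triangularis_Z', 'fc_ifg_opercularis_Z', 'fc_caudate_Z', 'vmhc_Z', 'fc_dmn_Z', 'vol_caudate_R']
0.8583333333333333
0.867 1.288
```

The selection recovers the planted signal: the three strongly affected
seed-Z features first, then the mildly affected VMHC/DMN features and the
right caudate volume. Ten-fold accuracy (~0.86) is the honest
generalization estimate; the full-dataset tree memorizes at 1.0. The ADOS
fit (r≈0.87) reflects the planted linear coupling of the score to
caudate/IFG connectivity; the slope above 1 is the attenuation of a
kernel smoother read in the observed~fitted direction.

The same chain runs as numbered drivers — `analysis/01_simulate_cohort.py`
through `analysis/07_group_stats.py` (tables under `results/`) — or as a
CLI: `mpmri simulate|networks|metrics|features|select|classify|predict|stats|run-all`.

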