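# Methods

## Scope and data model

The package analyzes post-preprocessing tabular MRI data for a two-group
(ASD vs. TD) cohort: per-subject cortical thickness over 148 regions,
regional volumes (45 subcortical + 70 white-matter regions plus the total
supratentorial volume), ROI time series (112 regions × 180 volumes,
TR = 2 s, already band-passed to 0.005–0.1 Hz and nuisance-regressed), and
clinical scores from five instruments (ADOS, ADI-R, IQ, SRS, VABS). All
image-space processing is assumed done upstream; there is no voxel or
NIfTI handling anywhere.

## Synthetic cohort generator

The generator is first-class code: it defines the study conditions under
which every downstream claim is tested.

**Anatomy.** Regional baselines are deterministic per region; subjects get
multiplicative noise (volumes: fractional SD 0.06; thickness: 0.05).
Group effects are multiplicative mean shifts on configured regions in the
ASD group. Defaults plant caudate enlargement (+6.5%/+8% L/R, within the
few-percent range typical of the condition), a mild bilateral hippocampal
increase (+2%), and ~4% cortical thickening on a subset of regions.
Ages are uniform on [8, 20] years for both groups and the female fraction
is 24%, matching the demographic conventions of the emulated sample; these
are conventions, not estimands.

**Thickness covariance.** Each subject's thickness deviation is
`√g·F + √a·f_b + √(1−g−a)·ε`, with `F` a cohort-wide factor, `f_b` one
factor per hemisphere-lobe block (8 blocks), and private noise. The pair
(g, a) is group-dependent: TD (0.35, 0.10) — an integrated, long-range
correlated cortex — versus ASD (0.05, 0.45) — a modular, locally
over-connected one. A pure per-block model cannot plant this difference:
both groups' thresholded graphs would fill within-block edges first and be
topologically indistinguishable; the cohort-wide factor is what gives the
TD group its cross-block edges and hence higher relative global
efficiency. This is the generator's expression of the local
over-connectivity / long-range under-connectivity hypothesis.

**Time series.** ROI `i` in seed network `m` follows
`x_i = √c_m·g_m + √h·q_p + √(1−c_m−h)·e_i`, all components unit-variance
white noise masked to 0.005–0.1 Hz in the frequency domain (so expected
correlations are analytically `c_m` within a network and `h` within a
homotopic pair, and fALFF values are predictable from band overlap). Each
seed network projects into a disjoint set of cortical "target" ROIs at
coupling `0.5·c_m`; without this, seed maps would contain no genuine
suprathreshold regions and N/Z would be noise. Couplings are jittered per
subject (SD 0.04, homotopic SD 0.06) — between-subject variability is what
gives the global VMHC/DMN summaries realistic within-group variance.
Default couplings: caudate 0.45/0.25 (TD/ASD), IFG subdivisions 0.40/0.22,
DMN 0.45/0.40, homotopic 0.32/0.29 — strong caudate/IFG reductions, mild
DMN/VMHC reductions.

**Phenotypes.** Each score is `intercept + Σ β_f·z_f + ε` on cohort
z-scored imaging features, truncated to instrument ranges (ADOS 0–22,
IQ 40–160, …) and rounded to integers. Signs follow the clinical pattern:
connectivity features couple negatively to ADOS/ADI-R and positively to
adaptive-behavior scores.

**What the generator does not emulate:** site/scanner effects, motion
artifacts, age/sex dependence of any measure, non-Gaussian anatomy,
spatially autocorrelated maps, voxel-level structure. Passing tests
therefore demonstrate that the *pipeline recovers what it assumes*, not
that real ASD data behaves this way.

## Networks and efficiency

Binarization keeps the `⌊s·n(n−1)/2⌋` largest positive correlations
(negative weights are never eligible; Fisher z is rank-preserving and thus
irrelevant before thresholding), with deterministic (row, column) tie
breaks, making edge sets nested across the sparsity grid (default
0.05–0.50 in steps of 0.05). If fewer positive correlations exist than
requested edges the grid point errors; the profile sweep records the error
and continues.

Efficiency uses the classical inverse-shortest-path definitions; distances
come from breadth-first search (a numba-compiled kernel, with an identical
pure-python fallback; `shortest_path_lengths` exposes the scipy BFS).
Unreachable pairs contribute zero efficiency rather than restricting to
the giant component, keeping `E_glob` monotone under edge addition and
defined at low sparsity. "Total" efficiency is defined as
`E_loc + E_glob` per sparsity. Null normalization uses double-edge-swap
rewiring (10× edge count accepted swaps, bounded retries; graphs such as
K3 with a unique degree-sequence realization return unchanged) and the
mean of `n_random` nulls (default 100 for one-off profiles; the replication
studies use 3–10).

**Group comparison.** Subject-level functional profiles use a pooled
two-sample t per sparsity. Group-wise structural covariance networks
report subject-resampling bootstrap error bars and 95% CIs, but
*significance* comes from a group-label permutation test: the bootstrap
spread of a thresholded-network statistic systematically overstates its
sampling variability (duplicated subjects inflate sample correlations), a
z-test against it rejected far below nominal rate, whereas permutation is
exact under the null by construction. This is a deliberate design choice
documented here because the two uncertainty routes answer different
questions: the bootstrap describes the estimate, the permutation tests the
group difference.

## Feature integration

The canonical table has exactly 22 columns: 9 normalized subcortical
volumes (`raw/supratentorial×1000`), N and Z for 4 seeds, 3 fALFF seed-set
means, global VMHC N and Z. Variance normalization uses the population
(n) denominator. Component counting decomposes the covariance of the
normalized table (equivalent to correlation-PCA) and returns the minimal k
whose leading eigenvalues hold ≥ 95% (or 99%) of the trace. mRMR
discretizes each feature into three bins at μ±σ (making selection
invariant to affine rescaling), uses plug-in MI in nats, and greedily
maximizes the difference criterion (quotient available); ties break toward
the lower canonical column index.

## Learners and evaluation

The random tree considers `⌈√d⌉` randomly drawn features per node and
splits at the best information-gain midpoint; a zero-gain split is still
taken when the node is impure (XOR-style interactions require it) and
growth terminates because candidate splits always leave both children
non-empty; nodes with all-duplicate feature rows become leaves. Leaf class
frequencies are the probability estimates feeding margin curves
(`p_true − max p_other`, sorted, with cumulative counts).

The instance regressor stores z-scored training features and predicts a
Gaussian-kernel weighted mean. The per-query bandwidth solves
`Σw/max(w) ≈ blend` (default 5 effective neighbors) by bisection on log h;
weights are computed relative to the nearest neighbor so the search is
immune to exponential underflow. `blend → 1` approaches nearest-neighbor
memorization (slope → 1 on noise-free targets); larger blends trade
variance for attenuation bias, which is why observed~fitted slopes exceed
1 on noisy full-dataset fits.

Protocols: full-dataset; stratified k-fold (round-robin assignment of
shuffled within-class indices, k ∈ [2,10]); percentage split
(fraction ∈ [0.1, 0.9], one reshuffle before erroring on a missing class).
Everything is seed-deterministic.

## Group statistics

Volumes are supratentorially normalized before comparison (×1000 scale);
thickness is compared in raw mm. The default test is pooled-variance
two-sided t (Welch by flag); regional p-values get the ×8 Bonferroni
factor (4 lobes × 2 hemispheres). Feature–phenotype correlations use
pairwise deletion of missing scores (minimum 4 complete pairs) and
correction by 5 (categories) × the category's sub-domain count
(ADOS 10, IQ 3, ADI-R 5, SRS 7, VABS 15). The bundled reference tables of
group means reproduce their tabulated percentage changes to the last
digit; one thickness cell differs by exactly one unit in the third decimal
because that change was rounded from unrounded means.

## Replication studies and problem sizes

`mpmri.studies` fixes the scaled study sizes (also used by
`scripts/acceptance.py` and the acceptance tests): graph-oracle agreement
on all 1 098 graphs of ≤ 5 nodes plus 500 random graphs of ≤ 40 nodes
against an independent Floyd–Warshall oracle; small-world power on 3
replicate cohorts of 50 subjects/group × 60 regions (6 mid-sparsity
points, 79 permutations, 6 nulls); type-I calibration on 200 null cohorts
of 25/group × 40 regions (one sparsity, 59 permutations); mRMR recovery
over 20 cohorts of 50/group at full feature dimensions; model calibration
at n = 200 (classification) and n = 300 (regression); and one
140-subject default-condition cohort for the end-to-end feature /
classification / prediction numbers.

## Known limitations

- Region-level N counts stand in for voxel counts; Gaussian-random-field
  cluster correction is replaced by the fixed z > 2.3 threshold.
- Only two learners are implemented (the tree classifier and the K*-style
  regressor) plus the evaluation harness; no classifier sweep.
- The permutation test for structural networks assumes exchangeability of
  subjects under the null — valid for the generator, an approximation when
  groups differ in nuisance covariates.
- Bootstrap CIs for thresholded-network statistics are descriptive, not
  inferential (see above).
- Component counts at 95%/99% depend on the data covariance; only the
  thresholding rule is guaranteed, not any particular k.
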