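# Methods

This note documents the models, parameter choices and numerical conventions
behind `flnet`, in the order the pipeline runs them.

## Task paradigm and HRF model

The default paradigm is the standard covert word-generation block design:
8 epochs, each 20 s of task followed by 30 s of rest, sampled at TR = 2.5 s,
giving 160 frames over 400 s. Epochs start with the task block at t = 0;
the order is configurable (`task_first`). The expected BOLD response is the
task boxcar convolved with a unit-area Gaussian kernel peaking 5 s after
stimulus onset with SD 2.5 s. These HRF parameters are conventional values
for a Gaussian response model; they are exposed in `AnalysisConfig`
(`hrf_peak_s`, `hrf_sd_s`) because the analysis literature does not fix
them. The kernel is sampled at TR, truncated at peak + 4 SD, and normalized
to sum exactly 1.

## Activation mapping

Per voxel, the statistic is the Pearson correlation r of the (optionally
detrended and spatially smoothed) series with the HRF regressor, converted
to a two-sided p-value via t = r·sqrt(T−2)/sqrt(1−r²) with T−2 degrees of
freedom. The choice of the t transform is ours; on Gaussian noise it is
exact, which the null-calibration tests verify. Constant series are flagged
and given r = 0, p = 1.

Filters, with defaults:

* voxel threshold `p_voxel` = 0.001 (two-sided);
* SD filter `sd_fraction` = 0.08 — a voxel is excluded when its temporal SD
  exceeds 8% of its temporal mean (large-vein and motion artefact rule),
  computed on the raw input series; voxels with nonpositive mean make the
  ratio undefined and are excluded and flagged;
* spatial smoothing `smooth_fwhm_mm` = 4 (FWHM; sd = FWHM/(2√(2 ln 2)) in
  mm, converted to voxels; 0 disables);
* linear detrending per voxel, on by default (drift parameters are not part
  of the contract, so only the linear term is removed);
* connectivity for clustering: 6 (faces) by default, the most conservative;
  18 and 26 are supported.

### Cluster-extent correction

Family-wise error over clusters is controlled at `fwe_alpha` = 0.05 by a
Monte Carlo null of the maximum cluster size. We considered circular
time-shift surrogates, but for a periodic block design a shared circular
shift realigns the regressor with itself for a large fraction of offsets
(the boxcar autocorrelation at lag 25 s is −0.67, at lag 50 s +1), so the
"null" reproduces the true activation and destroys genuine clusters. The
null used instead is the smooth-Gaussian-field approach standard in the
fMRI literature: estimate the residual spatial smoothness after regressing
out the task component (per-axis lag-1 neighbour correlation of the
residuals, inverted through the *discretized* Gaussian-kernel correlation so
that resimulation reproduces the measured correlation exactly); simulate
`n_null` (default 1000) white-noise fields smoothed to that smoothness,
masked like the data; threshold each at the two-sided Gaussian quantile of
`p_voxel`; record the maximum suprathreshold cluster size. The extent
threshold is the (1−α) empirical quantile (method "higher"), and observed
clusters survive only if strictly larger. Because cluster sizes are
integers the realized false-positive rate sits at or below α; on the
default 24×24×12 grid it measures ≈ 0.04.

## Network construction

Voxel networks use the full scan series (task + rest): the analysis is
deliberately task-conditioned — voxels are selected *because* they respond
to the task, and connectivity is interpreted given that selection. A link
joins two active voxels when |C_ij| ≥ θ; both intra- and inter-fROI links
are kept, links are binary, and the fraction of retained links with
negative correlation is reported (it is 0 in all bundled scenarios, and the
sign convention matters only if θ is lowered drastically).

θ has no canonical value; the library default is 0.6 and every group
comparison must use a single θ (output tables carry a configuration hash and
the CLI refuses to mix hashes). The bundled scenarios are θ-conditional by
design: 0.40 for the hierarchy-recovery study, 0.35 for the cohort
emulation (so that the weakest planted link is expressed in every subject
that carries it), 0.50 for the k-shell studies (so that the planted
periphery stays peripheral). Each value was chosen from the closed-form
correlation ladder of the generative model below, before freezing the
scenario.

fROIs are connected components of the active mask restricted to one
anatomical label. Components spanning two labels split; excluded labels
(visual cortex) are discarded entirely; active voxels with background label
are kept in a flagged "unlabeled" fROI so no active signal silently
disappears — they form their own module and never enter the named-structure
logic. The fROI weight is the number of cross voxel links divided by the
sum of the two fROI sizes; it is bounded by S_i·S_j/(S_i+S_j), attained
exactly at complete bipartite cross connectivity, and is verified against a
brute-force double loop in the tests. Region-scale graphs pool all fROIs of
one named region (sizes add, cross links add) so subjects can be matched by
region name at the group level.

## Common networks, structures, hierarchy

A link enters the group common network when present (W > 0) in at least
⌈τ·N⌉ subjects. The common weight is the mean of the subject weights over
the subjects where the link is present: averaging over carriers keeps the
common weight inside the range of the contributing weights for every τ,
and at τ = 1 it coincides with the mean over all subjects. τ defaults to 1
(strict consensus); the cohort scenario uses τ = 0.5 (majority), and every
report carries the per-link frequency so the choice is transparent.

Structure detection is role-based: a mapping from region names to the four
roles preSMA/BA/preMA/WA. The triangle requires all three links among
{preSMA, BA, preMA}; the V requires both WA–BA and WA–preMA. A subject
missing a role (region not active) counts the structure as absent. The
hierarchy ranks the five named links by common weight, descending; missing
links are listed last and flagged, and exact ties are flagged on every
member rather than silently ordered.

## k-shell analysis

Decomposition is the standard iterative pruning on the binarized voxel
network: repeatedly delete all nodes of degree ≤ k (cascading) to peel
shell k, for k = 0, 1, 2, …, on the whole (possibly disconnected) graph.
Isolated nodes land in shell 0. The implementation is checked against an
exhaustive k-core-membership oracle and against `networkx.core_number`.

Shell indices are normalized per subject by that subject's k_max so that
subjects with networks of different depth can be pooled; shell-0 nodes map
to 0 and are flagged, and an edgeless network (k_max = 0) is an error that
names the subject. Pooled nodes are binned into `n_bins` = 15 bins,
half-open [(b−1)/15, b/15) with the last bin closed at 1. Histograms are
normalized to fractions per (module, group) before SSE — group pools differ
in node count, so raw counts would make the SSE scale-dependent — and a
raw-count mode is exposed for sensitivity checks. A module with an empty
pool is reported as missing, never as a zero histogram, and SSE pairs
involving it are skipped and logged.

## The synthetic generator

Real scanner data cannot ship with the package, so every demonstration and
calibration runs on a generative model whose parameters are the study
conditions. Each voxel in region m follows

    x(t) = baseline + β_m s(t) + a_m η z_m(t) + Σ_n c_mn η' g_mn(t) + ε(t)

where s is the HRF-convolved boxcar, z_m a unit-variance Gaussian latent
shared by the region, g_mn a unit-variance latent shared by the coupled
region pair, ε white noise (SD `noise_sd` = 1), and η, η′ independent
unit-mean lognormal per-voxel loading factors with log-SD
`voxel_jitter_sd` = 0.6. The per-voxel heterogeneity is essential, not
cosmetic: with homogeneous loadings every cross pair of a region pair has
nearly the same correlation, thresholding produces all-or-nothing link
blocks, and no single θ can order several coupling strengths — whereas
real fROIs are heterogeneously coupled, which is exactly why empirical
fROI weights span two orders of magnitude. One further lognormal factor
per subject (log-SD `subject_jitter_sd` = 0.1) scales all amplitudes to
emulate inter-subject variability; its size is a stand-in, not an estimate,
since no quantitative description of that variability is available.
Background voxels receive baseline + noise only. Identical configuration
and seeds give bit-identical output; per-subject seeds derive
deterministically from the group seed, and dropout subjects consume the
same random stream as the others so that silencing a region in one subject
does not perturb the rest of the group.

Region dropout (a region functionally silent in a subject: task amplitude
and couplings zeroed, anatomical label retained) is the mechanism for
planting group-level structure frequencies — a region that never activates
cannot contribute links, which makes frequencies exact by construction.

### Scenario calibration

The bundled scenarios place 4×4×4-voxel cuboid regions on a 24×24×12 grid
of 4 mm voxels, separated by ≥ 6 voxels so smoothing cannot bridge them.
Task amplitudes β = 3 give voxel-level task correlations ≈ 0.35–0.55,
comfortably above the p < 0.001 detection threshold (r ≈ 0.26 at T = 160)
while leaving detection imperfect at region edges, as in real maps. The
hierarchy scenario plants couplings A..E = 2.66/1.77/1.18/0.79/0.53
(adjacent ratios 1.5); within-region amplitudes are 0.6 except WA's 1.549,
which tops WA's variance up so that the planted coupling order maps onto a
monotone inter-region correlation order (WA carries far less coupling
variance than the triangle regions, and correlations normalize by total
variance). The k-shell scenarios couple the triangle densely (1.5
pairwise) and WA weakly (0.4, or 1.2 vs 0.0 in the contrast study) with
WA's task amplitude reduced to 1.5 so that the task-driven correlation
floor does not pull WA into the core.

### What the generator does not emulate

No physiological noise (cardiac/respiratory), no head motion, no EPI
distortion, no anatomical variability in region geometry, and Gaussian
white temporal noise rather than the 1/f spectrum of real BOLD. Passing
tests therefore demonstrate that the chain recovers planted structure under
an idealized noise model — they do not certify performance on scanner data,
where preprocessing quality and the unknown true θ-sensitivity dominate.

## Problem sizes and runtime conventions

The test suite and the acceptance script run simulations at the scale the
statistics require rather than the largest scale the model supports:
10⁴ voxels for voxel-level calibration, 200 null replicates (n_null = 500)
for the FWE rate, 20 seeded runs of 8-subject groups for hierarchy
recovery, core/periphery occupancy and SSE discrimination, and n_null = 200
in the group scenarios (the 0.95 quantile of a max-statistic is stable well
below the library default of 1000). Full studies write every stage's output
before the next stage starts, and a manifest from which the run reproduces
bit-identically; floating-point tables use a fixed `%.10g` format for that
reason.

## Known limitations

* The cluster-extent null assumes stationary, approximately Gaussian
  spatial autocorrelation; heavy-tailed smoothness would make it
  anti-conservative (the classic failure mode of parametric cluster
  inference).
* Aggregating fROIs to named regions sums sizes and links; subjects whose
  activation splits a region into several components are treated as one
  region, which is the matching the group stage needs but loses
  within-region topology.
* θ-sensitivity is inherent to threshold-based network construction; all
  group results should be read as θ-conditional, and the configuration hash
  on every table is there to prevent accidental mixing.
* The SSE comparison has no sampling distribution attached; it is a
  descriptive distance between pooled histograms, as in the source analyses.
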