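# Methods

`dfnckit` implements a static and dynamic functional network connectivity
(FNC) analysis for independent-component time courses, together with a
synthetic cohort generator that plants known ground truth at every stage.
This note documents the models, the defaults and why they were chosen, the
numerical choices, and what the synthetic validation does and does not
demonstrate about real data.

## The analysis model

**Inputs.** Per subject: a T×C matrix of component time courses with
repetition time TR (seconds), six realignment parameters per volume, and a
cohort row (group ∈ {RRMS-F, RRMS-M, HC-F, HC-M}, site, age, mean framewise
displacement, structural covariates).

**Conditioning.** The chain is truncate → despike → detrend → low-pass →
(connectivity) → nuisance regression, recorded in an append-only provenance
list that downstream stages check. Despiking is robust MAD clipping: per
component, samples beyond `z_threshold` MADs from the median have their
excess deviation squashed through `tanh` (raw units, so any spike lands
within `z·MAD + 1` of the median); inliers are untouched, and a constant
series (MAD = 0) passes through. The low-pass filter is a fifth-order
Butterworth at 0.15 Hz applied forward–backward (`sosfiltfilt`), which
cancels phase and squares the one-pass magnitude response — tests compare
against |H(f)|² of the digital transfer function, since at 0.2 Hz (80 % of
Nyquist at TR = 2 s) the analog closed form is off by two orders of
magnitude. Framewise displacement is the 6-parameter backward-difference
sum with rotations converted to arc length at a 50 mm head radius;
`fd[0] = 0`. Motion QC excludes subjects with translation > 3 mm or
rotation > 3° (strict inequality, with a 1e-9 float guard so a subject at
exactly the limit is kept).

**Static FNC.** Pairwise Pearson correlation of the conditioned series,
Fisher z = atanh(r) with |r| clipped at 1 − 1e-7, zero diagonal.
Zero-variance components yield a zeroed row/column with a warning rather
than NaNs. Spatial-map statistics are one-sample t tests per voxel with
BH-FDR across voxels; the high-activation mask additionally requires
t > mean(t) + 4·SD(t) over tested voxels (the symmetric low tail is kept as
a separate mask), and an optional connected-component filter drops clusters
below 10 voxels (face adjacency by default; the neighborhood scheme is a
parameter because conventions differ).

**Dynamic FNC.** Windows of `width_tr` = 22 TRs (44 s) slide in steps of
1 TR (2 s); the weights are a rectangle convolved with a Gaussian of SD
3 TRs (6 s), truncated to the window and normalized. Per window the
taper-weighted covariance is standardized to correlation (partial
correlations are scale-invariant and the unit diagonal conditions the
solver) and passed to the graphical lasso; the precision matrix is
converted to partial correlations (−P_ij/√(P_ii P_jj)), Fisher-z
transformed, diagonal zeroed. The penalty λ is selected once per subject by
repeated two-window cross-validation: fit on a random window, score the
held-out Gaussian log-likelihood `logdet Θ − tr(S_test Θ)` on the *adjacent*
disjoint window (adjacent, because with nonstationary connectivity an
arbitrary test window is often in a different state, which biases the
selection toward total shrinkage), repeated `cv_repeats` = 10 times over a
grid of 8 points log-spaced on [0.01, 0.25]. The grid is capped at 0.25: a
22-volume window has an effective sample size near 11 after tapering and
low-pass autocorrelation, so held-out likelihood keeps improving toward the
diagonal solution, and λ ≥ 0.3 zeroes entire window matrices — at that
point all states collapse and the windowed analysis is meaningless. The
capped grid spans the range practitioners report for this estimator on
component time courses.

**States.** All subjects' windows are pooled (no exemplar pre-selection)
as vectorized upper triangles and clustered by k-means under the Manhattan
(L1) metric: assignment by city-block distance, centroid update by
coordinate-wise median (the exact L1 minimizer, so the objective is
monotone nonincreasing), k-means++-style initialization, best of 5
replicates, at most 150 iterations; an emptied cluster is re-seeded at the
farthest sample. States are relabeled by descending pooled frequency, so
State 1 is always the most frequent. Model order uses the elbow criterion
on a cluster-validity curve, validity(k) = mean within-cluster distance /
mean between-centroid distance, selecting the k of maximum curvature
(largest second-order difference); a flat or degenerate curve falls back to
the smallest candidate with a warning.

**Temporal properties.** Per subject and state: fraction time (share of
windows in the state), mean dwell time (mean run length of consecutive
windows × step seconds; 0 s for a state never entered), and the transition
count (adjacent unequal window pairs). State-entry percentage is the share
of a group's subjects with at least one window in the state.

**Statistics.** Univariate outcomes (sFNC entries, per-state mean dFNC
entries, map values, temporal metrics) are regressed on age, mean FD and
site dummies (optionally gray-matter volume); an omnibus one-way F over the
four groups is followed by pairwise Welch t tests for the four enumerated
contrasts (HC-F vs HC-M, RRMS-F vs HC-F, RRMS-M vs HC-M, RRMS-F vs RRMS-M),
with BH-FDR applied across the outcome family within each contrast at
α = 0.05. Temporal metrics are compared with Mann–Whitney U (exact
enumeration when both n ≤ 8 without cross-group tie failure, tie-corrected
normal approximation otherwise) at α = 0.01. ROC analysis reports the
rank-formula AUC, which equals U/(n₁n₂) exactly, with a percentile
bootstrap CI. Partial Spearman correlation rank-transforms both variables,
residualizes on the controls, and takes a Pearson correlation of residuals
with a t approximation at n − 2 − #controls degrees of freedom; with no
controls it reduces to plain Spearman exactly.

**Group ICA (optional front end).** Two-stage PCA reduction (subject 30,
group 20 by default; both configurable) with whitening operators retained;
Infomax ICA with logistic nonlinearity and natural-gradient updates, the
learning rate annealed whenever the gradient direction reverses;
ICASSO-style stability over reseeded runs (components pooled, clustered by
average linkage on 1 − |corr|, stability = within- minus between-cluster
mean similarity, centrotype returned); GICA3 back-reconstruction, under
which the mean of subject maps reproduces the group maps exactly (an
algebraic identity of the partitioned reduction operators). "100
iterations" of the stability analysis is kept as the configurable run
count, with 10 as the desk-scale default. Components are matched to
reference maps by optimal bipartite assignment on |correlation| with sign
alignment.

## The synthetic generator

The generator is the package's instrument for validation, so its defaults
are study conditions, fixed once:

- **Cohort**: four groups sized 135/73/123/105 with Gaussian age, mean FD,
  GMV, WMV and BPF per group, log-normal lesion volume and disease duration
  matched to the printed median and IQR on the log scale (an asymmetric
  printed IQR cannot be matched exactly by any log-normal; the median and
  the q3/q1 ratio are preserved), and EDSS as a log-normal draw rounded to
  the ordinal half-point scale. Six sites, uniform by default. Nonphysical
  draws (FD < 0, BPF outside (0, 1]) are clipped; BPF clipping is an
  explicit config flag.
- **States**: three planted connectivity regimes specified by their
  partial-correlation structure — the scale the windowed estimator measures —
  and converted to sampling covariances by precision inversion with
  spectrum clipping (dense strong partial correlations are mathematically
  infeasible, so overambitious patterns shrink rather than fail). State 1
  is near-empty (sparse), State 2 couples component pairs strongly (a
  matching graph; moderate overall connectivity), State 3 has dense block
  structure (the most connected state marginally). Mean absolute marginal
  correlation is ordered sparse < middle < high.
- **Switching**: a first-order Markov chain per subject,
  `P = (1−e)·I + e·1πᵀ`, which has stationary distribution π and geometric
  dwell with mean 1/(e(1−π_s)) steps. The default switch rate e = 0.015/TR
  gives dominant-state runs of minutes. This is deliberate: window-level
  state recovery is only defined when runs are long relative to the 44 s
  window, and the near-total single-state dominance reported for this kind
  of cohort (fraction times of 71–85 %, many subjects never entering other
  states) points to the slow regime. Occupancy defaults: healthy females
  (0.10, 0.80, 0.10) — concentrated in State 2; the other three groups
  ≈ (0.70–0.75, 0.15, 0.10–0.15) — concentrated in State 1.
- **Group effects**: female patients differ from female controls by the
  occupancy shift above; male patients additionally carry a −0.3
  correlation-scale offset on the block-0/block-1 between-network pairs,
  applied to each state covariance and projected back to SPD. The size was
  chosen so the effect is detectable at the desk-scale cohorts the package
  runs by default (n ≈ 10–12/group, where between-subject occupancy
  variability puts per-pair sFNC SD near 0.2 z); real clinical effects are
  smaller but also come with an order of magnitude more subjects.
- **Noise**: white observation noise (SD 0.15) and a slow polynomial +
  cosine drift (amplitude 0.2) that the detrend/filter stages must remove.
  Motion is a Gaussian random walk on six parameters whose increment scale
  is solved in closed form from E|N(0, s²)| = s√(2/π) so realized mean FD
  matches the per-group targets in expectation; scan length defaults to
  240 volumes (8 min at TR 2 s).

**Ground-truth window labels.** A window is a taper-weighted mixture of
the volumes it covers, so the planted label of a window is defined as the
state holding the largest total taper weight in its span. Recovery scores
(adjusted Rand index) compare k-means assignments against these labels.

## What the validation shows — and what it does not

Passing recovery tests show that the estimator chain is implemented
correctly and can recover structure *of the planted kind*: Gaussian
state-conditional signals, Markov switching slower than the window,
partial-correlation-distinct states, linear mixing, additive offsets. They
do not show that real resting-state fMRI satisfies those conditions. In
particular: real dwell times may be comparable to or shorter than the
window, in which case windowed clustering mixes states by construction;
real components are not Gaussian; hemodynamic convolution, scanner
artifacts and spatially correlated noise are not emulated; and site effects
enter only through covariate distributions, not through scanner-specific
signal structure. The type-I control result holds for Gaussian outcomes
with the modeled covariates; heavy-tailed outcomes would need the
Mann–Whitney path.

## Numerical choices

- Fisher z clips |r| at 1 − 1e-7, keeping duplicated series finite
  (z ≈ 8.4) rather than infinite.
- Window covariances are repaired by ridge jitter when an eigenvalue falls
  below 1e-8 (logged); the graphical lasso runs at tol 5e-3 / 100
  iterations with escalating jitter retries, and a pathological window
  falls back to a ridge-regularized inverse. λ = 0 bypasses the lasso and
  uses the pseudoinverse directly.
- k-means ties and empty clusters: stable argmin assignment; an empty
  cluster is re-seeded at the farthest sample.
- Degenerate inputs: constant series pass despiking unchanged; zero-variance
  components produce zeroed connectivity rows with a warning; identical
  samples make the elbow fall back to the smallest candidate k; all-equal
  two-sample data gives U = n₁n₂/2, p = 1.
- The single pipeline seed fans out to per-stage child seeds through
  `numpy.random.SeedSequence.spawn`, so toggling one stage does not change
  another stage's draws.
- Derived quantities (window/taper durations in seconds, Nyquist limits,
  window counts) are recomputed from primitives at validation and never
  stored.

## Problem sizes

Default desk-scale runs use 8–12 subjects per group, C = 8–10 components,
T = 200–240 volumes, chosen so a full pipeline run completes in tens of
seconds and the whole validation suite in minutes on one CPU. Recovery
checks use 20 seeded cohorts (10 in the reproduction script). The
end-to-end sign check scores the planted occupancy shift on the State 1
fraction-time comparison and the planted strength reduction across both
connectivity test families — static FNC and state-conditioned dFNC — since
the offset sits on every state covariance and the state-conditioned tests
are free of occupancy-mixture noise. Occupancy
convergence is checked on 50 subjects per group with 1200-volume chains,
since the time-average occupancy of a slowly switching chain concentrates
only over scans much longer than its dwell times. The sensitivity harness
re-runs the dynamic stage over the window-width × cluster-count grid
(22/30 TRs × k = 3/4) and tabulates the sign of every group difference.

## Known limitations

- The nuisance-regression contract ("six realignment parameters regressed
  on the connectivity matrix per subject") is ambiguous at the static
  level, where each subject has one matrix; the package offers a config
  switch: per-subject motion summaries regressed across subjects (static),
  per-window taper-weighted parameter means regressed across windows
  (dynamic), both, or off.
- The elbow criterion is formalized as maximum curvature of the
  within/between validity ratio; other formalizations (distortion jumps,
  gap statistic) can select differently on shallow curves.
- Per-subject λ selection can place different subjects at different
  shrinkage levels, which displaces all of a subject's windows coherently
  in state space; a shared-λ mode is available by passing a single-point
  grid.
- ICASSO stability indices above ~0.9 indicate reliable components, but
  the absolute value depends on the run count and clustering linkage.
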