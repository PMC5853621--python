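# Methods

This note documents the models, numerical choices and known limitations of
`netreconf`: what each stage computes, why the defaults are what they are,
and what the synthetic-data validation does and does not establish about
real data.

## Synthetic cohort model

The generator (`netreconf.synth`) emulates the statistical structure the
analysis assumes, not fMRI physics. Each run is a T×N matrix built from a
latent-factor model: ROI *i* in community *c* is

    x_i(t) = a·f_c(t) + b·g(t) + s·ε_i(t)

with a per-community factor f_c, a global factor g and node noise ε, all
unit-variance white Gaussian. Given target within- and between-community
correlations (w, v) and noise scale s, the loadings are solved exactly
(b² = v·V, a² = (w−v)·V, V = s²/(1−w)), so the *population* correlation is w
within and v between communities regardless of s. On top of this sit:

- a task signal: a 20 s-on/20 s-off boxcar convolved with the canonical
  double-gamma haemodynamic response (peak 6 s, undershoot 16 s, ratio 1:6),
  peak-normalised and added with amplitude `task_amplitude` to the
  ground-truth activated ROIs of task runs. The 20 s block length puts the
  task fundamental near 0.025 Hz, inside the analysis band, so filtering
  preserves it;
- low-frequency drift: cosines at 0.002/0.003/0.004 Hz — at least an octave
  below the 0.009 Hz band edge, so the band-pass stage demonstrably removes
  them;
- nuisance structure: six AR(1) motion-like series plus two tissue-mean-like
  series per run, leaking weakly (loading sd 0.1) into every ROI so confound
  regression has a real effect to remove.

### Study conditions (defaults) and why

| parameter | default | rationale |
|---|---|---|
| n_subjects | 20 | desk-scale cohort; validation suites use 30–40 |
| n_roi / n_subnetworks | 60 / 6 | scaled-down whole-brain parcellation; 10-node subnetworks keep within-community pair counts comparable to the 15% edge budget |
| n_timepoints / tr | 400 / 0.72 s | typical task-run length and repetition time for multiband acquisitions |
| within/between corr, rest | 0.60 / 0.02 | strongly segregated rest state: communities near-disconnect after thresholding |
| within/between corr, task | 0.65 / 0.30 | task state both more internally coherent and far more globally integrated |
| act_fraction | 0.3 | activated set covers roughly two subnetworks |
| task_amplitude / noise_sd | 2.0 / 1.0 | moderate single-subject effect (amplitude/noise = 2) |
| corr_jitter | 0.12 | inter-individual integration trait (below) |

The rest/task correlation levels deserve explanation, because at a *fixed*
edge density the link between correlation structure and binary-graph
efficiency is not monotone. Proportional thresholding keeps the top
k = ⌊density·N(N−1)/2⌋ edges by rank, so uniformly scaling all correlations
changes nothing; what matters is the *composition* of the retained edge set.
A strongly segregated state (large within/between gap relative to the
sampling noise of the correlation estimates) yields near-clique communities
with few bridges — long paths, low efficiency. A state whose
between-community correlation approaches the within level yields a
well-mixed edge set — short paths, high efficiency — and a lower optimal
modularity Q. The defaults therefore plant rest as segregated (0.60/0.02)
and task as integrated (0.65/0.30): the task state has *both* a higher
within-community correlation and a much higher between-community
correlation, producing the empirically observed rest→task signature
(efficiency up, modularity down) as a genuine property of the planted
covariance, not of the estimator. Note that temporal band-pass filtering
reduces the effective degrees of freedom of the correlation estimates by
roughly the retained bandwidth fraction (~10% here), which is why
correlation contrasts must be large at these run lengths to survive
thresholding.

`corr_jitter` implements a latent integration trait: per subject and state,
u ~ U(−1, 1) shifts the between-community target by +jitter·u and the
within-community target by −jitter·u/2. Subjects therefore differ stably in
how integrated their networks are, which makes per-subject changes in
global efficiency and in Act/L-Act interaction strength genuinely
correlated — the coupling the group-level partial-correlation analysis is
designed to detect. Activated ROIs are drawn community-by-community (task
activation concentrates in task-relevant subnetworks), so Act↔L-Act edges
are dominated by between-community pairs and interaction strength tracks
integration.

### What the generator does not emulate

Volumetric imaging, physiological noise, motion artifacts and their spatial
structure, haemodynamic variability across regions, non-Gaussian BOLD
statistics, task-design variety (a single regressor per task), and any
empirically calibrated effect size. Passing the validation suite shows the
*pipeline* is correct and well-calibrated and can recover planted structure
of realistic magnitude; it does not certify effect sizes or directions in
any real dataset.

## Preprocessing

Order contract: band-pass → confound regression → (task runs) task-activity
regression. Filtering first avoids reintroducing stop-band confound energy.
The filter is a 2nd-order Butterworth band-pass (0.009–0.08 Hz) applied
forward–backward (`sosfiltfilt`), i.e. zero-phase with doubled effective
order: pass-band sinusoids retain ≥ 94% amplitude, signals an octave beyond
the high cut retain ≤ 4%. Confound regression is OLS on
[intercept | confounds | backward differences (first row zero-padded)];
linearly dependent columns are dropped with a warning. Two details matter
for correctness and are enforced:

- the task regressor is band-pass filtered with the *same* filter as the
  data before regression, so the regression removes exactly the task
  component present in the filtered data;
- the filtered regressor is residualised against the confound design before
  the task regression (Frisch–Waugh), making the sequential regressions
  equivalent to one joint regression. Without this, a residual shared task
  component survives in activated ROIs and corrupts their connectivity.

No spatial smoothing and no global-signal regression are performed anywhere.

## Activation detection

Subject level: per ROI, OLS of the filtered series on
[intercept | filtered regressor] per run; the effect is the run-averaged
slope, its variance the averaged slope variance, degrees of freedom pooled
across runs; t→z conversion matches upper-tail probabilities (symmetric on
the half-line, clipped at |z| = 40 where the normal inverse saturates).
Group level: one-sample t over subjects' z scores per ROI, converted to z
and thresholded at z > 2.32, positive direction only. The subject-level
threshold 1.96 is kept as a reporting convention. This is an ROI-level
stand-in for voxelwise cluster-corrected GLMs: with one value per ROI there
are no clusters to correct over, so a plain z threshold at the conventional
group value is the appropriate analogue. Act and its complement L-Act always
partition the ROI set.

## Connectivity networks

Pearson correlation → Fisher z (|r| clipped to 1−1e−12 so perfect
correlations stay finite) → entrywise mean of the LR and RL networks →
negatives set to zero → proportional threshold at ⌊density·N(N−1)/2⌋ edges,
binarised. Averaging is done on raw Fisher-z values *before* negative
zeroing (zeroing first would bias the average upward; the z-scale is where
averaging is linear). Ties at the density cutoff are broken
deterministically: weight descending, then node-pair lexicographic order —
this makes edge sets nested across densities and runs bit-reproducible. If
fewer positive weights exist than requested edges, only positive-weight
edges are kept and the achieved density is logged.

## Graph statistics

- Shortest paths: BFS/Dijkstra on the binary adjacency
  (scipy.sparse.csgraph); the test suite cross-checks against an independent
  Floyd–Warshall implementation.
- Efficiency: unreachable pairs contribute 0 (Latora–Marchiori convention),
  so efficiency is defined on disconnected graphs; areal efficiency is
  computed on the region-induced subgraph — paths may not leave the region.
- Participation coefficient: the standard 1 − Σ_m (k_im/k_i)² over
  subnetwork modules on the binary network; isolated nodes are assigned
  PC = 0 rather than NaN so node vectors stay total (logged).
- Interaction strength depends only on cross-region entries; permuting
  intra-region edges leaves it invariant (tested).
- Subnetwork flexibility averages node flexibility within each *included*
  subnetwork; excluded subnetworks (a configurable set, mirroring the
  convention of dropping subnetworks without established functional roles)
  are omitted.

## Modularity family

Q uses the Newman–Girvan form with a multiplicative resolution parameter,
Q = (1/2w) Σ_ij [A_ij − γ·w_i w_j/(2w)] δ(g_i,g_j), summed over ordered
pairs including i = j (the degree-null term of a node with itself belongs to
its community). Optimisation is Louvain (networkx, seeded) with randomised
restarts; the restart with maximal Q — evaluated by this package's own Q
implementation — is kept, ties going to the first. γ = 1 and 100 restarts
are the defaults.

Fractional modularity Q_f restricts the Q summation to node pairs engaging
a region: *both* nodes in the region, or *at least one*. The summand keeps
the degree-null term for every eligible pair even where A_ij = 0; this makes
Q_f an exact decomposition — Q_f(region, at-least-one) +
Q_f(complement, both) = Q to machine precision — which is what lets the Act
and L-Act contributions to global modularity be compared on one scale.
Normalisations: none, per eligible pair (C(k,2)), or per eligible node (k),
where k is the region size under the both rule and N under the
at-least-one rule.

The z-Rand partition similarity uses the pair-counting statistic w (pairs
co-classified in both partitions) centred and scaled by its *exact*
mean and variance under the permutation null that relabels one partition
uniformly at random with group sizes fixed. The variance is derived from
pair-of-pairs combinatorics (shared-node pairs need three co-grouped nodes;
disjoint pairs need two independent co-grouped pairs) and was verified by
Monte-Carlo relabeling: the resulting z is mean 0, sd 1 under the null to
within simulation error. Degenerate cases (N < 4, single-group partitions)
raise rather than return an arbitrary value.

Representative (consensus) partitions: the module-allegiance matrix (co-
classification frequency across subjects) is thresholded at the 95th
percentile of a pooled permutation null (1000 group-size-preserving
relabelings of each subject's partition), then clustered with the same
best-of-restarts Louvain on the thresholded weighted matrix. If all input
partitions are identical the consensus is returned directly.

## Group statistics

Paired t (two-sided), sign-flipping permutation test of the mean paired
difference with the add-one correction p = (1 + #{|null| ≥ |obs|})/(1 + B)
(default B = 10,000, so the smallest attainable p is 1/10,001), and a
composite normality check (Lilliefors-calibrated KS with estimated
parameters). FDR correction defaults to Benjamini–Hochberg; Storey q-values
(fixed-λ = 0.5 π₀ estimate) are available because some common toolchains
default to them. The two-way repeated-measures ANOVA on the
[subjects×states] × [region class] design is computed from closed-form
balanced sums of squares (cross-checked against statsmodels' `anova_lm` in
the tests) and reports the region-class main effect and the block×class
interaction. Adjusted correlations are Pearson correlations of OLS residuals
on [intercept | sex | age] with n−2−C degrees of freedom; a variable fully
explained by the confounds yields r = 0, p = 1 by convention.

Type-I error of all three tests is verified by null simulation
(2000 replicates each) to lie within 0.05 ± 0.015.

## Problem sizes used in the validation suites

The test and acceptance workloads run on scaled-down cohorts chosen as the
package's own validation conditions: 40 subjects × 60 ROIs × 400 frames ×
two encodings for end-to-end recovery (20 cohort seeds), 30 subjects for
activation-mask recovery, 4×15-node planted-partition graphs (100 seeds)
for community detection, random graphs up to n = 50 for the oracle checks,
and a 5-subject pipeline for bit-identical determinism across two complete
runs.

## Known limitations

- Binary networks only; weighted variants of efficiency/PC/Q are out of
  scope.
- One regressor per task; no contrast menus, no voxel-level GLM, no
  mixed-effects (FLAME-style) group model, no cluster-based correction.
- The representative-partition null (group-size-preserving relabeling,
  pooled 95th percentile) is one reasonable choice among several published
  consensus procedures; its parameters are configurable.
- The Storey π₀ estimate uses a single fixed λ, not the smoother-based
  estimate of the original procedure.
- Efficiency comparisons are meaningful only at matched density; the
  package never compares efficiencies across different densities.
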