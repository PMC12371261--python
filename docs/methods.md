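# Methods

`guildflow` implements a guild-level, time-series analysis of longitudinal
gut-microbiome dietary-fiber intervention studies: daily stool sampling over
a 28-day window (habitual diet days 0–13, low-dose fiber days 14–20,
high-dose days 21–27), with paired fecal metabolomics and continuous glucose
monitoring (CGM). This note documents the models, the defaults and why they
were chosen, the synthetic-data generator the test-suite relies on, and the
numerical choices that matter.

## Compositional correlation networks (per participant)

Relative abundances are compositional, so taxon–taxon Pearson correlations
are distorted by closure. We use the SparCC model: with basis variances
ω_i² and basis correlations ρ_ij, the observable pairwise log-ratio
variances satisfy

    t_ij = Var log(x_i/x_j) = ω_i² + ω_j² − 2 ρ_ij ω_i ω_j.

Under a sparsity assumption (Σ_j ρ_ij ω_i ω_j ≈ 0) the t-row sums give a
linear system for ω_i², from which ρ_ij follows. Pairs with |ρ| above an
exclusion threshold (default 0.1) violate sparsity and are iteratively
removed from the system and the system re-solved (up to 10 rounds, stopping
early if a taxon would be left with fewer than two partners). Uncertainty
about the underlying fractions is propagated by resampling fractions from a
Dirichlet posterior (+1 pseudocount over a configurable depth of 10,000,
since the input is relative abundances rather than counts) for 50 inner
iterations; the estimate is the entrywise median. ω² is floored at 1e-10
before square roots.

Two-sided significance per pair comes from permutations that shuffle every
taxon's samples independently, with the add-one estimator
p = (1 + #{|ρ_perm| ≥ |ρ_obs|}) / (n_perm + 1) (default 1000 permutations,
so the smallest attainable p is 1/1001). Each permutation replicate solves
the basis system in a single vectorised pass without posterior resampling
or exclusion rounds: the replicate only has to reproduce the *null*
sampling variability of the estimator, and the single-pass null makes a
200-taxon, 20-participant screen feasible on one CPU. Taxa are first
filtered for prevalence: a taxon is kept for a participant only if it is
non-zero in strictly more than 45% of that participant's samples.

Known limitation: at n samples the estimator's per-pair sampling noise is
~1/√n regardless of implementation, so with a few hundred samples null
pairs routinely reach |ρ| ≈ 0.15–0.2. Edge calling therefore relies on the
permutation p-values, not on a magnitude cut-off.

## Consensus networks and guild (CAG) partitioning

Within each participant group, an edge enters the consensus network only
if at least `min_support` participants (default 6) carry a significant
(p ≤ 0.05, boundary inclusive) edge for that pair *with the same sign*;
the sign-consistency requirement is configurable because the source
protocol's wording admits both readings. The consensus weight is the mean
correlation over exactly the supporting participants.

Taxa are clustered on the distance 1 − mean ρ (pairs with no consensus
edge get the maximal distance 1, since Ward linkage needs a complete
matrix) with Ward.D2 linkage. The tree is descended top-down; each binary
split is tested with a free-permutation PERMANOVA of the two child labels
on the sub-distance matrix (default 9999 permutations, accept at
p < 0.001). When the number of distinct label arrangements is ≤ 20,000 the
arrangement set is enumerated and the p-value is exact — Monte-Carlo
p-values cannot resolve below ~1/1000 for small splits, which would make
small guilds undetectable at α = 0.001. A significant child smaller than
the minimum guild size (default 5) can never form a guild: it is peeled
off (its taxa end up unassigned) and the descent continues in the larger
child; without this rule one small outlier cluster near the root would
block all partitioning. Terminal clusters below the minimum size are
labelled unassigned and excluded from trajectory analysis rather than
force-merged, to avoid diluting guild signal.

CAG abundance is the exact member sum of relative abundances per sample.
Functional profiles divide a CAG's summed CAZy (or transport-KO) counts
per substrate by the CAG's total CAZy (KO) count; a CAG with zero total is
reported missing, not zero. Category comparisons use two-sided
Mann–Whitney U per substrate plus Kruskal–Wallis with Dunn's post hoc
(tie-corrected z statistics, BH-adjusted).

## Daily trajectories and differential abundance

Per CAG we fit the linear mixed model

    log(abundance + pseudocount) ~ day (categorical) + (1 | participant)

by REML (statsmodels MixedLM with its default optimizer; L-BFGS was
observed to return wrong fixed effects without reporting failure when the
random-intercept variance is on the zero boundary). Two codings are used:
for the intervention-window analysis all habitual-diet days share the
reference level, so the intercept is the habitual-phase mean and the
trajectory is T(d) = intercept + β_d with a Wald p per day; for the
28-day series consumed by the association screen, every day is a level
with day 0 as reference. The pseudocount defaults to half the smallest
non-zero value of the series (scale-aware) and to zero when the series has
no zeros. With balanced data and zero participant variance the fit reduces
exactly to per-day means. Non-convergence falls back to fixed-effect
per-day means with a warning.

Differential abundance is "LinDA-like": the same LMM with a phase (or
endpoint day-pair) fixed effect — the whole-intervention contrast adds a
crossed random day intercept — followed by an optional compositional bias
correction that recenters the per-CAG effect estimates on their
kernel-density mode (disabled below 3 CAGs), Wald p-values and BH
step-up q-values, with increase/decrease calls at q < 0.05. A zero-effect,
zero-variance degenerate series gets p = 1 by convention.

## Temporal-pattern clustering (DTW)

Trajectories are expressed relative to the habitual-phase mean (so clusters
capture response shape, not abundance level) and compared by classic
dynamic time warping: local cost |a − b|, symmetric step pattern with the
diagonal counted twice (the starting cell carries weight one, matching the
R `dtw` symmetric2 convention), no window. Ward.D2 on the DTW matrix; the
number of clusters maximises the mean silhouette width over k = 2…8 (ties
to the smaller k; a constant distance matrix yields a single cluster).
Silhouette-based selection merges super-clusters when between-archetype
separations are very unbalanced; at the generator's default noise the six
planted archetypes are recovered exactly, and at several-fold higher noise
the increase/decrease super-clusters win — a property of the criterion,
not of the distance.

## Change-point detection

For single series (daily glycemic-variability or diversity traces) we scan
all interior split points with a t-standardised CUSUM: the difference of
segment means scaled by √(k(n−k)/n) and divided by the pooled
within-segment standard deviation. Significance comes from shuffling the
series (999 permutations, add-one p). A circular-shift null is available
for strongly autocorrelated series; note it has only n − 1 distinct
rotations, so its attainable p is coarse (≥ ~1/n) and its power against a
clean step is intrinsically limited, which is why exchangeability is the
default for the near-iid daily residuals this scan is applied to.
Constant series return no change-point and p = 1.

## Delay-limited local similarity analysis (LSA)

Series are rank-normalised to normal quantiles, Φ⁻¹(r_i/(n+1)) with
average ranks for ties ("percentileZ"). The local similarity score is the
maximal zero-clamped contiguous sum of lagged products x_i·y_{i+d} over
all lags |d| ≤ 3 (the DP over the banded alignment grid reduces to a
Kadane scan per diagonal), divided by n; the sign records whether the
positive or negative accumulator won, and a positive delay means the guild
series precedes the metabolite. Ties break toward the smaller |delay|.

Significance: the default is the exact conditional permutation null — one
series is shuffled (9999 shared permutation index sets per screen,
vectorised across permutations), keeping the null conditional on the other
series' ordering, which matters because the screened series are smooth.
A theoretical mode approximates the null tail via the limiting
distribution of the scaled statistic: under the null √n·score/σ̂ (with
σ̂² the product of the two series' second moments) converges to the range
R of a Brownian motion on [0,1], whose tail is
P(R > r) = 8 Σ_{k≥1} (−1)^{k−1} k Φ̄(kr), and the 2·max_delay + 1
diagonals are treated as asymptotically independent. This asymptotic is
conservative at n = 28 (measured null rejection ≈ 0.01 at nominal 0.05),
so it is offered for large-n use and validated against the permutation
reference by rank correlation rather than trusted for calibration.

The screen scores every guild × metabolite pair on the LMM-estimated
28-day population series, applies BH across the full pair set and retains
hits at q < 0.05, annotating direction from the delay sign.

## CGM metrics

Per participant-day (96 expected readings at 15-min cadence; days under
70% coverage are dropped, as are user-specified exclusion days such as
sensor changes): MBG; SD overall and split at 06:00/22:00 into day/night;
TIR/TAR/TBR as the percentage of readings in [70, 180], > 180 and < 70
mg/dL — the below-range boundary is taken at 70 so the three percentages
partition to exactly 100; % readings < 180; MAGE (turning points from a
9-point moving-average-smoothed series, amplitudes read off the raw
readings, averaging excursions in the direction of the first amplitude
exceeding one within-day SD); CONGA-1h (SD of differences between readings
one hour apart, nearest match within ±5 min); J index 0.001·(MBG+SD)²;
LBGI/HBGI from the symmetrizing transform f(g) = 1.509((ln g)^1.084 −
5.381) with risk 10f² averaged over the low/high sides; LAGE = max − min;
CV; eA1C = (MBG+46.7)/28.7; GMI = 3.31 + 0.02392·MBG.

Phase summaries follow the trial's scheme: per-participant phase means,
one-way ANCOVA between groups on intervention means adjusted for the
habitual-phase mean, and one-tailed Wilcoxon signed-rank within groups.

## Multi-omics integration

* **PERMANOVA** partitions squared Bray–Curtis (or Euclidean) distances;
  with strata, labels permute only within participants (audited by tests).
  Add-one p, 999 permutations by default.
* **Adjusted PCoA** Gower-centers G = −½·J·D²·J, projects the participant
  hat matrix out on both sides, and eigendecomposes; coordinates come from
  positive eigenpairs. Without a covariate this is classical PCoA (equal
  to PCA scores for Euclidean distances up to sign).
* **Procrustes** uses the scipy disparity m² with a protest-style
  row-permutation p.
* **rmcorr** centers x and y within participants; r_rm is the signed root
  of SS_x/(SS_x+SS_err) with df = N − k − 1 (reducing to Pearson for one
  participant).
* **Mediation** fits M ~ T + (1|participant) and Y ~ T + M +
  (1|participant) by REML, then draws (a) and (b, c′) from their
  asymptotic normals (the outcome pair jointly with its estimated
  covariance); ACME, ADE and total are draw means, so total = ACME + ADE
  holds exactly; the ACME p-value and percentile CI come from the draws
  (quasi-Bayesian, 1000 draws). Pairs enter mediation only after an
  rmcorr + BH screening gate at q < 0.05, applied per family of pairwise
  links.

## Synthetic-data generator

The generator emulates the *derived* tables of such a study, never raw
reads. Abundances: 2 groups × 10 participants × 28 days × 200 taxa in 20
guilds by default. Log-basis model per taxon: baseline (SD 1.0 across
taxa) + participant offset (SD 0.5) + the guild's archetype curve +
σ·(√ρ_w·guild factor + √(1−ρ_w)·idiosyncratic) with σ = 0.7 and within-
guild correlation target ρ_w = 0.7; rows are closed to the simplex
(optionally multinomially resampled at a given depth). Archetype curves
are piecewise-linear in log space with onset at day 14: sustained increase
(ramp to +1.5 by day 17), transient increase (peak +1.5 at day 20, back to
0 by 27), late increase (ramp days 21–27), rapid decline (−1.5 by day 16),
late decline, stable; amplitude 1.5 natural-log units ≈ 4.5-fold, a
moderate-to-strong response for fiber-reactive taxa.

Metabolites: 20 by default, five of them lag-coupled to guilds (delays
0–3 days, both signs, effect 1.0 on the per-participant z-scale, noise SD
1.0, exponentiated to stay positive); the coupling is undefined for the
first `delay` days, which carry noise only — clamping them to the day-0
value was observed to bias recovered delays downward. Glucose traces:
per-participant baseline ~N(110, 10) mg/dL, three Gaussian meal
excursions (amplitude ~55 mg/dL, width 50 min) and AR(1) noise (φ = 0.6,
σ = 6); from day 14 the excursion amplitude is multiplied by
1 − intervention_effect (default 0.35), lowering within-day variability
without moving the baseline. Annotations: Poisson counts per CAZy
substrate / KO transport group, with fiber substrates and PTS transporters
enriched 3× in increase-archetype guilds and pectin/galactitol in decline
guilds. A separate mediation panel generator plants a
treatment → serum-mediator → glycemic-outcome path (a = 1.0, b = 0.5,
direct effect 0.3, participant random intercepts and residuals SD 0.5)
and records the planted coefficients in the ground truth.

What the generator does *not* emulate: taxonomic identity and phylogeny,
read-count sparsity and zero inflation, metabolite chemistry and
cross-metabolite correlation, meal timing variability, sensor dropout and
drift. Passing recovery tests therefore demonstrates that the estimators
invert the generative model they target at realistic noise — not that
real data satisfy that model.

## Problem sizes used by the validation suite

Recovery and calibration runs are sized to a desk-scale study: one group
of 10 participants, 200 taxa / 20 guilds, 20 metabolites; 10–20 seeds per
benchmark; 250 network permutations inside the guild-recovery chain (the
module default stays at 1000, whose p-floor is checked separately); 9999
partition permutations; 1000 null simulations per calibration check. The
original study's scale (~1100 genomes, ~1200 metabolites, 19 participants)
is reachable by the same code paths but is not what the shipped tests run.

## Known limitations

* SparCC permutation replicates use the single-pass null (see above);
  bootstrap confidence intervals for ρ are not provided.
* The theoretical LSA tail is conservative for short series; use the
  permutation default at n ≈ 28.
* Silhouette-chosen k can merge unbalanced archetype families at high
  noise.
* Mediation assumes sequential ignorability; no sensitivity analysis is
  provided.
* The trajectory LMM treats days as exchangeable levels; no smoothing or
  autocorrelation structure is imposed.
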