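# Methods

## The inferential problem

Binned ¹H-NMR serum spectra yield tens of correlated, skewed relative
intensities per sample, and case-control contrasts for sole-lesion outcomes
are weak. Ranking variables by a single selector's output on a single data
draw invites false positives; the pipeline therefore treats *selection
stability under resampling*, triangulated across three unrelated selectors
and judged against permutation-derived chance thresholds, as the unit of
inference.

## Preprocessing model

Bin integrals are non-negative signal plus baseline noise; a non-positive
integral is evidence of a near-zero concentration, so it is replaced by
one-fifth of the bin's minimum positive value — small, positive, and
bin-specific. Total-intensity normalization (each row divided by its sum)
removes per-sample technical scale; the resulting relative intensities are
dimensionless and sum to one. Autoscaling (column mean 0, sample SD 1,
ddof = 1) is applied where a method requires it, and always recomputed inside
each CV fold or bootstrap resample from that resample's training data only —
the leakage-free default.

Representative-bin selection reduces redundancy in three stages: one bin per
annotated metabolite (the bin with the highest mean Pearson correlation to
its siblings; ties to the lowest ppm boundary); unlabeled bins with |r| ≥ 0.9
to a kept labeled bin are dropped; the remaining unlabeled bins are clustered
by complete linkage on Euclidean distances between standardized bin profiles.
The dendrogram is cut at the **largest** number of clusters whose maximum
between-cluster |r| stays below 0.9: any coarser cut merges uncorrelated
bins, any finer cut splits a correlated pair. (Cutting at the smallest such
number would be vacuous — with one cluster there are no between-cluster
pairs.) This guarantees every pair of retained unlabeled bins correlates
below the threshold. Correlations are computed on normalized intensities;
Pearson r is location/scale invariant, so this equals the autoscaled-data
correlation, but fixing the stage makes the computation deterministic.

The choice of representative is an automated proxy (maximal mean correlation
within the group) for what is, on real spectra, a manual judgement involving
annotation confidence and peak isolation; the proxy is reproducible and
monotone in the correlation criterion the manual procedure also used.

## Outcome classification

Outcomes are pure functions of the lesion history: *new SH* (severe SH at T3,
no severe SH/SU at T1–T2), *new SU* (SU at T3, clean before), *chronic SU*
(SU at T3 and already at T1 or T2), *control* (no lesion of any grade at T3
and no severe SH/SU at T1, T2 or T4). Precedence is explicit — exclusions
(second parity, toe ulcer, hemolysis grade ≥ 3 at any sampled time point),
then chronic SU ≻ new SU ≻ new SH ≻ control — so degenerate histories
classify deterministically; histories failing every definition (e.g. mild SH
only at T3) are excluded. Mild SH never disqualifies a case but does
disqualify a T3 control; the T4 check applies to control eligibility only.
The 17 subsets cross these outcomes with time point and parity; T1 is
analyzed in the first-parity cohort only, where precalving heifers are
metabolically homogeneous. Control matching draws, per parity cohort, as many
controls as cases uniformly at random without replacement; when a simulated
cohort is short of controls the orchestrator takes the whole pool and warns,
rather than aborting the run.

## Selectors

* **PLS-DA.** Two-class PLS regression on the 0/1 class indicator (sklearn's
  NIPALS-equivalent), prediction by thresholding the fitted response at the
  class-code midpoint 0.5. VIP_j = √(p·Σ_a SSY_a (w_aj/‖w_a‖)² / Σ_a SSY_a),
  with SSY_a the response variance explained by component a; Σ_j VIP_j² = p
  identically, so VIP > 1 means above-average contribution.
* **Lasso.** Logistic regression with penalty λΣ|β_j| on the mean
  log-likelihood scale, intercept effectively unpenalized (liblinear with a
  large intercept scale). λ_max = max_j |x_jᵀ(y−ȳ)|/n is the smallest
  all-zero penalty; the tuning grid is 50 log-spaced points from λ_max down
  to 0.01·λ_max. Selection = nonzero coefficients in the model refit at the
  CV-winning λ on the full (sub)sample.
* **Boruta.** Each iteration appends an independently shuffled shadow copy of
  every unresolved variable, fits a random forest, and scores a hit when a
  real variable's importance exceeds the best shadow's. Hit counts are tested
  two-sided against Binomial(iterations, ½) with Holm step-down correction at
  α = 0.01; unresolved variables after the iteration cap stay tentative and
  count as **not** selected (selection must be binary; conservative).
  Importance is the forest's impurity (Gini) importance: shadows share the
  impurity measure's biases, so the real-vs-shadow comparison stays
  calibrated, and it is computed at no extra cost during fitting — relevant
  when Boruta runs inside thousands of bootstrap resamples.

Tuning uses stratified 5-fold CV repeated 20 times (100 fold-fits per grid
point), identical folds across grid points; out-of-fold predictions are
pooled within a repeat, balanced accuracy `(recall_case + recall_control)/2`
averaged over repeats; ties prefer fewer components / larger λ / smaller
mtry. Random-forest prediction grids use mtry ∈ {√p, p/3, p/5} at 500 trees.
A class with fewer members than folds triggers a leave-pair-out fallback
(one case plus one control per test set, at most 100 seeded pairs) with a
warning.

## Stability and thresholds

Bootstrap resamples are stratified by class (size n, within-class draws with
replacement), so every resample contains both classes by construction.
Stability_j = 100·(#resamples selecting j)/B with B = 200; observed stability
is the unweighted mean over the three methods. Baseline stabilities repeat
the identical procedure after uniformly permuting the labels (class sizes
preserved), 10 permutations × 20 resamples; per permutation the 99th
percentile (linear interpolation) and the maximum of the per-variable
baselines are taken, and T99/T100 are their means over permutations.
Flags use strict inequality.

By default, hyperparameters are re-tuned inside every bootstrap resample, so
stability reflects the complete selection procedure. The reduced-cost
configuration (`AnalysisConfig.reduced()`) instead freezes each method's
hyperparameters from a single tune on the unresampled data and reuses them in
every resample and permutation — the same freezing applied to observed and
baseline computations alike, so the calibration of T99/T100 against observed
stabilities is preserved.

## Synthetic-data generator

The generator emulates, per sample: log-normal latent metabolite
concentrations (log-SD 0.35 — positive, right-skewed, matching the rank
test's motivation); per-metabolite bins sharing the latent with independent
log-normal bin noise sized so sibling bins correlate at a configured r
(default 0.95, above the 0.9 pruning threshold so selection is exercised;
r = 1 with zero noise makes siblings exact scalar multiples); 93 unlabeled
bins grouped into 51 latent clusters with the same correlation structure; a
configurable fraction (default 15%) of unlabeled bins as weak baseline
signals with additive noise that occasionally drives integrals negative.
Lesion grades are drawn independently per time point from per-parity
prevalence tables whose defaults are the observed frequencies of a ~737-cow
Holstein herd (e.g. first parity at T3: 0.37 none / 0.32 mild SH / 0.26
severe SH / 0.05 SU). Case effects multiply the latent concentration of a
designated metabolite by 2^log2FC for animals whose outcome matches the
effect's context, so the planted log₂ fold-change of group means is well
defined before normalization. Hemolysis grades are drawn per sample
(defaults 0.68/0.22/0.07/0.02/0.01 for grades 0–4); an optional additive
shift on a bin subset models hemolysis contamination, off by default.

What the generator does **not** emulate: longitudinal correlation of lesion
states across time points (grades are drawn independently from the marginal
prevalences), peak shapes or chemical-shift structure (generation starts at
binned integrals), inter-animal covariance beyond the shared latents, and
systematic time-point or parity effects on the metabolome. Passing tests
therefore demonstrate the statistical machinery's correctness and
calibration, not that real serum spectra carry a given signal. Variance
components of real metabolite intensities are unknown here; the noise scales
are free parameters chosen once, not calibrated quantities.

## Numerical and degenerate-input choices

Sample SDs use ddof = 1 everywhere. Inside resamples and folds a by-chance
constant column is standardized to zero (it carries no class information)
rather than raising; the strict `autoscale` pipeline operation raises and
names the column. The rank test uses the exact Mann-Whitney null for
tie-free data up to combined n = 50 and the tie-corrected normal
approximation with continuity correction otherwise. PLS fits with zero
explained response variance return all-equal VIP by convention. The 100th
percentile is the maximum. One master seed (numpy SeedSequence) drives
simulation, fold assignment, forest randomness, bootstraps and permutations;
fixed seed means bit-reproducible output.

## Problem sizes used in the shipped checks

The calibration study in `scripts/acceptance.py` and the test suite uses 20
replicate null datasets of 100 samples × 85 variables with the reduced-cost
configuration (B = 50 observed resamples, 10 permutations × 20 resamples,
7-tree/15-iteration Boruta, frozen hyperparameters); power and recovery
checks use 150 animals per class and cohorts of 250–2000 animals. These sizes
were chosen as the smallest at which the binomial/Monte-Carlo tolerances of
the respective checks are meaningful.

## Known limitations

* Reduced-cost Boruta (7 trees, 15 iterations) can only confirm a variable
  with a near-perfect hit streak; with several competing strong variables its
  selections can be empty while PLS-DA and Lasso still carry the stability
  signal. Full-cost Boruta (500 trees, up to 100 iterations) does not share
  this limit.
* The nominal false-positive interpretations of the thresholds are
  approximate. T99 calibrates well: on replicate null datasets about 1% of
  variables exceed it. T100, however, is the *mean* over permutations of the
  per-permutation maximum baseline stability — for a fresh null dataset,
  whose stabilities are exchangeable with any single permutation's baselines,
  the dataset maximum exceeds a mean of maxima roughly half the time. "0%
  expected false positives" therefore describes the baseline distribution's
  own construction, not a strict bound on new data; occasional T100
  exceedances on null data are expected and observed, and T100 flags should
  be read as "least likely to be artifactual", not "artifact-free".
* T99/T100 are computed from 20-resample baselines but compared against
  200-resample (or 50 in reduced mode) observed stabilities; the coarser
  baseline adds threshold variance relative to the observed quantities.
* The Lasso intercept is approximately, not exactly, unpenalized (large
  intercept-scaling under liblinear); with balanced classes the distortion
  vanishes.
* `run_full_analysis` at full defaults over all 17 subsets is an
  overnight-scale computation; the reduced configuration exists precisely so
  the complete pipeline remains exercisable end to end.
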