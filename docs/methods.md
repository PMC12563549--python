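# Methods

This note documents the models, numerical choices and validation logic
behind `icnet`, in the order the pipeline runs.

## Single-trial estimation (LS-S)

Each trial's activation pattern is estimated with a Least-Squares-
Separate scheme: one GLM per trial, with the trial of interest as one
regressor and all remaining trials of the same kind collapsed into a
second regressor. Encoding designs model six task components (trial of
interest — the 6 s encoding window; other trials; rating period with
response-time duration; post-rating remainder, 6 s − RT; ITI fixations;
instructions), leaving the control-judgment blocks as implicit baseline.
Retrieval designs model the source-judgment period (RT duration) as the
trial of interest, other source trials, post-judgment remainders, item-
retrieval periods, post-item remainders and instructions, leaving ITI
fixations unmodeled. Six motion columns and one spike regressor per
censored volume are appended, plus an intercept.

Numerical choices:

* **HRF**: canonical double gamma (response peak 6 s, undershoot peak
  16 s, dispersions 1 s, undershoot ratio 1/6), truncated at 32 s and
  peak-normalized. Regressors are built on a grid of TR/10 so jittered
  onsets that fall between volume acquisitions are represented
  correctly, then sampled at t = i·TR.
* **Estimator**: ordinary least squares without temporal prewhitening —
  the standard choice for single-trial models, stated here explicitly.
  The reported pattern is the t-map β̂/SE(β̂) with residual dof
  = rows − columns; the SE is unregularized. Because all single-trial
  designs of a run share every column except the two trial columns, the
  shared block is residualized once per run via QR (Frisch–Waugh) and
  each trial reduces to a 2-column solve; this is algebraically
  identical to fitting each full design (asserted in tests at 1e-13).
* **Degenerate cases**: zero-variance voxels yield t = 0 rather than
  NaN; rank-deficient designs raise an error naming the first collinear
  column; a trial with a missing response time is modeled at its nominal
  6 s duration and flagged.

Motion handling: volumes with FD > 0.9 mm are censored via spike
regressors; a run is excluded when more than 20% of its volumes are
censored or absolute displacement exceeds 1.25 mm (half a voxel); a
trial is excluded from similarity analyses when any censored volume
falls inside [onset, onset + duration + 6 s]. The +6 s window is a
design choice covering the HRF rise to peak; it is exposed as a
parameter (`response_window`).

## Representational similarity and informational connectivity

RSMs are Pearson correlations across voxels between trial t-maps,
restricted to cross-run, same-context pairs (cross-run to avoid
within-run temporal autocorrelation), Fisher z-transformed with
correlations clipped to ±(1 − 1e−7) so numerically perfect correlations
(noiseless synthetic data) stay finite. The "combined" variant pools
within-spatial and within-temporal pairs; cross-context pairs never
enter any matrix. Retrieval RSMs use correct source judgments only;
encoding RSMs apply no rating-based filter. Pearson is computed on
t-values as-is, with no voxel standardization beyond the correlation's
own centering.

The ICM correlates cell-aligned RSM vectors between every ROI pair and
Fisher z-transforms the result; both transforms (RSM entries and ICM
entries) are applied. Correlating z-valued rather than r-valued RSM
cells is the implemented default (`use_tmaps`, `min_cells` and the
RSM-value scale are configurable); a floor of 10 shared cells per
correlation avoids degenerate estimates. Zero-variance vectors yield
flagged NaN entries rather than silent ones.

## Group inference

Per edge, the subject-level Δz (post − pre) is contrasted between a
target group and all remaining subjects with a pooled-variance
two-sample t (Welch available by flag). The null distribution shuffles
the target-vs-rest dichotomy across subjects, preserving group sizes —
the subject-level Δ is the exchangeable unit, which respects the
within-subject pairing. Two-sided p = (1 + #{|t*| ≥ |t|})/(n_perm + 1);
when the number of distinct dichotomies is at most n_perm the scheme
switches to exhaustive enumeration. Subjects are canonically reordered
internally so results are bit-identical under input reordering. BH-FDR
is applied across all edges of one (phase, context, target) contrast at
q < 0.05; families are never merged across contexts. Significant edges
are reported with signed direction (increase/decrease of the target
group's change relative to the others).

## Connectivity-profile distance

A ROI's profile is its row of the ICM with the self-entry removed
(length n_roi − 1), in shared partner order for the spatial and
temporal matrices. Distance = 1 − correlation (Pearson or Spearman,
both reported) ∈ [0, 2]; profiles with fewer than three finite entries
or zero variance yield a flagged NaN. Pre/post change is tested per
group with paired t-tests per ROI and BH-FDR across ROIs; the t-sign
follows the post − pre convention and a `post_greater` flag restates
the direction to avoid sign confusion.

## Behavioral statistics

Navigation distance errors are (actual − optimal)/optimal for the
transfer task and (actual − optimal)/(1.2·optimal) for the training
criterion (route success ⇔ actual ≤ 1.2·optimal, boundary inclusive).
The transfer learning rate is −(E_first − E_last)/(E_first + E_last)
over the 20-trial session's halves; sums and means give identical
values, the statistic is bounded in [−1, 1] and invariant to rescaling
all errors, and an all-zero error series yields a flagged NaN. The
verbal learning rate is (last − first)/n_trials on ≤ 12-word recall
counts over ≤ 5 attempts; word matching is case-insensitive,
whitespace-trimmed, order-free, duplicates counted once. Training-course
slopes are closed-form OLS of daily maximum recall on day index, fit
separately for days 1–5 and 6–10 (the training paradigm changes between
those phases), with a one-sample cohort t against zero.

Correlation utilities follow the convention: Pearson when both
variables pass Shapiro–Wilk at α = 0.05, Spearman otherwise (gating on
both variables is the conservative choice); partial correlations
residualize both variables on [intercept, covariates] (sex, site), with
p from n − k − 2 dof; two independent correlations are compared with
Fisher's z-test, two-sided by default and one-sided only when asked.
FDR family membership is always an explicit input, never inferred.

## Synthetic study generator

The generator emulates the study design end to end: three groups
(default 27/27/21), pre/post sessions, four context-pure encoding runs
(two spatial, two temporal; 80 trials, 6 s stimuli, rating periods,
jittered 2–6 s ITIs, periodic unmodeled control blocks as implicit
baseline), four retrieval runs (100 trials; item then source judgments
with ~85% source accuracy), TR = 1.56 s, per-ROI voxel×time matrices
(≥ 30 voxels), FD traces with spike probability 2% (spikes 1.0–2.5 mm
over a ~0.08 mm baseline) plus slow random-walk motion columns, and
behavioral tables.

**Informational coupling is planted through shared latent trial
fidelities.** Each ROI holds a fixed unit-RMS, zero-mean context
pattern per context, stable across sessions; trial t's pattern is
f·P + sqrt(1 − f²)·η with fidelity f ∈ [0.15, 0.9] obtained by a
Gaussian-copula map from a latent normal. A coupled ROI pair draws its
latents with correlation equal to the coupling strength (base 0.2;
+delta at the post session in the target group only), so trial-pair
similarity — which tracks f·f′ — becomes correlated across the pair:
informational connectivity is, by definition, correlated trial-pair
similarity structure, and shared fidelity is its minimal generative
cause. Residual directions η are mutually orthogonal, zero-mean and
equal-norm where voxel count allows, which makes similarity equal
f·f′ exactly in the noiseless limit (and two fully coupled ROIs'
RSMs identical). The pattern time course is the trial regressor
(same HRF as the GLM) scaled to a contrast-to-noise ratio of 1
(per-voxel peak signal amplitude in noise-SD units); spatially uniform
responses are added for nuisance events, plus three low-frequency
cosine drifts, white noise, and large artifacts at spike volumes. An
optional global background factor (`background_coupling`, default 0)
gives every ROI correlated spatial/temporal profiles; a planted
`distance_roi` loses that factor on temporal trials post-training,
which is the BOLD-level mechanism for a profile-distance divergence.

Coupling calibration: with the defaults above, base 0.2 → 0.7 coupling
produces a mean planted-edge change of ≈ +0.5 Fisher-z units — the
planted-effect size used in the recovery experiments.

Behavior: navigation transfer errors decay as a·exp(−k(t−1)) + b
(a = 0.8, b = 0.15, k = 0.10, truncated-normal noise 0.05); the
post-session initial-error amplitude shrinks by 15% for everyone
(practice effect) plus `behavior_gain` for the navigation group, which
narrows the early-late gap and raises the learning rate. Recall counts
grow linearly (3.5 + 1.2·trial + noise, capped at 12); the slope gains
`behavior_gain` post-training in the verbal group. Training-course
daily maxima grow linearly with group-dependent slopes (verbal
2.5 then 1.5 words/day; navigation 0.8/0.5; control 0.5/0.3 around an
intercept of 7).

**What the generator does not emulate** — and hence what passing tests
do not show about real data: spatial autocorrelation and hemodynamic
variability across voxels/regions, temporal autocorrelation of
physiological noise (the generator's noise is white plus drift),
realistic motion-artifact structure, vividness ratings, retrieval
accuracy heterogeneity, and any anatomical realism. Validation
demonstrates that the statistical machinery is calibrated and recovers
effects under its own generative assumptions, not that those
assumptions hold in vivo.

## Validation experiments and problem sizes

The heavyweight experiments (in `icnet.validation`, reported by
`scripts/acceptance.py`) run at deliberately reduced problem sizes so a
full replicate set completes in minutes on one CPU; the stated sizes
are the package's validation conditions:

* **Null calibration**: 100 replicate null studies, 24 ROIs, 12
  subjects/group, 24 encoding trials, 1,000 permutations; pooled
  per-edge permutation p-values tested for uniformity (KS) and
  empirical FDR of the BH family compared with q + 3·MC-SE.
* **Planted-edge recovery**: 50 replicates at group sizes 26/25/20
  (navigation/verbal/control), 12 ROIs, 40 encoding trials, two planted
  edges at Δz ≈ 0.5 in the verbal group; success requires every planted
  edge to survive FDR in ≥ 90% of replicates with non-planted
  discoveries inside the FDR budget.
* **LS-S fidelity**: amplitude-recovery correlation per ROI at the
  default CNR (40 trials, 50 voxels), and exactness at 1e−8 with noise
  off and one trial per run (isolated trials make the signal lie
  exactly in the design span; with several trials per run the pooled
  "other trials" regressor makes LS-S an approximation by construction).
* **Distance recovery**: 50 replicates of a distance-level planted
  divergence (+0.3 post shift, subject SD 0.1, n = 24, 24 ROIs) fed to
  the real paired-t + FDR test. The BOLD-level decoupling mechanism is
  exercised separately in the unit tests.

## Known limitations

* LS-S bias with temporally adjacent trials is inherent to the design
  (the "other trials" pool absorbs amplitude differences imperfectly);
  the fidelity experiment quantifies it at the default CNR instead of
  pretending exactness.
* Permutation inference assumes exchangeability of subjects across the
  target-vs-rest dichotomy; site strata are not preserved by default
  (no stratified option is currently wired into the CLI).
* The "combined" ICM pools within-context pairs; it is not any average
  of the spatial and temporal ICMs and is only required to be symmetric
  and finite.
* With very few ROIs (< 4) connectivity profiles are too short for a
  meaningful distance; the pipeline flags these as NaN and skips the
  family.
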