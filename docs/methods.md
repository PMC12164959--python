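# Methods

This note documents the models implemented in `selectmem`, the generative
assumptions behind its synthetic cohorts, the numerical choices made where
the design was open, and what the passing test suite does and does not
establish about real data.

## The generative model

### Individual-difference layer

Participants are drawn from a recursive linear path system on standardized
variables, with age as the exogenous predictor X (standardized against the
uniform(60, 88) population moments), plasma pTau181 (M1), DAN
subsequent-memory effect (M3), neural selectivity (M2), and a memory
propensity (Y):

    M1 = a1·X + ε1
    M3 = a3·X + ε3
    M2 = a2·X + d21·M1 + d23·M3 + ε2
    Y  = c′·X + b1·M1 + b2·M2 + b3·M3 + ε4

Default path values carry the signs seen in aging cohorts — pTau rises with
age (a1 = 0.35), selectivity falls with age (a2 = −0.25) and pTau
(d21 = −0.25) and rises with DAN engagement (d23 = 0.35, a3 = −0.30), and
selectivity supports memory (b2 = 0.40); magnitudes sit in the moderate
0.2–0.4 band typical of individual-difference effects. When `noise_sd` is
left unset, each residual SD is solved from the implied covariance algebra
so that every endogenous variable has unit population variance; the declared
coefficients are then simultaneously the raw and the completely standardized
paths, which makes parameter-recovery checks exact. pTau181 is affine-mapped
to mean 1.59, SD 0.54 pg/ml, education to round(N(16.7, 2)) years, sex to
Bernoulli(0.57) — plausible cohort summaries, not claims about any dataset.
Sex and education carry no true effects by default, so they act purely as
the confound set every downstream equation adjusts for.

### Trial layer

Each cohort has 5 runs × 24 trials (half face, half place, shuffled per
run), events of 4 s every 8 s, TR 2 s. The probability of an associative hit
follows a logistic link on the participant's memory propensity plus a
per-trial signal-quality latent (intercept −0.3, slope 0.7, quality slope
0.4, giving hit rates centred near 0.45); the remaining probability mass is
split over associative miss / item hit / item miss / no response at fixed
proportions 0.40/0.30/0.20/0.10. These proportions are a free choice — only
the hit vs. non-hit margin drives the analyses — and are config-exposed.

### Pattern layer

Per ROI, each trial's voxel pattern is

    base template + response·1 + ρ·(category pattern) + run nuisance + noise.

The uniform `response` term carries mean activation: on preferred-category
trials it is `category_signal` times a gain that is linear in the
participant's latent selectivity on remembered trials (constant, lower, on
forgotten trials — so the selectivity loss is attenuation, not broadening)
plus a small per-trial quality term; nonpreferred trials respond at a fixed
low level. The zero-mean category pattern with fixed strength ρ carries the
multivoxel category information; keeping its strength constant per category
decouples pattern similarity from mean activation, so the pair-mean
residualization in the PSA removes an activation confound rather than the
category signal itself — amplitude-scaled patterns would make the two
perfectly collinear, which is not how multivoxel category structure behaves.
DAN responds only on remembered trials, with magnitude linear in M3; VAN has
a small constant memory effect. The run-shared nuisance component makes the
within-run pair exclusion in the PSA consequential.

BOLD runs, when simulated, convolve 4-s boxcars with the double-gamma HRF
sampled at TR and weight them by the per-trial voxel patterns (which are
stored as ground truth), plus white noise.

### What the generator does not emulate

No autocorrelated scanner noise, drift, motion, susceptibility artifacts,
spatial smoothness, or volumetric geometry; ROIs are index sets, not
volumes. Passing tests therefore establish the correctness and calibration
of the estimators under the declared statistical structure — not robustness
to fMRI preprocessing failures, which are out of scope.

## Estimation choices

**HRF.** Double gamma with peak delay 6 s, undershoot delay 16 s, unit
dispersions, undershoot ratio 1/6, 32-s support, peak-normalised. The
kernel peaks near 5 s and has exactly one post-peak sign change.

**LSS.** Per trial: target EV, one pooled EV for all other trials, and an
intercept; OLS per voxel; the trial map is the t statistic (β/SE, df = T−p).
The pooled EV is a deliberate simplification: with heterogeneous overlapping
amplitudes it shrinks estimates slightly (documented in the tests), but it
recovers isolated or homogeneous events exactly and clearly beats an
unconvolved-regressor fit on noisy runs. The other-trials EV is not split by
condition. High-pass filtering is omitted because the generator adds no
drift. t rather than β is propagated downstream.

**Condition contrasts.** One EV per condition cell (category × memory
outcome for BOLD; cell indicators across trial estimates for the pattern
route), contrast t averaged over ROI voxels. Remembered = associative hits;
forgotten = associative misses + item hits + item misses; no-response trials
are excluded. Cells under 3 trials flag the participant rather than failing
silently. On the contrast-estimate scale, selectivity equals preferred minus
nonpreferred activity exactly; on the t scale the identity holds only up to
the differing denominators.

**Leave-one-participant-out ROIs.** A voxelwise one-sample t of the
face-vs-place contrast over all other participants, thresholded two-sided
and intersected with the prior mask, defines the held-out participant's ROI;
masks under 30 voxels are flagged excluded. The function default threshold
is p < 0.001; the pipeline passes p < 0.01 because synthetic ROIs have tens
of voxels, not thousands — with a handful of heldout-independent maps the
stricter threshold would leave almost every mask under the 30-voxel minimum.
The statistical point — independence from the held-out participant — is
enforced by construction and verified by a corrupt-and-compare test.

**PSA.** Associative-hit trials only; Pearson correlation over voxels
(the field-standard metric implied by the Fisher z step); same-run pairs
excluded; z regressed on the pair-mean activation (one covariate plus
intercept, fit per participant × ROI; a config switch provides two separate
trial-mean regressors); residual within-category minus across-category
means, computed per member ROI and averaged over the ROI group. Correlations
are clipped at 1−1e−15 before arctanh so degenerate (identical) patterns
yield finite z and zero residual selectivity. Trials without an eligible
partner in either category are flagged missing, never scored zero.

**Mixed models.** Random-intercept REML via statsmodels MixedLM. Fixed
effects are tested with containment degrees of freedom: between-participant
terms against G − p_between, within-participant terms against
N − G − p_within, which reproduces the paired t test exactly on balanced
two-condition designs and keeps null rejection rates at ~5% in simulation.
A design with one row per participant (or a single group) falls back to
OLS and matches it to machine precision. Satterthwaite replication is
deliberately out of scope. Follow-up simple slopes refit the focal predictor
within moderator levels and are Holm-corrected as one family. Partial η² is
computed as t²/(t² + df).

**Holm.** Step-down with enforced monotonicity; NaN entries pass through
without counting toward the family size.

**Dependent overlapping correlations.** Zou's (2007) CI built from the
Fisher-z interval of each correlation and the analytic correlation between
the two correlation estimates; verified against a 10,000-resample percentile
bootstrap and covering the true difference at 94–96% in simulation.

**Path systems.** Equation-wise OLS on complete cases (listwise deletion,
minimum 20). For a recursive system of observed variables with each
equation's predecessors included, OLS coincides with the ML point estimates
of the just-identified SEM, and the total-effect identity
c = c′ + Σ(indirect products) holds as exact algebra of the fitted
coefficients — the tests assert it at 1e−10/1e−8. Indirect-effect CIs use a
percentile bootstrap over participants (default 5000 resamples; the pipeline
default is 1000), implemented as batched normal-equation solves so that
thousands of resamples cost a few einsums; resamples with a constant
predictor are redrawn and counted. The completely standardized solution
refits on z-scored variables; each bootstrap resample standardizes with its
own SDs (refit-per-resample semantics). BCa intervals are not implemented;
percentile was chosen as the stated convention.

**Variance partition.** unique_i = R²_full − R²_omit-i;
shared_ij = R²_full − R²_omit-ij − unique_i − unique_j; at most four focal
predictors (the scheme is defined pairwise). Negative components are
possible under suppression and are stored as computed, with a flag.

## Pipeline and problem sizes

The pipeline runs generate → score → (optional BOLD+LSS) → masks →
selectivity/PSA → mixed-model and correlation inference → mediation/SEM/R²,
writing deterministic CSV artifacts, a manifest with the config hash, and a
markdown report. Identical configs reproduce byte-identical CSVs.

Simulation-based checks use: 200 cohorts (n = 150) for parameter recovery,
500 cohorts × 1000 bootstrap resamples for CI coverage, 2000 families for
Holm calibration, 2000 simulations for correlation-CI coverage, 100 runs
for the LSS comparison, and 100 end-to-end pipeline replicates for
direction reproduction; the acceptance script uses 100/1000/30 for its
recovery, coverage, and direction summaries. These sizes give Monte-Carlo
standard errors well inside the asserted bands while keeping the whole
suite within a few minutes on one CPU.

## Known limitations

- The pooled other-trials EV biases LSS under dense heterogeneous designs;
  beta-series alternatives are not implemented.
- The t-statistic scale couples selectivity estimates to per-cell trial
  counts, so participants with few forgotten trials have noisier (and
  slightly inflated-variance) forgotten-condition scores; the
  remembered-vs-forgotten correlation comparison inherits this property of
  t-based extraction.
- Mask definition uses a parametric threshold, not permutation-based
  cluster statistics; only the independence logic of the leave-one-out
  scheme is reproduced.
- The MST similarity slope is per-participant OLS; mixed-model shrinkage of
  those slopes is available through `fit_lmm` but is not the default.
- Overall associative d′ pools false alarms across both category responses;
  averaging category-specific d′ is the documented alternative.
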