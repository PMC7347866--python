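# Methods

This note documents the models and procedures implemented in
`rapidindex`, the assumptions behind them, the parameters that matter,
and what the synthetic data can and cannot establish.

## Problem setting

Hospitalised children wear two wireless sensors: a chest ECG patch
(heart rate HR, respiratory rate RR, one sample per minute) and a wrist
pulse oximeter (SpO2 and pulse rate). Bedside nurses additionally record
an aggregated Paediatric Early Warning (PEW) score every one to four
hours. The package computes, from the per-minute streams, a
patient-adaptive *surprise index*: a non-negative per-minute quantity
that stays near a calibrated baseline while a patient behaves like the
training population (or like their own recent past) and rises when their
joint HR/RR/SpO2 dynamics become unusual. Alarms are threshold crossings
of this index; the evaluation module supplies the case-control accuracy
statistics used to compare the index with the PEW score.

## Validity filtering

Raw wireless values pass broad plausibility filters before any
modelling: HR and pulse rate outside 20–300 /min, RR outside
5–200 /min, SpO2 below 30% are *invalid*; absent values are *missing*.
Bounds are exclusive-as-printed (a value exactly on a bound is valid).
A sensor-minute is *captured* when any of its channels is present and
*valid* when no present channel fails its range, so per sensor
`missing + invalid + valid = intended` minutes exactly. Filtering never
alters stored values; it only sets the validity mask.

## The index pipeline

1. **Windowing.** Sliding windows of the three index channels (HR, RR,
   SpO2), `window_len = 15` min, stride 1 min. Gaps inside a window are
   carried forward up to 5 min; a window is usable when at least 80% of
   its cells were actually observed and none remain missing. The 15-min
   horizon matches the imputation horizon and the sampling interval
   found advantageous for arrest prediction in intensive care.
2. **Standardization.** Per-channel z-scores with mean/sd frozen on the
   training cohort, so new patients are measured on the training scale.
3. **SVD conditioning.** Each standardized window is replaced by its
   best rank-2 approximation. The discarded smallest-variance direction
   carries unphysical high-frequency content; `discarded_energy`
   records the removed fraction of squared singular values.
4. **Dynamics models.** A VAR(2) is least-squares fitted per window;
   the residual covariance is the one-step residual second moment. A
   rank-deficient design falls back to ridge with jitter `1e-6` (and a
   warning). Because rank-2 conditioning makes each window covariance
   singular by construction, an isotropic floor `sigma_floor = 1e-3`
   (standardized units) keeps predictive densities well defined.
5. **Dissimilarity.** Between two window models, the symmetrised
   Gaussian Kullback–Leibler divergence of their one-step predictive
   distributions, `d = ½[KL(N1‖N2) + KL(N2‖N1)]`, averaged over lag
   histories drawn from 30 shared reference windows. It is a
   pseudo-metric (non-negative, symmetric, zero on identical models);
   the triangle inequality is not claimed and does not hold in general.
6. **Descriptors.** Each model is flattened to a 27-vector: lag
   matrices, a location parameter, and the lower-triangular Cholesky
   factor of the residual covariance. The location slot holds the
   *mean-form* parameter `mu = (I − ΣA)⁻¹ c` rather than the raw
   intercept `c`: for persistent vital signs `c` attenuates
   between-patient level differences roughly tenfold, whereas `mu`
   carries them at full scale. Singular values of `I − ΣA` are clipped
   at 0.05 so near-unit-root window fits cannot send `mu` to infinity.
7. **Topographic map.** A Gaussian RBF network (centres from seeded
   k-means, `m = min(n, 50)`; width = median inter-centre distance;
   plus a bias output) maps descriptors to 2-D, trained to minimise the
   raw Sammon-type stress `Σ_{i<j} (d_ij − ‖y_i − y_j‖)²` over its
   output weights with L-BFGS (analytic gradient, 4 restarts:
   classical-MDS initialisation plus seeded random ones; the recorded
   stress sequence is monotone non-increasing). Unlike plain
   multidimensional scaling the trained network projects new
   descriptors out of sample, and its Jacobian is available in closed
   form.
8. **Local geometry.** At a descriptor x the map's Jacobian J (2×D)
   gives the metric tensor `G = J Jᵀ` and the magnification factor
   `√det G` — the local area scaling of the map, our operational
   reading of the visualisation space's "local curvature". With a
   Gaussian basis the Jacobian decays away from the training manifold,
   so magnification collapse (or inflation) marks departure from
   learned behaviour.

## The surprise index

Per minute t, the window ending at t runs through steps 1–8 and scores

    index(t) = z_mag(t) + z_dens(t) + z_adapt(t)

* `z_mag = min(|log M − med| / MAD, 50)`: absolute robust z-score of the
  log magnification factor against the training distribution. The
  absolute value is used because both collapse and inflation of the
  local metric are departures from the trained geometry.
* `z_dens = clip((med_logdens − logdens)/MAD, 0, 50)`: the deficit of
  training density (Gaussian KDE over training projections) at the
  projected point — the "novel or sparse region" signal. Config
  `density_augment`, default on.
* `z_adapt = clip((movement − med)/MAD, 0, 50)`: movement of the
  current projection away from the patient's *own* trailing-median
  position (componentwise median over minutes [t−360, t−61], so the
  current excursion does not contaminate its reference). Its scale is
  calibrated by replaying the training sessions. This term makes the
  index patient-adaptive: it fires even when deterioration moves an
  atypical patient *toward* the population manifold, where the two
  population terms alone would fall. Config `adaptive_augment`,
  default on.

Robust spreads of the two log-scale statistics are floored at 0.2
(ratios below e^0.2 are treated as noise) so that a near-constant
training distribution cannot make one component hypersensitive.

The first value appears at minute 5 from an expanding window (VAR order
drops to 1 until the window can identify order 2; lower-order fits are
zero-padded so descriptors keep a fixed dimension). The alarm threshold
is the nearest-rank 95th percentile of the pooled per-minute training
index; alarms are maximal contiguous runs of `index ≥ threshold`, with
no de-bounce by default.

## Phenotypes and imputation

Training projections are clustered with seeded k-means, k in 2..10
chosen by silhouette; each cluster stores per-channel mean, sd, lag-1
autocorrelation and the within-cluster cross-channel correlation of its
member windows. Per-channel gaps of up to 15 minutes are filled from
the assigned phenotype's AR(1): conditional mean given the last
observed value plus innovation noise at the conditional spread
(deterministically seeded per gap), so imputed stretches are realistic
continuations rather than unnaturally smooth curves that the dynamics
models would flag as novel. The level reverts to the phenotype mean by
default (`impute_level="phenotype"`): a constant, patient-independent
reference whose bias cancels in longitudinal contrasts. Options expose
a patient-trailing-mean level and cross-channel conditioning on live
sensors (`impute_cross`); the latter is off by default because coupling
the imputed level to live-channel offsets blurs pre/post contrasts for
patients away from their cluster centre. Gaps longer than 15 minutes
are refused and the index is unavailable for the affected windows.

## PEW score

Seven parameters (respiratory rate, respiratory distress, SpO2,
inspired oxygen, heart rate, systolic blood pressure, capillary refill
time) map through age-banded bands to integer subscores summing to at
most 26; a total of 9 or more alerts. The published chart's exact
cut-offs are not in the public record, so the default table is a
structural reconstruction — seven parameters, max 26, threshold 9,
age-banded vital-sign bands around standard paediatric normal ranges —
adequate for simulation work, editable via YAML, and not a clinical
instrument.

## Evaluation

Session-level accounting: a case (session with an annotated
deterioration) is a true positive when any alarm starts within the
detection window (24 h usual, 72 h exploratory) before its event; a
control is a false positive when it alarms at all. Sensitivity and
specificity carry exact Clopper–Pearson intervals. PPV/NPV are
prevalence-fixed at 5.6% via Bayes' rule with logit-transformed
(Mercaldo) intervals; a degenerate test leaves the undefined predictive
value as NaN. Paired method comparisons use McNemar's test on
discordant pairs (continuity-corrected chi-square; exact two-sided
binomial below 25 discordants) with paired Wald intervals for the
difference. Warning times (first qualifying alarm to event, hours) are
summarised with inclusive-linear quartiles; undetected events are
excluded and the reduced n reported.

## Synthetic sessions

The generator stands in for undeposited patient data. Stable
physiology: per-channel AR(1) (autocorrelation 0.9) around age-banded
baselines (e.g. infant HR 130, adolescent 75) with a sinusoidal
circadian term, coupled across channels by a shared latent "stress"
AR(1) factor (loading HR +6, RR +3, SpO2 −1.5 per unit). Deterioration
ramps the stress mean linearly from a therapy-escalation onset to the
significant event (default 6 units at event: HR +36/min, SpO2 −9%);
onset-to-event gaps are lognormal with a study-scale median of 47 h,
and the onset floor guarantees at least a sixth of the session as
pre-onset baseline. Sensor loss is bursty (two-state Markov, mean burst
10 min for dropout and 8 min for artifact) with stationary rates
calibrated to the wireless feasibility profile: chest sensor ~93%
captured / ~63% valid of intended time, wrist oximeter ~55% / ~50%.
Injected artifact values always lie outside the validity ranges, so the
filter recovers the corrupted-minute count exactly. Nurse observations
derive the four unmonitored PEW parameters from the same latent stress.

What the generator does *not* emulate: real paediatric pathophysiology
(arrhythmias, intervention responses, medication effects), non-linear
or non-monotone deterioration trajectories, measurement error in nurse
observations, or inter-channel noise covariance estimated from data —
the coupling structure is an assumption. Passing tests therefore show
the machinery behaves as designed under a plausible data-generating
process, not that the index would achieve any particular accuracy on
real ward data.

## Problem sizes and numerical choices

Tests and the acceptance script run at a desk scale chosen as the
package's demo conditions: 36 stable training sessions of 12 h
(≈400 window models, mirroring the study's ~410 training sessions),
evaluation cohorts of 36 cases and 36 controls at 12 h with a 7-h
median onset gap, and ~10⁴ held-out minutes for false-alarm
calibration checks. The end-to-end demo pipeline (12 training sessions,
6 cases / 6 controls) completes in well under five minutes on one CPU.
Determinism: every stochastic step (generator, k-means, subsampling,
restarts, imputation draws) is seeded; identical configuration and seed
reproduce identical numeric artifacts.

Known limitations: the symmetrised-KL dissimilarity and the
magnification-factor reading of "curvature" are declared design
choices, not disclosed study internals; the alarm threshold percentile
(95) is a configuration default, so alert *rates* are not comparable to
the study's unpublished threshold; the detection contrast (post-onset
vs pre-onset mean index) is only defined for sessions with an observed
baseline, and sessions whose baseline was lost to sensor outage are
excluded from that measurement; specificity of a per-minute index
evaluated session-wise is intrinsically poor over long sessions — the
same pattern the bedside comparison reports.
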