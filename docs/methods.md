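# Methods

This note records the models the package implements, the defaults and why,
what the synthetic-data generator does and does not emulate, and the
numerical choices that were genuinely open.

## Task model

The Novelty Task is a three-armed bandit. Three stimuli are on screen each
trial (positions randomized uniformly per trial); each stimulus carries a
fixed win probability and a win magnitude (a whole number of cents,
$0.00–$0.30), and each is scheduled for a lifetime of 5–9 consecutive
trials before being replaced by a novel stimulus. A session introduces 40
replacement stimuli by default; participants are paid 10% of their total
winnings, rounded half-up to the cent.

Design choices where the published task description is silent:

* **Reward contingencies.** Win probabilities are drawn uniform on
  [0.2, 0.9] and magnitudes uniform on {5¢, …, 30¢}. The task's
  "unique probability / unique value" property is enforced at the
  (probability, magnitude)-pair level: with whole-cent magnitudes there are
  at most 31 distinct values but 43 stimuli per session, so literal
  magnitude uniqueness is impossible. Both ranges are configurable.
* **Session termination.** The three replacement slots run independently
  (staggered), so slot lifetimes end at different trials. A session runs
  until the last scheduled lifetime ends (`max(intro + lifetime)`); each
  slot's final stimulus simply stays on screen until then, which keeps
  exactly three stimuli on screen on every trial. Only the (at most three)
  final stimuli can exceed their nominal lifetime, and expected session
  length remains ≈ (3 + n_novel) · mean(lifetime) / 3 ≈ 100 trials.
* **Timing.** Trial duration 3 s and ITI 3 s by default; these affect only
  the event onsets consumed by the GLM stage.

## Learning model

Rescorla–Wagner with a single learning rate α and softmax choice with
inverse temperature β:

* RPE_t = F_t − EV_t(chosen); EV_{t+1}(chosen) = EV_t(chosen) + α·RPE_t.
* p(choose i) = exp(β·EV_i) / Σ_j exp(β·EV_j), computed with the max
  subtracted for stability at large β·EV.

Parameters, units, defaults:

| parameter | meaning | default | rationale |
|---|---|---|---|
| α | learning rate, fraction of RPE incorporated | 0.692 | fixed population estimate used for trajectory replay |
| β | softmax inverse temperature, 1/$ | 15 | EVs are dollars in [0, 0.30]; β ≈ 15 gives strong but stochastic value guidance (a 10¢ EV gap → ~82/18 binary preference) |
| EV init (novel) | starting value of replacement stimuli, $ | 0.216 | population indifference value of novelty |
| EV init (trial-0 stimuli) | starting value of the three initial stimuli, $ | 0.216 | unspecified by the task description; same as novel for symmetry, configurable |

The softmax functional form itself is a design decision (the standard
exponential softmax of the bandit-modeling literature); only the existence
of β is given.

## Subject-level inference

**Maximum likelihood.** The choice NLL is minimized over α ∈ [0.01, 0.99]
and β ∈ [0, 50]. Because the replayed EV trajectories depend on α alone,
the NLL is *profiled*: for each α the EVs are replayed once and β is
optimized in one dimension (bounded scalar minimization bracketed by a
7-point grid); α is then optimized by bounded scalar minimization seeded
from a 9-point grid. This is deterministic given the data, covers at least
a 5×5 grid of start combinations, and was verified against a 197-point
fine grid on sample sessions (NLL differences < 1e-5). Standard errors
come from the numerical Hessian at the optimum. Fits on fewer than 30
trials warn. Single-session estimates are noisy by nature: at ~100 trials
the sampling s.d. of α̂ is ≈ 0.18, and for a uniformly-random (β = 0)
agent the null sampling s.d. of β̂ is ≈ 1 on the dollar EV scale — the
test suite therefore checks recovery in aggregate across sessions.

**Explore labels.** A trial is Explore iff the chosen stimulus is a
replacement stimulus at its second presentation (presentation counting is
by on-screen appearance, not by choice).

**Novelty calibration and NP.** Over trials where a novel stimulus sits at
its second presentation, the indicator "chose the novel stimulus" is
regressed (logistic) on the replayed EV of the best non-novel on-screen
alternative; the indifference value is −intercept/slope, clamped to
[0, 0.30]. Complete separation (including deterministic choosers) falls
back to the empirical switch midpoint or the appropriate boundary, with a
quality flag. Novelty propensity (NP) is the cohort z-score (population
s.d.) of the indifference value.

A property worth knowing: applied to full three-option sessions the
calibration is a *downward-biased* proxy of the generative novel value
(measured ≈ 0.157 vs 0.216 generative), because the third on-screen option
absorbs choice probability relative to the binary-logistic model and
because a novel stimulus chosen at its first presentation has already been
updated by its second. The bias is common to all subjects and NP is
z-scored, so the covariate is unaffected; the pure binary-choice version
of the procedure recovers the generative value to ±0.02 at 2,000 trials.

## Subject-level GLM

The BOLD-like stage operates on one extracted ROI time series per subject
(no volumes, no NIfTI). The design has a baseline event regressor (unit
boxcars at every trial), an RPE modulator restricted to Explore trials and
one restricted to Non-Explore trials — modulator weights mean-centered
within condition *before* convolution, so they are orthogonal to the mean
event response in the weight domain — plus an intercept and optional
polynomial drifts. Convolution uses a unit-peak double-gamma HRF
(difference of gamma densities with shape 6 and 16, undershoot ratio 1/6;
peak ≈ 5 s, zero by 32 s) on a 0.1 s grid, sampled at TR = 2.5 s.
Couplings are estimated by OLS; a rank-deficient design is an error that
names the collinear columns. Simulated noise is white Gaussian by default
with optional AR(1), variance-normalized so the marginal s.d. equals the
configured value.

## Synthetic cohorts

The generator fabricates the statistical structure the group analysis
assumes, not a realistic population:

* **CTQ profiles** are rejection-sampled per group from independent
  discretized truncated normals (exposure subscales proposed near
  cutoff + 4, s.d. 3; non-exposure subscales near 6, s.d. 1.5). Real CTQ
  subscales are correlated; independence is assumed and flagged as a
  non-goal. Group assignment uses the published cutoffs (emotional abuse
  > 8, physical abuse > 7, sexual abuse > 5; emotional neglect > 9,
  physical neglect > 7); a below-all-cutoffs subject with psychopathology
  is excluded rather than counted as a control.
* **Agents** get α ~ Beta centered on 0.692 (concentration 30) and
  β ~ logNormal(log 15, 0.25), then play a full simulated session; NP is
  computed from that session exactly as it would be for real data.
* **Couplings** (signal per dollar of RPE) are Gaussian around condition
  means (defaults 1.2 Explore / 0.8 Non-Explore, s.d. 1.0 — Explore larger,
  mirroring RPE augmentation for novel stimuli in unexposed individuals).
  A Neglect-by-Explore effect of standardized size d subtracts d·s.d. from
  the Explore coupling of neglect-exposed subjects only; Non-Explore
  couplings are identical across groups. Estimated couplings add Gaussian
  estimation noise (s.d. 0.5) by default, or are produced by the full
  BOLD-simulation + OLS route (`estimate_via="glm"`).
* **Sizes.** Equal cells are the default for calibration and power work; a
  named 178-subject preset (45/45/44/44) reproduces the study's total.

What passing tests on these cohorts show: the analysis chain is unbiased,
calibrated (type-I ≈ 5% per effect under a fully null generator) and
powered (> 80% at d = 0.8, n = 45/cell) *given its own assumptions*. What
they do not show: robustness to correlated CTQ subscales, non-Gaussian
coupling distributions, hemodynamic model mismatch, motion or physiological
confounds — none of which the generator emulates.

## Group ANCOVA

With a two-level within factor, the mixed
2 (Abuse) × 2 (Neglect) × 2 (Explore) ANCOVA decomposes exactly into two
between-subject OLS models: subject means M = (b_explore + b_nonexplore)/2
carry the between effects; differences D = b_explore − b_nonexplore carry
the Explore main effect (the D-model intercept) and all Explore
interactions. Factors are effect-coded (±1), NP enters both sub-models
with all its group interactions by default (`include_np_interactions`
toggles this; the full between model has 8 parameters and needs n > 8),
and every single-df effect is tested by Type-III drop-one-term model
comparison. Partial η² = SS_effect/(SS_effect + SS_error). The
implementation matches statsmodels' `anova_lm(typ=3)` with Sum coding to
machine precision, including unbalanced cells.

Post-hoc contrasts are two-sample t tests (exposed minus unexposed, so a
lower exposed mean gives a negative t) on condition-averaged responses for
main effects and within each Explore condition for interactions.

Cluster-extent thresholding binarizes a voxelwise p-grid at the initial
threshold (default p < 0.001), labels face-connected components (no
diagonal adjacency) and discards components below k voxels (default 17).
Autocorrelation-based corrections are out of scope; k is a parameter.

## Determinism and problem sizes

Every random draw flows from explicit `numpy.random.Generator` objects;
the pipeline splits its master seed into named streams via
`SeedSequence.spawn`, so identical configs give byte-identical outputs.
The test suite and the acceptance script use desk-scale problem sizes
chosen so the whole suite runs in well under a minute of simulation time:
50 agents for learning-rate recovery, 2,000 choices for the calibration,
1,000 null cohorts (n = 45/cell, couplings-only fast path) for type-I
calibration, 250 for power, and 5 replicate full-pipeline cohorts for the
qualitative Neglect-by-Explore signature.

## Known limitations

* The calibration's downward bias on three-option sessions (above).
* α and β are weakly identified per session; population-level replay is
  the supported analysis, per-subject fits are exposed but noisy.
* The GLM stage models one ROI time series with known HRF; it is a
  stand-in for the unavailable volumetric individual-level analysis, not a
  reimplementation of it.
* The ANCOVA assumes two within-condition measurements per subject; the
  M/D decomposition does not generalize to > 2 within levels.
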