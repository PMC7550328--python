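# Methods

## The task geometry

All angles live on a ring, measured in degrees in [0, 360) with 0°
pointing right and 90° up; conversion to radians happens only inside the
design generator, where the axis-exclusion parameter is specified in
radians (0.0873 rad = 5°). Every distance-type measure is the minor-arc
angular distance, bounded by 180°, which fixes the chance level of both
retrieval error and foil generalization at exactly 90° (the mean distance
of a uniform angle from any fixed point).

Category centers are sampled uniformly outside four 5°-half-width bands
around the cardinal axes, by rejection (acceptance probability
1 − 40/360 ≈ 0.889). Only the first center is tested against the bands;
the second is placed exactly 180° away and inherits validity because the
axis set is symmetric under a half-turn. Item locations are drawn from the
cosine density f(x) ∝ (cos(x − center) + 1)/2 by rejection sampling under
a uniform envelope (exact; acceptance 1/2). Because the two category
densities have antipodal centers, their sum is constant: the pooled
120-item distribution is uniform by construction, and the per-participant
chi-square check (default 10 bins, df 9 — chosen so the reference
χ² = 15.50 corresponds to p ≈ 0.078) should rarely reject.

Schedules: encoding is three cycles of one random permutation of all 120
pairs, each split into two 60-trial blocks; the immediate test is one
permutation in two blocks; the delayed test interleaves the 120 old items
with 48 foils in three 56-trial blocks, reshuffling until no more than two
foils are consecutive (success probability per shuffle ≈ 2–3%, so the
retry cap of 10⁵ is unreachable in practice).

## Generative response model

A retrieved location is one draw from

  p(x) = w_epi·VM(x; θ_enc, κ_epi) + w_schema·VM(x; θ_center, κ_schema) + w_guess/2π,

with VM the von Mises density — the canonical circular analogue of
Gaussian response noise; nothing in the analysis depends on this choice
beyond unimodality. Foils have no episodic component; its weight is
reallocated to schema and guessing in proportion.

The weights come from a hierarchical retrieval story: an episodic trace is
available with probability p_epi; failing that, schema knowledge is used
with probability p_schema; otherwise the subject guesses. Hence
w_epi = p_epi and w_schema = (1 − p_epi)·p_schema. Delay multiplies p_epi
and p_schema by per-group decay factors (and the concentrations by the
square root of the same factors, a milder precision loss). The defaults
are

| group  | p_epi | p_schema | κ_epi | κ_schema | epi_decay | schema_decay |
|--------|-------|----------|-------|----------|-----------|--------------|
| 24h    | 0.80  | 0.60     | 12    | 6        | 0.85      | 0.97         |
| 1week  | 0.80  | 0.60     | 12    | 6        | 0.45      | 0.80         |

Immediate-test parameters are identical across groups (the groups differ
only in delay), episodic memory always decays faster than schema
knowledge, and the week-long delay decays both more than the day-long
one. These values are not fitted to any dataset; they were chosen once to
put immediate error near 27°, delayed error near 34° (24 h) and 52°
(1 week), and generalization in the 50–60° range — magnitudes typical of
continuous-report location memory — while instantiating the structural
assumption (fast episodic decay, slow schema decay). The hierarchical
form matters: because episodic failures fall back on the schema, the
schema component's *mixture weight grows* at the delayed test even as
absolute schema knowledge shrinks. This is what produces, without any
further tuning, the package's three delayed-test signatures — a steeper
consistency→error slope, worse foil generalization in the 1-week group,
and a larger encoded-vs-retrieved divergence — and it is the point the
simulation is built to make: a decay scheme that dumped lost episodic
mass into pure guessing would produce a *shallower* delayed slope.

Subject heterogeneity: one latent "memory ability" per subject shifts
both logit(p_epi) and logit(p_schema) (SD 0.6) plus independent
idiosyncratic jitter (SD 0.3); concentrations get lognormal jitter
(σ = 0.25). The shared latent is what couples average error and
generalization across subjects, giving the across-participant
correlations their sign. Confidence is reported only at the delayed test:
each drawn component first chooses "new" with a fixed probability
(guess 0.5, schema 0.15, episodic 0.02 — so foils, which never draw the
episodic component, are called "new" more often the larger the guessing
weight), otherwise a 4-point rating is drawn from a softmax whose
sharpness is confidence_gain × log(1 + κ) of the drawn component. Only
the monotonicity (more precise component → higher ratings) is load-bearing.
Missing responses are missing completely at random at rate 0.03.

## Mixture fitting

The fitter is EM over the weight simplex and the two concentrations, with
component means pinned per trial (episodic at θ_enc, schematic at
θ_center). Concentration M-steps use the Best–Fisher approximation to
A⁻¹(R); three starts at κ ∈ {2, 8, 32} guard against local optima;
convergence is an absolute log-likelihood increase below 1e−8 (max 500
iterations), κ capped at 1e6. Identifiability comes from the episodic
mean varying across trials while the schematic mean is fixed; subjects
whose responses are all identical are flagged as degenerate, and fits on
fewer than 50 trials warn. At the study's 120 trials per subject the
cohort-mean weights are recovered to within 0.05 per component
(per-subject estimates are noisier, ~0.04–0.06 SE per weight).

## Divergence

Locations are binned into 36 ten-degree bins (bin k = [10k, 10(k+1));
360° wraps to bin 0), normalized, and smoothed by circular convolution
with a Gaussian kernel evaluated at the circular distance between bin
centers and renormalized — at σ = 22° the kernel's antipodal tail is
e⁻³³, so explicit tail-wrapping is unnecessary, and every smoothed bin is
strictly positive, which is the purpose of smoothing: an empty bin in the
reference distribution makes D_KL infinite. D_KL(P_encoded ‖ P_retrieved)
uses the natural log (nats), is computed per category on each phase's
completed old-item trials, and the two category values are averaged into
one subject-phase score. Outlier flagging (> group mean + 3 SD, per group
and phase) is single-pass: thresholds always come from the full group, so
the rule is idempotent; analyses are reported with and without flagged
subjects.

## Inference

One-sample, paired and two-sample t-tests are classical and two-tailed,
with d = t/√n for the one-sample case; the Fisher-z comparison of two
independent correlations uses z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) +
1/(n₂−3)). The 2 × 2 divergence ANOVA (between: group; within: time) is
delegated to `pingouin.mixed_anova` and cross-checked in the tests
against a hand sums-of-squares decomposition; partial η² =
SS_effect/(SS_effect + SS_error). Across-subject regressions are OLS with
treatment-coded group factors; rank-deficient designs raise an error
naming the collinear columns.

Trial-level mixed models are fit by REML via `statsmodels` MixedLM with
per-subject random intercepts plus random slopes for every predictor
named in the spec; continuous variables are z-scored jointly across all
trials and participants before fitting (a convergence aid that leaves the
t statistics of affine-equivariant terms unchanged). statsmodels does not
provide Satterthwaite degrees of freedom, so p-values use a
containment-style two-tier rule: terms that vary only between subjects,
and terms carrying a per-subject random slope (whose Wald variance is
dominated by the slope-variance component), are tested on n_subjects − 2
df; purely within-subject terms without a random slope on n_obs − rank
df. In the two regimes that occur here this tracks Satterthwaite to well
within the precision that matters and calibrates to ~4–5% type-I error at
the null (verified by simulation in the test suite). Non-convergent fits
trigger a fallback ladder — optimizers bfgs → lbfgs → powell, then random
slopes dropped last-first, finally intercept-only — with every drop
logged; a fit whose fixed-effect covariance is not positive definite is
treated as non-convergent. Simple effects (e.g. the consistency slope
within one phase) are linear contrasts of the fixed effects with the
smallest df of the involved terms. Tests are two-tailed with no
multiple-testing correction.

## Problem sizes and determinism

Defaults mirror the study conditions: 28 (24-h) and 29 (1-week) subjects,
120 encoded pairs, 48 foils, per-subject random centers. All randomness
descends from one master seed through named `SeedSequence` spawns, so
cohorts are byte-identical across runs. Replicate-seed checks in the test
suite use 20 cohort replicates for the qualitative delay signatures and
100 replicates of a 20-subject, 120-trial null cohort for mixed-model
calibration; the full default pipeline runs in a few seconds on one core.

## What the synthetic cohorts do and do not show

The generator reproduces the *statistical structure* the analysis
assumes — mixture-of-sources responding, delay-dependent decay, coupled
subject-level abilities — not human data. Passing tests therefore
demonstrate that the measures and models detect these structures when
present and stay calibrated when absent; they say nothing about effect
sizes in real cohorts, whose inferential statistics depend on the
deposited raw data. Known simplifications: encoding is assumed successful
(no learning dynamics across the three cycles); there is no response bias
toward the schema center (errors for schema-drawn responses are centered
on the category center, not attracted part-way); no reaction-time or
trajectory information; missingness is unstructured; and confidence is a
one-parameter monotone readout rather than a metacognitive model. The
HC/LC confidence boundary (ratings {3,4} vs {1,2}) is configurable
because a canonical split of the 4-point scale is not mandated by the
design.
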