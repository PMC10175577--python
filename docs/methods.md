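# Methods

This note records the models, defaults and numerical choices behind
`wmtstudy`, and what the simulations can and cannot say about real data.

## Task engine

A block at load level *n* has `20 + n` screens; the first *n* are lead-in
and can never be targets. Six target positions are drawn uniformly
without replacement from the 20 critical slots and re-drawn every block;
no adjacency or lure constraint is imposed beyond the defining one
(`stimuli[i] == stimuli[i-n]` exactly at targets). Stimuli are laid down
left to right: targets copy the stimulus *n* back, non-target critical
screens sample uniformly from the alphabet minus that single symbol —
so lures at other lags can occur, and only the lag-*n* symbol is
excluded. Accuracy is (hits + correct rejections)/20 over the critical
screens only; responses during lead-in are ignored.

Sessions run eight blocks: two 1-back blocks, one 2-back block, then the
staircase (≥ 90 % → up one level, ≤ 70 % → down one, floor 1). Block 3
is fixed at 2-back regardless of block 2's accuracy; the staircase first
governs block 4. The session outcome is the mean level of blocks 4–8.
The task itself has no level ceiling; the simulator caps levels at 12
(`TaskConfig.max_level`) purely to bound runtime — simulated learners
never approach it. Stimulus/ISI durations are metadata; the engine is
turn-based, with no response-time modelling.

The **logistic responder** performs the correct action on each screen
(press at target, withhold otherwise) with probability
`lapse/2 + (1 - lapse) * logistic(discrim * (capacity - level))`.
Defaults `discrim = 3` per level and `lapse ∈ [0.02, 0.10]` make
performance degrade over roughly one load level, which produces staircase
trajectories hovering just below capacity, single-session outcome SDs of
about 0.06–0.26, and long-run mean levels within one level of the true
capacity (both verified by simulation in the test suite).

An important consequence: the mapping from latent capacity to expected
session outcome is a monotone but locally *stair-shaped* curve (flat
stretches where the staircase cannot resolve sub-level capacity changes,
steeper stretches between them, local gain anywhere between ~0 and ~1.8).
Population heterogeneity in baselines averages this out at the cohort
level, but for a single homogeneous group of learners the observed
learning curve is not an affine image of the latent one. This is why
parameter-recovery checks of the spline analysis (below) use the
outcome-level generator, where the identity mapping holds by
construction.

## Synthetic cohort

Allocation mirrors the trial design: schedules alternate by enrolment
order; treatment is 1:1 within schedule by blocked randomisation in
consecutive pairs; first-session task order is counterbalanced exactly
within each of the four arms. Calendars follow the spacing rules
(distributed: day offsets {0, 2} per week for 8 weeks; intensive:
{0, 1, 2, 3} per week for 4 weeks); `validate_schedule` re-checks any
calendar against these patterns and treats a short calendar as a
non-completer signal rather than an error.

Trained learners follow a piecewise-linear-with-plateau latent capacity
`c_t = baseline + s1*min(t, k) + s2*max(0, t - k)` over sessions
t = 1..16; controls have `s1 = s2 = 0`. This latent family is chosen so
the downstream one-knot spline analysis is correctly specified and
recovery of (k, s1) is a meaningful check. Population defaults:
baseline ~ N(2.0, 0.5) clipped at 1, s1 ~ N(0.12, 0.06) clipped at 0.01,
s2 ~ N(0.01, 0.01) clipped to [0, s1], k uniform on {5..11}. These give
first-session outcomes near 2, plateau onsets around the middle of
training, smoothed-scale learning rates of ~0.1 level/point and a large
training effect (g well above 1) — the regime such trials report.

Two training-outcome generators:

* `training_model="engine"` (default): every session is run through the
  full per-screen engine with the logistic responder.
* `training_model="outcome"`: outcomes are drawn directly as
  `max(1, round_to_fifths(c_t + N(0, outcome_sd)))`, i.e. Gaussian
  volatility quantised to the staircase-outcome grid (means of five
  integer levels). `outcome_sd = 0.15` is calibrated to the engine's
  measured stationary session-outcome SD (~0.14). This mode exists for
  large Monte Carlo runs (hundreds of studies) where the per-screen
  engine would dominate runtime without changing the statistics under
  study; single-study analyses use the engine.

Transfer scores: latent spans (forward ~ N(6.5, 1.2), backward
~ N(5.0, 1.2)) and a z-scored reasoning ability are drawn per
participant; post-training latents add a common practice shift
(`session_effect`, in SD units, default 0), a trained-group shift
(`treatment_transfer_effect`, default 0 — the no-transfer regime), and
retest noise (0.5 SD). Measured scores are produced by the actual task
simulators — the adaptive span administration with a logistic per-trial
success curve (width 0.4), and the timed reasoning run with items of
increasing difficulty (~15 items answered in 5 minutes) — so transfer
outcomes inherit realistic discreteness, floors and ceilings.

Attrition is missing-completely-at-random: with probability
`attrition_prob` (default 0.10, giving ~18 completers per arm of 20) a
participant stops before a uniformly drawn session; post-training scores
are then missing, as are baseline scores if the first session was never
reached. Real attrition is unlikely to be MCAR and differed by arm in
trials of this kind; group-specific or informative dropout is out of
scope (the config accepts only a scalar rate). Acceptability ratings are
drawn from fixed Likert profiles with majority agreement and no
programmed group differences; 93 % of completers answer the
questionnaire.

Demographics (age ~ N(65.9, 6.8) clipped to 55–85; ~27 % male) exist so
the baseline-comparability stage has material to test; they influence
nothing else. No device, time-of-day or learning-transfer mechanisms are
modelled — a null transfer effect is programmed, not emergent, so
passing tests say nothing about whether real WMT transfers.

## Learning-curve analysis

Step 1: for each N in 2..16, a 2 (schedule) × 2 (session: S1 vs SN)
mixed ANOVA on the trained participants; each effect family's 15
p-values are BH-FDR corrected separately (the default; a joint-45 family
is a config switch, `fdr_family="joint"`). Pairs missing either session
are dropped per contrast.

Step 2: each 16-point series is smoothed to 15 adjacent-pair means, then
fitted by OLS on the basis {1, t, max(0, t − k)} for every k in 2..14;
the highest R² wins, ties breaking to the smallest k (earliest plateau —
deterministic and conservative). A zero-variance series has undefined R²
and no selectable knot; such participants are excluded and logged. Knots
sit on the 1..15 data-point scale, where data point j averages sessions
j and j+1 — a latent plateau starting at session k therefore appears at
data point k−1..k, and a noiseless raw-scale plateau is *not* exactly in
the one-knot class after smoothing (R² ≈ 0.997 rather than 1); exact
recovery statements apply to series defined on the data-point scale.
First-segment slope and knot location are compared between schedules by
Mann-Whitney U with group means/SDs/medians and Hedges' g alongside.

Estimator caveat, verified by simulation: when the total programmed rise
is small relative to noise (e.g. rise 0.4 level against 0.3-level
volatility), max-R² knot selection drifts late and the first-segment
slope biases low — knot and slope estimates are coupled. Under the
calibrated noise level the recovery checks (median knot within ±1 data
point, median slope within 25 %, 30 learners per condition) pass across
knots {5, 8, 11} × slopes {0.1, 0.2}.

## Statistics

With exactly two within-subject levels the mixed factorial ANOVA is
computed by the exact split-plot decomposition: per-subject mean →
between-subject effects; per-subject difference → all session-involving
effects (the within main effect is the intercept test of the difference
model). Both halves are OLS with sum-to-zero coding and Type III sums of
squares, matching the mainstream statistics packages for the unbalanced
cell sizes attrition produces. Partial η² = F·df₁/(F·df₁ + df₂).
Independent t-tests pool variances (df = n₁ + n₂ − 2, as the printed
degrees of freedom of such trials imply); Hedges' g uses the
J = 1 − 3/(4·df − 1) correction, with the paired version standardised by
the SD of the differences. Mann-Whitney U is exact by enumeration for
n₁·n₂ ≤ 400 without ties, otherwise normal with tie and continuity
corrections. The chi-square test is Pearson without continuity
correction. Extreme outliers use Tukey fences at 3×IQR with quartiles by
linear interpolation (fence membership can differ under Tukey hinges —
documented because it changes sensitivity-analysis membership, not the
primary results). The repeated-measures sample-size routine inverts a
noncentral-F power computation with f² = η²/(1 − η²), noncentrality
λ = f²·N·m/(1 − ρ) and df = ((g−1)(m−1), (N−g)(m−1)), returning the
smallest N that is a multiple of the group count; conventions differ
between power tools, so its output is documented rather than matched to
any published figure (with η² = 0.06, α = 0.05, power 0.80, ρ = 0.5 it
returns N = 34).

Follow-up t-tests (first/final session by treatment, within-group
first-vs-final) run only when the treatment × session interaction is
significant at α = 0.05. Sensitivity reruns exclude participants flagged
as 3×IQR outliers on either the pre or post distribution of the measure
and repeat the ANOVA. The attrition summary applies
(dropouts/assigned) × 100 per arm and overall with a Pearson chi-square
across arms; Likert items (coded 1–5) get between-subjects 2 × 2 ANOVAs
among questionnaire responders.

## Pipeline and determinism

A run is a pure function of (config, seed): every participant draws from
an independent child of one root `SeedSequence`, CSVs are written with a
fixed float format, and simulate → analyze → report re-runs are
byte-identical (tested). Manifests record the config hash, seed, package
version, row counts and a per-participant exclusion log; every input
participant appears as analyzed or excluded-with-reason in each analysis.

## Monte Carlo problem sizes

The calibration checks use 500 simulated null studies (1500 transfer
interaction tests pooled over the three measures) for the type-I error
rate, 200 studies for detection power, 30 learners per condition for
spline recovery, 100 engine-mode learners for knot recovery, and 10,000
blocks for construction validation — sizes at which the binomial error
of the estimated rates is well inside the asserted bands.

## Known limitations

* Active controls are simulated directly as zero-trend outcome series;
  the control tasks' own mechanics (word search, visual search) are not
  modelled.
* No real-time behaviour: timing fields are metadata, practice blocks,
  instruction screens and breaks are absent.
* Dropout is MCAR with a single rate; informative or arm-specific
  attrition is not modelled.
* The latent learning curve is piecewise linear by design; if real
  learning is smoothly exponential, the knot is a modelling construct
  and the recovery guarantees here do not transfer.
* The engine's capacity→outcome stair-distortion means latent slopes are
  not identifiable to high precision from single homogeneous groups;
  cohort-level contrasts are unaffected.
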