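# Methods

## Task model

The environment is a two-stage Markov decision task with block-wise reward
reversals. Structure: 6 blocks × 40 trials (practice: 6 × 5); first-stage
actions a₁/a₂ map to second-stage states s₂/s₃ through a fixed bijection,
each action reaching its mapped state with probability 0.7; second-stage
options pay 100 points with block-dependent probabilities (block 1:
0.6/0.2 in both states; later blocks: 0.8/0.2 in the favored state,
0.2/0.2 in the other, favored state alternating s₂, s₃, s₂, s₃, s₂ from
block 2). Block transitions are uncued, so nothing in the trial stream
marks a reversal and simulated learners never reset their values. Option
identity within a state is stable across trials; screen position and color
counterbalancing are display-level details with no effect on
contingencies and are not modeled. Within each state the first listed
option carries the high reward probability — which of the two options does
so is an arbitrary, fixed convention. The "advantageous" first-stage
action is the one mapped to the favored state; it is undefined in block 1,
so the advantageous-choice probability is computed over blocks 2–6 only.

## Learning model

Two first-stage action values decay each trial and receive increments
split by outcome valence and by system (see README for the attribution
table). Conventions the equations themselves do not fix, chosen here once:

* **Initial values** V₀ = 0 for both actions (and all second-stage
  options): symmetric, so the first choice is uniform.
* **Decay** applies to chosen and unchosen values alike, every trial; the
  chosen option's update is therefore γV + Δ literally.
* **Outcome valence only**: the 0/100 magnitude is binarized; points never
  enter the value equations.
* **No stickiness term, no inverse temperature**: choice randomness is
  absorbed by the Δ magnitudes.
* **Likelihood scope**: only first-stage choices enter the likelihood.
  Second-stage behavior is generatively necessary (it produces the outcome
  stream) but carries no information about the first-stage parameters.

Because only the value difference d = V(a₁) − V(a₂) enters the softmax,
and d follows the linear recursion d′ = γd + s·m (s = ±1 for the chosen
action, m one of four trial-type increments), the session log-likelihood
is evaluated with a single IIR filter pass (`scipy.signal.lfilter`) over
the encoded trial sequence (~25 µs per evaluation for 240 trials). An
explicit per-trial reference loop is kept alongside and the two are
required to agree to 1e-9 in tests; the α/κ and γ/Δ forms are required to
trace identical values to 1e-12.

## Second-stage policy (simulation only)

The first-stage model is silent about second-stage choices, but the
simulator needs them. Agents learn per-state option values on the
binarized outcome by Rescorla–Wagner (rate 0.3) and choose through a
softmax with inverse temperature 5 on the 0–1 value scale — at asymptote
an 0.8-vs-0.2 option pair yields ≈95% choice of the better option. These
are deliberate minimal-standard defaults: sensible exploitation of the
second stage is all that is required to make first-stage values
meaningful, and none of the fitted quantities depend on this policy's
exact form.

## Synthetic cohorts

With no trial-level study data deposited, cohorts are synthesized to carry
the statistical structure the analyses assume: 26 subjects per condition,
each playing one 240-trial session. Per-condition parameter presets are
the median best-fitting estimates reported for the control group
(γ = 0.47, Δ₊ᵐᶠ = 1.09, Δ₊ᵐᵇ = 0.33, Δ₋ᵐᶠ = 0.48, Δ₋ᵐᵇ = −0.14) and the
stress group (γ = 0.73, Δ₊ᵐᶠ = 0.50, Δ₊ᵐᵇ = −0.04, Δ₋ᵐᶠ = 0.02,
Δ₋ᵐᵇ = −0.01). Between-subject heterogeneity is normal jitter around the
preset with per-parameter scales derived from the reported interquartile
ranges (σ ≈ mean IQR / 1.349: 0.28 for γ, 0.74/0.41/0.33/0.26 for the four
Δs); jittered γ is clamped to [0, 1]. All randomness flows from one master
seed through `numpy` SeedSequence spawning, so cohorts are byte-identical
across reruns.

What the generator emulates: group sizes, task schedule, hybrid choice
dynamics at the reported parameter regimes, between-subject spread, and
the occasional perseverating subject (which the exclusion rule removes, as
in the original sample). What it does not: reaction times, within-session
parameter drift, second-stage strategy differences between conditions,
latent-state inference strategies, and any correlation structure between
parameters across subjects (jitter is independent per parameter). Passing
tests therefore show the pipeline recovers the assumed generative
structure — not that real subjects obey it.

## Fitting

Per-subject maximum likelihood via Nelder–Mead. γ is constrained to [0, 1]
by optimizing an unconstrained surrogate mapped through a logistic
(avoiding simplex boundary-clipping artifacts); the four Δs float freely.
Random initial points: γ uniform on (0.05, 0.95), Δ uniform on (−2, 2) — a
box bracketing the fitted-parameter quartiles of both conditions. Simplex
tolerances 1e-6 on both function value and parameters, at most 2000
iterations per restart; non-converged restarts still contribute their best
point but are counted in the result. The default is 500 restarts per
subject; the analysis scripts and validation runs use 30–50, which on
240-trial sessions reproducibly reaches the same optimum (the acceptance
suite checks the fitted likelihood against an independent grid-search
oracle — a coarse γ × [−3,3]⁴ grid with local refinement, evaluated in a
vectorized pass that exploits the likelihood's linearity in Δ at fixed γ).
Sessions with a single unique first-stage choice are fitted but flagged
degenerate: their likelihood has no finite optimum. Per-subject fitting
seeds derive from the master seed and a hash of the subject id, so results
are independent of subject order.

## Statistics

* **Exclusion**: subjects whose modal first-stage action exceeds 95% of
  trials (strict inequality) are removed before fitting and analysis.
* **Stay probabilities**: each trial from the second onward is classified
  by the previous trial's outcome × transition; "stay" means repeating the
  previous first-stage choice; block boundaries do not break the sequence.
* **Mixed ANOVA** (2 within × 2 within × 2 between): implemented from the
  conventional split-plot partitioning via orthonormal per-subject
  contrasts — the subject mean carries the between stratum, each within
  contrast its own stratum with the contrast's pooled within-group
  residual as error. Effect sums of squares use unweighted condition
  means (the Type-III convention) so unequal group sizes after exclusion
  are handled the way standard commercial ANOVA routines do; with equal
  groups this coincides with the classical partitioning exactly. No
  installed Python package offers this two-within-one-between design,
  hence the in-house implementation; it is pinned in tests against an
  independent split-plot fit of a frozen dataset and against the
  algebraic identity that each 2-level within effect's F equals the
  squared t of the corresponding per-subject contrast.
* **Group comparisons**: two-tailed pooled-variance t tests (control minus
  stress). **Regression**: OLS of Δ₋ᵐᶠ on γ and a treatment indicator
  (statsmodels), reporting B, SE, standardized β, p. **ANCOVA**: condition
  effect on Δ₋ᵐᶠ adjusting for advantageous-choice probability
  (pingouin). No multiple-comparison correction is applied anywhere.
* Subjects with an empty stay cell are dropped from the ANOVA with a
  warning; at 240 trials per session this is vanishingly rare.

## Validation design and known limitations

The headline group statistics of the original study depend on its raw
data and are not exactly reproducible; validation is therefore structural
(task counts and calibration against the printed design quantities) plus
simulation-based (parameter recovery, directional group effects, and the
qualitative stay-shift signatures of pure strategies). Two caveats are
worth stating explicitly:

* In a reversal variant of the two-step task, a *pure model-free* agent
  shows a small but genuinely nonzero reward × transition interaction
  (≈ +0.05 at the default settings; measured at 1500 sessions): conditioning
  on the previous transition correlates with which second-stage state
  produced the outcome, which under reversals correlates with value state.
  This is the known "model-free looks model-based" confound that motivates
  the advantageous-choice ANCOVA, and tests assert the honest version —
  the model-free interaction stays an order of magnitude below the
  model-based one — rather than exact zero.
* At 26 subjects per condition some downstream effects have modest power:
  the total-points and advantageous-choice differences between preset
  cohorts are directionally reliable across many sessions but not
  significant in every single cohort draw, and the three-way ANOVA
  interaction p fluctuates across seeds. The parameter-level Δ₋ᵐᶠ
  comparison, by contrast, is strongly powered at this size.

Hierarchical/Bayesian estimation, model comparison criteria, reaction-time
modeling, and latent-state inference models are out of scope.
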