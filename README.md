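# twostep

Simulation, model fitting, and behavioral statistics for a two-stage Markov
decision task with uncued reward reversals — the paradigm used to separate
**model-free** (habitual) from **model-based** (goal-directed) reinforcement
learning, and to ask how a between-subject manipulation (e.g., acute stress
vs. control) shifts the balance between the two systems.

The package is written for computational cognitive modeling work where raw
trial data are unavailable: it generates synthetic cohorts with the
statistical structure of the original study, fits the hybrid learning model
per subject by maximum likelihood, runs the standard analysis battery, and
validates the whole pipeline by parameter recovery.

## The task

Each of 240 trials (6 uncued blocks × 40 trials) has two stages. A
first-stage choice between actions a₁ and a₂ leads to second-stage state s₂
or s₃; each action reaches its associated state with probability 0.7
("common" transition) and the other state otherwise ("rare"). A second-stage
choice then pays 100 points or nothing according to a block-wise schedule:
block 1 offers 0.6/0.2 in both states (no first-stage action dominates);
from block 2 on, one *favored* state offers 0.8/0.2 while both options in
the other state pay 0.2, and the favored state alternates across blocks
(reversal learning). A practice variant has 5 trials per block (30 trials).

## The model

First-stage behavior is captured by two action values that decay and receive
outcome-dependent increments. For every option x, per trial,

    V(x) ← γ V(x) + Δ

with decay factor γ ∈ [0, 1] and increments split by outcome valence
(Δ₊ / Δ₋) and by system (model-free Δᵐᶠ credits the chosen action;
model-based Δᵐᵇ credits the action whose common transition leads to the
state where the outcome occurred):

| previous trial        | chosen action          | unchosen action |
|-----------------------|------------------------|-----------------|
| common, rewarded      | Δ₊ᵐᶠ + Δ₊ᵐᵇ            | —               |
| rare, rewarded        | Δ₊ᵐᶠ                   | Δ₊ᵐᵇ            |
| common, unrewarded    | Δ₋ᵐᶠ + Δ₋ᵐᵇ            | —               |
| rare, unrewarded      | Δ₋ᵐᶠ                   | Δ₋ᵐᵇ            |

Choice probability is a unit-slope softmax on the value difference,
P(a₁) = 1/(1 + exp(−(V(a₁) − V(a₂)))); no inverse temperature is needed
because the Δ magnitudes set choice determinism. The parameterization is
algebraically equivalent to the Rescorla–Wagner form
V ← (1−α)V + ακ with γ = 1−α, Δ = ακ, but numerically stabler. Fitting is
per-subject maximum likelihood (Nelder–Mead, many random restarts, γ
constrained to [0, 1], Δs free).

## Worked example

The numbered scripts under `analysis/` run the study end to end:

```bash
python analysis/01_simulate_cohort.py --seed 123   # 26 + 26 subjects
python analysis/02_fit_model.py --restarts 30
python analysis/03_behavioral_statistics.py
python analysis/04_parameter_recovery.py
```

which prints (seed 123, 30 restarts):

```
simulated 52 subjects x 240 trials (seed 123) -> results/cohort
excluded 5 perseverating subject(s): ['stress_10', 'stress_15', ...]
median fitted parameters by condition:
           gamma  d_plus_mf  d_plus_mb  d_minus_mf  d_minus_mb
control    0.414      1.113      0.288       0.584      -0.171
stress     0.809      0.140      0.099      -0.117       0.127
stay ANOVA three-way interaction: F(1,45) = 6.59, p = 0.0137
model-free no-reward increment, control vs stress: t(45) = 5.82, p = 5.8e-07
treatment effect controlling gamma: B = -0.466 (SE 0.124), p = 0.00049
recovery on 47 subjects:
 parameter  spearman_rho    n
     gamma         0.729   47
 d_plus_mf         0.959   47
 d_plus_mb         0.868   47
d_minus_mf         0.918   47
d_minus_mb         0.727   47
```

Reading this: the cohort was generated with control/stress parameter
presets; the fitted medians recover them (e.g., control γ ≈ 0.41 vs the
0.47 preset). The condition × reward × transition interaction in the
stay-probability ANOVA and the reduced Δ₋ᵐᶠ under "stress" are the two
headline effects the pipeline is built to detect, and the Spearman
correlations show the fits rank-track the generating parameters.

The same pipeline is available as a console tool
(`twostep simulate|fit|analyze|reproduce`); `twostep reproduce --seed 0
--out results/run` writes the full bundle (trial log, ground truth, fits,
stats report, manifest) and is bit-reproducible from its manifest.

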