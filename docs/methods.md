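# Methods

## The decision model

The package's core is the basic diffusion decision model with asymmetric
absorbing bounds. Evidence x(t) accumulates from x(0) = 0 with increments
N(μ·dt, dt) — unit-variance noise per millisecond — until it reaches +A
(rightward decision) or −B (leftward decision). Drift is linear in signed
motion coherence, μ = k·Coh, with Coh a **fraction** in [−1, 1]. Choice
probability and the per-side conditional mean decision times have the
standard closed forms

    P(right) = (e^{2μB} − 1) / (e^{2μB} − e^{−2μA})
    E[T | right] = (A+B)/μ · coth(μ(A+B)) − B/μ · coth(μB)
    E[T | left]  = (A+B)/μ · coth(μ(A+B)) − A/μ · coth(μA)

Reaction time adds a response-side non-decision time (t0_left, t0_right, in
ms). This model family predicts mean correct RTs and choice probabilities
only — deliberately: no drift variability, no collapsing bounds, no full RT
distributions. That is sufficient to separate the two bias mechanisms of
interest and keeps every prediction in closed form.

### Bias terms and phases

Each parameter set describes both experimental phases at once. The baseline
phase uses (k, A, B, t0_left, t0_right). The test phase adds:

* `sp` (evidence units) — a starting-point shift, implemented as bounds
  A−sp and −(B+sp). Positive sp moves the start toward the rightward
  bound and so favours rightward choices. |sp| < min(A, B).
* `dcoh` (percent-coherence points) — an additive offset to the effective
  coherence, μ = k·(Coh + dcoh/100). Reported in % points because it is
  directly commensurate with PSE shifts; used internally as a fraction.
* `dt_left`, `dt_right` (ms) — additive test-minus-baseline changes in the
  non-decision times (practice effects; negative = faster in test). The
  group estimates this package uses as reference ground truth pair the
  first printed non-decision time with the left response and the second
  with the right, and read the printed parenthesised values as the signed
  change. Published descriptions of this family are internally inconsistent
  about both the side labels and the sign of sp; this package fixes one
  convention (the formulas above, sp as a start shift) and states it
  everywhere. Under that convention the behaviour of a cohort that avoids a
  costly *left* response corresponds to sp > 0, and the reference magnitude
  |sp| = 1.62 on a ~23.8-unit bound separation (normalized shift ≈ 6.8%).

### Units

The unit convention (coherence as fraction, time in ms, unit noise per
√ms) is the only one under which the reference group parameters
(k ≈ 0.29, A ≈ B ≈ 12, t0 ≈ 460 ms) yield non-saturated psychometric
functions, chronometric ranges of tens of ms, and a dcoh (≈ 4) commensurate
with the observed ~4% PSE shifts. `drift`, `p_right` and
`mean_decision_time` all follow it.

### Model variants

Four nested variants share the 7 baseline+non-decision parameters:
`baseline` (7; no bias), `starting_point` (8; + sp), `sensory_evidence`
(8; + dcoh), `full` (9; both). A variant's fixed deltas are hard
constraints: supplying a non-zero fixed delta raises.

## Likelihood and fitting

Data enter as per-(phase, coherence) aggregates of manual discrimination
trials: trial count, rightward count, mean and SD of correct-trial RTs.
Zero-coherence conditions are excluded (no defined correct side), as are
error-trial RTs. The joint negative log-likelihood is

* binomial: n_right ~ Bin(n, P(right)) per condition, and
* Gaussian: the observed mean correct RT around the predicted mean with
  standard error sd/√n_correct (conditions with < 2 correct trials
  contribute no RT term).

The Gaussian-on-the-mean choice reflects that the model predicts mean
chronometric functions, not RT distributions. Invalid parameter regions
(non-positive effective bounds) return +∞ so optimizers treat them as
penalties.

Fitting is multi-start Nelder-Mead (derivative-free; the likelihood surface
has mild ridges between sp and dcoh): one moment-based start plus
seed-controlled uniform draws inside a documented search box (k ∈ [0.01, 2],
A, B ∈ [1, 40], t0 ∈ [50, 800] ms, dt ∈ [−150, 150] ms, sp ∈ [−6, 6],
dcoh ∈ [−20, 20]), followed by a polish pass from the incumbent. Fits are
deterministic given the seed. BIC uses n = the number of fitted data points
(choice cells + RT cells, typically 40); the exact n entering log(n) is a
documented convention and configurable — Schwarz weights are insensitive to
it when all variants are fitted to the same data.

## Model comparison

Group fits average per-condition choice proportions and mean correct RTs
across participants (unweighted), keeping the summed trial counts; with the
generator's equal per-participant allocations this equals pooling.
Uncertainty comes from resampling participants with replacement, averaging
each resample, and refitting every variant warm-started from the group
solution. The default is 200 resamples (a desk-scale stand-in for the
reference analysis's 10,000; configurable), with percentile 2.5/97.5%
intervals. Individual-level inference fits the full model per participant
and reports medians of sp/(A+B) and dcoh with two-sided Wilcoxon
signed-rank tests.

At realistic cohort sizes (≈45 participants × ≈30 trials per condition)
the starting-point and sensory-evidence variants are only moderately
separated (ΔBIC ≈ 10 in favour of the generating variant, with
seed-to-seed variability of similar order), which mirrors how delicate the
discrimination is in real data; at 10,000 trials per condition it is
decisive (ΔBIC > 80).

## Trial-level simulation

`ddm_sim` integrates the same process with an Euler step (default 0.5 ms,
increments N(μ·dt, √dt)). Discretely monitored barriers are harder to hit
than continuous ones, so by default each bound is pulled inward by
β·√dt with β = |ζ(1/2)|/√(2π) ≈ 0.5826 (the Broadie–Glasserman–Kou
continuity correction); with it, simulated choice probabilities and
conditional mean decision times match the closed forms within Monte-Carlo
error at the default step, which is what makes the simulator a usable
independent oracle. Walks exceeding 5,000 ms are capped, attributed to the
nearest bound and flagged. Each (phase, coherence) cell of the error-RT
contrast draws from its own keyed substream, so tables are reproducible
regardless of evaluation order.

The error-RT contrast is the discriminating fingerprint: conditional mean
first-passage times are even in μ, so with a start shifted toward the
non-costly bound, errors on costly-direction stimuli (which end at the
nearer bound) get faster from baseline to test while errors on non-costly
stimuli get slower; an evidence shift of matched size produces the opposite
ordering. The package summarises this as the costly-minus-non-costly
difference in Δ(mean error RT).

## Synthetic experiments

The generator reproduces the four canonical designs: (1) manual
discrimination, 5/15/5 blocks × 66 trials, 11 coherence levels (0, ±3.2,
±6.4, ±12.8, ±25.6, ±51.2%), resistance on the left; (2) as (1) with
instructed-arrow induction movements; (3) no 0% level, 4/14/4 blocks,
10-manual + 10-vocal discrimination mini-blocks, resistance side
counterbalanced 7/7; (4) 6/13/6 blocks, 11-manual + 7-vocal detection
mini-blocks. Cohort sizes default to the analysed samples (10/9/14/12,
totalling 45).

Manual choices and RTs are first-passage draws from the DDM (bias terms
active only in the test phase; induction uses baseline parameters). The
default ground truth is the reference group parameter set with the
start-shift sign that produces avoidance of the costly side (sp = +1.62),
so the generated cohort reproduces a ≈ −4% PSE shift end to end.

Vocal discrimination responses are Bernoulli draws from a logistic in
coherence (%) with slope 0.12 per % (JND ≈ 9%, a typical value for this
stimulus class) whose PSE equals bias·exp(−λ·(tsm−1)), where tsm is the
position since the last manual trial. Detection responses use the
equal-variance SDT model with d′ = 1.349 (≈75% correct at a neutral
criterion, matching the titration target band of 65–85%) and the same
exponential offset on the criterion of the resisted direction. The decay
form and constants are the generator's own choices — the reference
behavioural results report windowed averages, not trajectories — set to
λ = 0.05/trial for discrimination (weak, statistically unresolved decay)
and λ = 0.35/trial for detection (clear decay within 7 trials), with
first-trial magnitudes −3.5% PSE and +0.4 criterion units. A 2% lapse rate
mixes in uniform guessing. The viscous-resistance coefficient is tracked
per trial: 0.10 Ns/cm at baseline, +0.0008 per resisted-hand movement
during induction, capped at 0.18 and held through test.

One master seed spawns a substream per participant, so any participant is
reproducible in isolation and tables are byte-identical across runs.

### What the generator does not emulate

Within-trial kinematics (velocities, movement amplitudes, two-hand starts),
response deadlines and the truncation they impose on slow decisions,
between-participant parameter heterogeneity, sequential dependencies, and
any awareness-driven strategy. Passing recovery tests therefore shows the
*analysis chain* is correct and well-calibrated under the model's own
assumptions — not that real data satisfy those assumptions.

## Psychophysics conventions

Manual RTs outside [100, 850] ms are excluded before analysis. Data from
right-hand-resisted participants are mirrored (coherence signs, left/right
labels) so negative coherence always denotes the resisted direction; the
map is an involution. The psychometric function is a plain
maximum-likelihood logistic (statsmodels GLM) of P(rightward) on coherence
in %; PSE = −intercept/slope and JND = (x75 − x25)/2 = ln 3 / slope (the
symmetric slope-derived convention). No lapse parameters are estimated.
Per-participant PSEs are computed first and then averaged — never fitted on
pooled raw trials — matching the paired design of the analyses. Complete
separation is flagged rather than fatal. Sliding windows pool positions
w..w+4 (discrimination, 6 windows over 10-trial mini-blocks) or w..w+2
(detection, 5 windows over 7-trial mini-blocks) across mini-blocks;
detection windows subtract the identically windowed baseline and report
right-minus-left differences, so negative values mean a more conservative
criterion for the resisted (left) direction.

SDT uses the equal-variance conventions d′ = z(H) − z(F) and
C = −(z(H) + z(F))/2. When a hit or false-alarm rate is exactly 0 or 1 the
log-linear correction (add 0.5 per cell, 1 per total) is applied; the
correction policy is explicit because the reference analysis does not state
one.

## Numerical choices

* P(right): log-space/expm1 forms split by drift sign so neither tail
  cancels to zero; below |μ|(A+B) < 1e−4 a Taylor ratio exact to O(μ³)
  with limit B′/(A′+B′).
* Conditional times: coth via 1/tanh; below |μ|(A+B) < 1e−3 the series
  ((A+B)² − B²)/3 − μ²((A+B)⁴ − B⁴)/45, avoiding the 1/μ² cancellation.
* Probabilities clipped to [1e−12, 1−1e−12] inside the likelihood only.
* Degenerate aggregates (all-error conditions, < 2 correct trials) are kept
  and flagged; they simply lose their RT term.

## Known limitations

Mean-RT likelihoods cannot exploit RT-distribution shape, so sp/dcoh
discrimination at single-study sizes is genuinely noisy (see above). The
bootstrap default (200) understates tail quantiles relative to the
reference 10,000. Group-averaged fitting can bias parameter estimates when
participants are heterogeneous; the synthetic cohorts are homogeneous, so
recovery tests do not probe that failure mode. The Euler oracle carries a
residual o(√dt) bias after continuity correction — negligible at the
default step for these parameter ranges, and checked by step-halving tests.
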