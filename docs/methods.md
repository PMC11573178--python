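# Methods

## The assay

The package models a binary social learning task. On each of 153 trials
a participant predicts the outcome of a two-option lottery using two
cues: a pie chart showing the options' true win probabilities
(non-social cue) and a recommendation from an adviser (social cue) whose
helpfulness changes over time. The adviser is consistently helpful for
the first 35 trials (stable phase) and then alternates rapidly between
helpful and misleading regimes (volatile phase, 118 trials). On trials
14, 49, 73, 99 and 134 — plus once before the task — participants
explicitly report whether they believe the advice is "helpful",
"random" or "misleading".

The exact trial-by-trial fidelity schedule of the volatile phase is not
published as numbers; the default schedule in
`advicehgf.task.DEFAULT_SCHEDULE` (alternating fidelity 0.8/0.2 in
blocks of 10–20 trials after a 35-trial stable block at 0.9) is a
structural approximation and is fully overridable through the
`blocks=` argument. Likewise the pie-chart cue values are not published;
the default cue set {0.55, 0.65, 0.75, 0.85}, sampled uniformly per
trial, spans weak to strong non-social evidence. Trial indices are
1-based everywhere, matching how probe trials are conventionally quoted.

The generator draws the lottery outcome first (the pie-favoured option
wins with its displayed probability) and conditions the advice on the
realised outcome: the adviser points at the actual winner with
probability equal to the current fidelity. Marginally the
advice-accuracy sequence u(t) is Bernoulli(fidelity(t)); the advised
option's cue probability c(t) is the pie value re-expressed on the
advised colour.

## Perceptual model

Agents are 3-level binary Hierarchical Gaussian Filters. Level 1 is the
trial's advice accuracy x1 ∈ {0, 1}; level 2 the adviser's fidelity
x2 in log-odds, with p(x1 = 1) = s(x2); level 3 the log-volatility x3
of the fidelity: x2 evolves as a Gaussian random walk with step variance
exp(κ2·x3 + ω2), and x3 as a random walk with step variance ϑ. The
variational (precision-weighted prediction error) update equations of
the binary HGF are implemented as stated in `advicehgf.hgf.filter_beliefs`;
the mean-reverting variant drifts the level-3 prediction by
ϕ3·(m3 − μ3) before each update, a discrete-time Ornstein–Uhlenbeck
tendency toward a subject-specific volatility equilibrium.

Parameter vectors for which a posterior precision turns non-positive —
the standard ill-posedness signal of the binary HGF — raise a
`TrajectoryRejection` naming the offending trial. The fitter treats such
proposals as having zero posterior density; nothing is silently clipped.

## Response model

The advice belief is blended with the non-social cue,
b = ζ·μ̂1 + (1 − ζ)·c, clamped to [1e−8, 1 − 1e−8] so the
log-likelihood stays finite (the clamp is documented, configurable in
source, and far below any behaviourally meaningful resolution). Choice
follows a power sigmoid p(follow) = b^β / (b^β + (1 − b)^β) with
inverse temperature β = exp(−μ̂3 + ν): higher inferred volatility means
noisier decisions, on top of the constant noise offset ν. ν is treated
as a real-valued parameter on the scale entering β (its prior is
Normal(log 48, 1) on that scale), matching how the prior is quoted.

## Model space and fitting

Four models: the standard (m1) and mean-reverting (m2) HGF with free
perceptual parameters, plus ideal-observer controls (m1b, m2b) whose
perceptual parameters are fixed to values minimising cumulative input
surprise on the advice sequence alone (no choice data) under the same
priors. ϑ = 0.5 and ϕ3 = 0.1 are fixed throughout; σ2(0) = σ3(0) = 1.0
(toolbox convention; they are not free parameters and are configurable
on `AgentParams`).

Free parameters and priors (mean, variance in estimation space):
κ2 (0, 1) logit-transformed with upper bound 1; ω2 (−2, 4); μ2(0)
(0, 1); μ3(0) (1, 1); ζ (0, 1) logit; ν (log 48, 1); m3 (1, 1), m2
only. "Variance" in the prior table is taken as a variance, not an sd,
in estimation space.

MAP estimation maximises log-likelihood plus log-prior in estimation
space with L-BFGS-B from five starts (the prior mean plus four seeded
prior draws; gradient tolerance 1e−6, at most 500 iterations); rejected
trajectories score as −∞ and failed/rejected starts are recorded. The
Laplace log model evidence is log-joint(MAP) + (d/2)·log 2π −
½·log det H, with H the central-finite-difference Hessian (step 1e−4)
of the negative log joint; a non-positive-definite H is eigenvalue-
clipped to the nearest PD matrix and flagged in the diagnostics. In a
doubling experiment (10 starts instead of 5) every recovered estimate
was bit-identical, so the multistart default is not the accuracy
bottleneck.

## Model selection

Random-effects BMS with a Dirichlet(1, …, 1) prior over population
model frequencies, estimated by the usual variational scheme.
Exceedance probabilities are Monte-Carlo estimates from 10^5 seeded
Dirichlet posterior samples; the Bayes omnibus risk comes from the
free-energy comparison of the frequency model against the
equal-frequency null, and protected exceedance probabilities are
PEP = (1 − BOR)·EP + BOR/K. Note the variational EP is a property of
the Dirichlet approximation: it differs from the exact-posterior
exceedance (a Gibbs sampler shows ~0.05 discrepancies on small
cohorts), which is inherent to the published method, not an
implementation artifact; the tests check the expected frequencies
against the exact posterior and the EP against the closed-form Beta
tail of the converged Dirichlet counts.

## Synthetic cohorts

A paired (test/retest) cohort draws each subject's session-1 parameters
from the fitting priors (estimation-space Gaussians mapped to native
scale, so bounds hold by construction). Session-2 parameters add a
fixed practice shift plus zero-mean within-subject noise per parameter,
re-clipped to bounds — fixed additive shifts mirror a fixed-effects
practice analysis; idiosyncratic practice effects are representable
only through the within-subject sd. About a quarter of raw prior draws
are ill-posed on the default design; draws are therefore
rejection-sampled against the design (real cohorts are well-posed by
construction, since their parameters come from successful fits), and
within runs an agent's inputs are redrawn a bounded number of times
before it is counted as a failure.

What the generator deliberately does not emulate: state-like
fluctuations between sessions beyond parameter noise, idiosyncratic
strategy changes, lapses/attention failures, and any mismatch between
the agent's generative model and the fitted model. Passing tests
therefore show the pipeline's statistical machinery is correct and that
reliability is bounded by recoverability under model-true conditions;
they do not show that real participants satisfy the model.

## Recovery experiments

Parameter recovery simulates one fresh session per agent per run,
refits by MAP, and summarises generating-vs-recovered agreement per
parameter as ICC(A,1) and Pearson r, averaged over seeded runs (the
canonical experiment uses 39 agents and 5 runs; each run's seed derives
from a single master seed). Generating values are, by default, MAP
estimates obtained by fitting the model once to prior-drawn synthetic
play ("empirical-like" generating values). This mirrors the empirical
procedure, which reuses fitted estimates as generating values, and it
matters: fitted estimates carry prior shrinkage, while raw prior draws
do not, and agreement statistics between an unshrunk generating set and
shrunk recoveries systematically understate recoverability (measured on
this pipeline: κ2 recovery ICC ≈ 0.0 with raw draws vs ≈ 0.2 with
empirical-like values; 2 vs 5 parameters above ICC 0.7). Any
user-supplied generating table is accepted unchanged.

Under these synthetic conditions the recovery ordering reproduces the
qualitative pattern expected of the assay — ω2 at the top of the
perceptual parameters (ICC ≈ 0.95), κ2 at the bottom (ICC ≈ 0.2, the
least identifiable parameter at 153 binary trials), μ3(0) poor — with
one nuance: the response weight ζ recovers marginally better than ω2
(≈ 0.97 vs ≈ 0.95, a gap of about two Monte-Carlo standard errors of
the five-run average). With model-true agents the advice weight is
strongly constrained by every one of the 153 choices, whereas empirical
cohorts plausibly dilute ζ's identifiability with model mismatch.

Model recovery simulates cohorts under each of the four models (the
ideal-observer generators receive ideal perceptual values for their own
inputs and prior-drawn response parameters), fits all four models to
every session, runs RFX-BMS per run, and averages the PEPs into a
confusion matrix.

## Psychometrics

Behavioral measures per session: total accuracy (fraction of trials
choosing the pie-favoured option; a config switch scores the realised
winner instead), advice taking overall and per phase, win-stay
P(y(k+1) = y(k) | win(k)) and lose-switch P(y(k+1) ≠ y(k) | loss(k)).
Empty conditioning sets yield flagged missing values, dropped listwise
with the n used recorded.

Reliability is ICC(A,1) — two-way, single-measure, absolute-agreement —
computed from the two-way ANOVA mean squares, with the F-based 95% CI
(Satterthwaite denominator df). Pearson's r is reported alongside;
the gap between the two indexes the offset (practice-effect)
component. Paired session differences get a t-test, Cohen's d =
mean(diff)/sd(diff), and the JZS Bayes factor for the null (Cauchy
scale r = √2/2 on the standardised effect, evaluated by adaptive
quadrature). Identical sessions (zero-variance zero-mean differences)
are reported as t = 0, d = 0 by convention; zero-variance non-zero
differences are flagged as undefined. Extreme outliers are screened by
Tukey's 3·IQR rule with type-7 (linear-interpolation) quartiles, a pair
being excluded when either session's value is flagged. Influence
diagnostics use Cook's distance from the session-2-on-session-1 simple
regression with the conventional 4/n screening threshold (configurable);
a numerically perfect fit reports all-zero distances rather than noise
ratios. Conventional qualitative ICC labels (poor < 0.5, moderate,
good, excellent) are attached to reports as annotations only.

Probe reports are generated from the level-2 prediction at the probe
trial: "helpful" above +0.5 log-odds, "misleading" below −0.5, else
"random" — a symmetric three-way partition around indifference, with
the threshold exposed as `tau`. The face-validity contrast
(helpful-vs-misleading fidelity belief) is non-circular only when the
beliefs are recomputed from refitted parameters; the pipeline does that
by default and the by-construction variant is available for
diagnostics.

## Problem sizes and numerical choices

The per-trial filter is a scalar recursion over plain floats (~0.1 ms
per 153-trial pass), which keeps a full seven-parameter multistart MAP
fit near half a second and makes the recovery studies tractable on one
core. The shipped experiments use: 39 agents × 5 runs for parameter
recovery (the acceptance script's configuration), 10 subjects × 2 runs
for the model-recovery confusion matrix in the test suite, and paired
39-subject cohorts for the reliability analyses. Session length is 153
trials throughout; doubling runs or subjects changes no default
behaviour, only precision.

Known limitations: no joint or hierarchical two-session estimation (the
fits of the two sessions are fully independent under the same fixed
priors); no full-posterior inference (MAP + Laplace only); no
family-level BMS; binary choices only. The numbered scripts under
`analysis/` are the command-line surface of the package — each is a
thin driver over these library functions with `--seed`/`--out` flags —
so no separate console-script entry point is installed.
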