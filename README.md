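# advicehgf

Psychometrics of a computational assay of **advice taking under
volatility**: how reliably can Hierarchical Gaussian Filter (HGF)
parameters be measured from a binary social learning task?

In the task, a participant predicts a binary lottery on each of 153
trials using a pie chart (true win probabilities) and an adviser's
recommendation whose helpfulness is stable for 35 trials and then
volatile. A 3-level binary HGF models how the participant infers the
adviser's fidelity x2 (in log-odds, p(advice accurate) = s(x2)) and its
volatility x3, via precision-weighted prediction-error updates; a
response model blends the fidelity belief with the pie chart,
b = ζ·μ̂1 + (1−ζ)·c, and maps it to choice through
p(follow) = b^β / (b^β + (1−b)^β) with β = exp(−μ̂3 + ν). The free
parameters are κ2, ω2, μ2(0), μ3(0), ζ, ν (plus the volatility
equilibrium m3 in the mean-reverting variant).

Because participant-level data for this assay are not publicly
deposited, the package makes every stage of the analysis runnable on
**synthetic cohorts**: it generates task designs and paired test-retest
cohorts of HGF agents, MAP-fits the four-model space (standard /
mean-reverting HGF, each with an ideal-Bayesian-observer control) under
fixed priors with Laplace model evidence, arbitrates models by
random-effects Bayesian model selection (protected exceedance
probabilities), and audits the assay psychometrically: ICC(A,1)
test-retest reliability with CIs, Pearson's r, paired t / JZS BF01
practice-effect tests, Tukey outlier screening, Cook's-distance
influence, parameter/model recovery, and face-validity checks. It is
aimed at computational-psychiatry researchers who want to stress-test
this (or a similar) assay before trusting its parameters as individual-
difference measures.

## Worked example

```python
from advicehgf import task, hgf, fitting

design = task.make_task_design()          # 153 trials, stable prefix of 35
inputs = task.sample_advice_outcomes(design, rng=1)
agent  = hgf.AgentParams()                # prior-mean agent
session = hgf.simulate_choices(agent, inputs.u, inputs.c,
                               variant="mean_reverting", rng=2,
                               phase=design.phase)
fit = fitting.fit_map(session, "m2", seed=3)
print(round(fit.lme, 1), {k: round(v, 2) for k, v in fit.params_native.items()})
```

prints

```
-22.9 {'kappa2': 0.49, 'omega2': -1.95, 'mu2_0': 0.68, 'mu3_0': 0.58,
       'm3': 1.27, 'zeta': 0.49, 'nu': 4.02}
```

i.e. the MAP fit of the mean-reverting model to one simulated session:
a Laplace log evidence of −22.9 and parameter estimates close to the
generating (prior-mean) values — ω2 ≈ −2, ζ ≈ 0.5, ν ≈ log 48 ≈ 3.9 —
with the weakly identified κ2 and μ3(0) shrunk toward their priors.

The full analyses are the numbered drivers in `analysis/`
(`01_simulate_cohort.py` … `06_practice_and_face_validity.py`), each a
thin script over the library with `--seed`/`--out` flags, writing tidy
CSV/TSV/JSON tables under `results/`. For example
`python analysis/05_test_retest.py` fits the winning model to both
sessions of every synthetic subject and prints the per-measure ICC
table.

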