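# dmckit

Tools for studying individual differences in conflict tasks (flanker, Simon,
color-word and spatial Stroop) with the **diffusion model for conflict tasks
(DMC)**: a trial-level simulator, preprocessing of trial tables, simulation-
based model fitting with parameter recovery, a synthetic-cohort engine that
imposes known cross-task parameter correlations, and a multilevel
random-effects meta-analysis of cross-task correlations.

## The scientific problem

Congruency effects (RT costs and error costs) are the standard measures of
"inhibitory ability", yet they confound conflict processing with response
strategy and general processing speed. The DMC decomposes behaviour into
these components. Evidence accumulates toward boundaries ±b at a drift that
is the sum of a constant controlled rate μ<sub>c</sub> and the derivative of
a transient automatic activation

&nbsp;&nbsp;&nbsp;&nbsp;E[X<sub>a</sub>(t)] = A·e<sup>−t/τ</sup>·\[t·e/(τ(a−1))\]<sup>a−1</sup>,

which peaks at amplitude A at time τ(a−1) and then decays; it aids the
correct response on congruent trials and opposes it on incongruent trials.
Start points follow a symmetric beta on (−b, b); a uniform nondecision time
T<sub>er</sub> is added to the first-passage time. A and τ index conflict
processing; μ<sub>c</sub>, b, and T<sub>er</sub> index speed, caution, and
residual processes.

With this generative model one can ask: *if conflict mechanisms were truly
correlated across two tasks, how much correlation would the observable costs
show?* The cohort engine draws participant parameter vectors for two tasks
from multivariate normal populations with an imposed correlation on chosen
parameters, simulates both tasks, and measures the emergent Spearman
correlation of RT/error costs. The meta-analysis module pools observed
cross-task correlations (Fisher-z scale, two-level REML with dataset
clusters) and computes heterogeneity (I²) and the smallest pooled
correlation detectable at a given power.

## Worked example

```python
import numpy as np
from dmckit.cohort import PopulationSpec, ScenarioSpec, SCENARIOS, run_scenario

pop = PopulationSpec.for_task("simon")            # time-to-peak mean 72 ms
sc = ScenarioSpec(SCENARIOS["both_conflict"], imposed_r=0.7,
                  n_participants=400, n_trials_per_condition=1000)
res = run_scenario(pop, sc, np.random.default_rng(7))
print(f"rho(RT cost) = {res.rho_rt_cost:.3f}")
print(f"rho(error cost) = {res.rho_error_cost:.3f}")
print(f"realized amplitude r = {res.realized_parameter_rho['amplitude']:.3f}")
```

prints

```
rho(RT cost) = 0.465
rho(error cost) = 0.186
realized amplitude r = 0.712
```

Even with amplitude and time-to-peak correlated at r = .7 across the two
simulated Simon tasks (realized r ≈ .71), the observable RT-cost correlation
is only ≈ .47 at this scale: independent variation in drift, boundary, and
nondecision time dilutes the behavioural signature of shared conflict
mechanisms. For the meta-analytic side:

```python
from dmckit.meta import sensitivity_power
print(sensitivity_power(k=13, n_avg=162, i2=25.0))   # 0.07
print(sensitivity_power(k=13, n_avg=162, i2=75.0))   # 0.12
```

i.e. a meta-analysis of 13 correlations with average n = 162 has 80% power
for pooled correlations as small as .07 (low heterogeneity) to .12 (high).

A `dmckit` command-line interface exposes the stages (`simulate`, `fit`,
`recover`, `scenario`, `meta`); every run writes a JSON log with its seed
and config hash so outputs can be reproduced bit-identically. Shipped
presets: `desk` (1,000 participants × 1,000 trials/condition, reduced
optimizer budget) and `paper` (2,000 × 5,000, full budget).

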