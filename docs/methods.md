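# Methods

## Model

The DMC is a two-boundary diffusion with time-varying mean drift. On each
trial, evidence X(t) starts at a random point drawn as b·(2B − 1) with
B ~ Beta(α, α) (symmetric on (−b, +b); α = ∞ is accepted as a degenerate
fixed start at 0) and evolves by Euler–Maruyama:

    X(t + dt) = X(t) + v(t)·dt + σ·√dt·N(0, 1)

absorbed at +b (correct) or −b (error). The drift is

    v(t) = μc ± d/dt E[Xa(t)],      E[Xa(t)] = A·e^(−t/τ)·[t·e/(τ(a−1))]^(a−1)

with "+" on congruent, "−" on incongruent, and no automatic term on neutral
trials. The derivative has the closed form E[Xa(t)]·((a−1)/t − 1/τ) with
limit A·e/τ at t = 0 for a = 2. The observed RT is the first-passage time
plus a nondecision draw.

Parameter conventions: the gamma shape a is fixed at 2 (so the activation
peaks at t = τ), the diffusion constant σ at 4; b is the *upper* boundary,
and the conventionally reported boundary separation is 2b
(`DMCParameters.boundary_separation`). All times are in ms, evidence in
arbitrary units.

### Numerical choices

* dt = 1 ms, horizon 3000 ms. Halving dt changes mean RT and accuracy by
  less than sampling error at n = 10⁴ (tested). Trials that reach the
  horizon unabsorbed are flagged censored, excluded from all summaries, and
  counted; at the population defaults they are ≪ 0.1%.
* The drift profile v(t) depends only on time, so it is precomputed per
  condition and shared by all trials; the per-trial walk is a numba-compiled
  kernel seeded from the caller's generator (all seeds < 2³¹).
* Nondecision time: the parameterization is mean Ter and SD TerSD. We sample
  a uniform distribution centred on Ter with half-width √3·TerSD (so its SD
  is exactly TerSD), truncated at 0. Uniform residual-time variability is
  the standard diffusion-model convention; a normal would be an equally
  defensible reading, and the truncation never binds at realistic values.

## Preprocessing

Participants below 60% accuracy in *any* task (pooled over conditions and
blocks, untrimmed data, strict inequality) are excluded from all tasks.
RT trimming is per participant × task × condition: drop RT < 100 ms, then
drop RT strictly greater than median + 3·MAD, with median and MAD computed
once on the post-fast-trim cell. The MAD is the raw (unscaled) median
absolute deviation — a literal reading of the rule; a `mad_scale` flag
provides the 1.4826 normal-consistency variant. The rule is single-pass by
design: because removing an outlier shrinks the MAD, iterating it to
convergence would remove progressively more, which is not the stated rule.
RT costs use correct trials only; error cost is the difference in error
rates; neutral trials pass through trimming but never enter costs.

## Fitting

Simulation-based minimization of a G² discrepancy. Per condition, the
observed correct RTs are binned at their .1/.3/.5/.7/.9 quantiles (six bins);
error RTs likewise when at least 11 errors are available, otherwise a single
collapsed error bin. Observed counts are the actual per-bin counts, so
evaluating the data against itself gives exactly 0. Expected proportions
come from simulating n_sim trials per condition (default 10⁴) under the
candidate parameters, floored at 10⁻⁵ of the total to keep G² finite.

The optimizer is differential evolution within the uniform fitting box
(amplitude 15–40, τ 20–120, drift .2–.8, b 45–80, Ter 270–400, TerSD 20–50,
start shape 1–3; wider τ 100–600, Ter 270–500, shape 1–10 for four-choice /
Stroop variants). One simulation seed is drawn per fit and reused for every
objective evaluation (common random numbers), making the objective
deterministic and the whole fit bit-reproducible from (data, bounds, config,
seed). Convergence uses scipy's population-spread criterion (tol 10⁻³) with
a generation cap; population size is `popsize` members per free parameter.
Degenerate bounds (lower = upper) fix a parameter and drop it from the
search. The boundary may vary over condition groups (e.g. speed/accuracy
instruction blocks) with all other parameters shared. Neutral conditions
need no special casing: the generative model itself carries no automatic
activation on neutral trials. Four-choice tasks are fitted with the same
two-boundary (correct vs. any error) architecture.

Parameter recovery draws generating vectors uniformly from the fitting box
(shape fixed at 2), simulates each synthetic participant, refits, and
reports per-parameter Pearson correlations. At full scale (~30+ participants,
5,000 trials/condition, full optimizer budget; roughly 1–2 h on one CPU via
`dmckit recover --preset paper`) drift, boundary, and nondecision time
recover at r ≳ .93 while time-to-peak recovers far worse — the pattern the
test suite checks at reduced scale (10 participants, 1,000 trials/condition,
reduced budget), where the same ordering holds at lower absolute values.

## Synthetic cohorts and scenarios

Populations are normal per parameter with means A 27.5, τ ∈ {72, 135, 505}
(Simon / flanker / Stroop dynamics), μc 0.5, b 62.5, Ter 335, start shape
2.5, TerSD 0, and SDs equal to the fitting ranges divided by six (A 4.17,
τ 16.67, μc 0.1, b 5.83, Ter 21.67, shape 0.167) — so the box edges sit
three SDs from the mean. Each parameter is drawn from a bivariate normal
over (task A, task B) with the imposed correlation if the parameter is named
in the scenario and 0 otherwise; parameters are mutually independent. Draws
violating positivity (or shape < 1) are rejection-resampled; at these
population values the invalid mass is negligible, so the joint correlation
structure is preserved (a warning fires if > 1% of draws are rejected).

The four scenarios correlate: amplitude only; time-to-peak only; both
conflict parameters; or drift + boundary (the nonconflict scenario), at
magnitudes .3/.5/.7. Scenario costs are computed on raw simulator output
(no trimming) — appropriate for synthetic data with no contaminant trials —
and correlated across participants with Spearman's rho. Full scale is 2,000
participants × 5,000 + 5,000 trials; the desk preset (1,000 × 1,000 + 1,000)
runs a scenario pair in ~30 s. Trial-sampling noise attenuates cost
correlations, so desk-scale values sit slightly below full-scale ones
(e.g. Simon both-conflict r = .7: ≈ .48 desk vs ≈ .52 full).

What the generator does *not* emulate: contaminant/anticipatory responses,
sequential (post-error, congruency-sequence) effects, practice or fatigue
drifts, and across-trial drift variability. Tests passing on this synthetic
data therefore validate the pipeline's internal consistency, not the model's
adequacy for any empirical dataset.

## Meta-analysis

Effects are correlations with sample sizes and dataset (cluster) labels,
pooled on the Fisher-z scale with sampling variance 1/(n − 3) (a
`spearman_adjust` flag provides the 1.06/(n − 3) Spearman-specific variant).
The model is two-level: a dataset-level random intercept plus per-effect
heterogeneity, estimated by REML (L-BFGS-B on the −2·restricted-log-
likelihood with non-negativity bounds, multiple starts). With one effect per
cluster only the sum of the two variance components is identified and the
fit reduces to the standard single-level random-effects model; tests verify
both cases against R's metafor (rma.mv / rma) and a brute-force profile
grid. The pooled estimate is the GLS mean with a normal-approximation CI,
back-transformed by tanh. I² = 100·τ²_total/(τ²_total + v̄) with v̄ the
Higgins–Thompson typical sampling variance from the inverse-variance
weights. No multiplicity adjustment is applied across measures.

The sensitivity power analysis treats the pooled estimate as normal with
variance (v + τ²)/k, v = 1/(n_avg − 3) and τ² = v·I²/(100 − I²), and solves
atanh(r) = (z_{1−α/2} + z_power)·SE for the smallest detectable correlation,
reported at 0.01 resolution (the conventional reporting precision; the
upper tail dominates, the lower tail is negligible). With k = 13,
pair-weighted n̄ = 162 (from per-pair ns 50, 103, 102, 43, 3×187, 3×203,
3×213) this gives .07/.09/.12 at I² = 25/50/75%. A "smallest grid value
whose power reaches 80%" reading instead gives .08/.09/.13 — the
solve-then-round form is the one consistent with the published triple and
is the default.

## Problem sizes in the shipped checks

The test suite runs the scenario reproduction at the desk preset (5 seeds),
the null calibration with 20 seeds × 2,000 participants × 150
trials/condition (trial count does not affect the null), recovery at the
reduced scale above, and 200-replicate CI coverage; the acceptance script
runs the two headline scenarios at the desk preset, averaging 5 seeds (the
seed average has far lower run-to-run variance than a single full-size
cohort; full scale shifts the Simon value from ≈ .48 to ≈ .57 as trial
noise vanishes). These sizes were chosen so
each check completes in minutes on one CPU while leaving the quantity it
measures interpretable at its stated tolerance.
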