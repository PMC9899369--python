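"""Synthetic cohorts with imposed cross-task parameter correlations.

Participant-level DMC parameter vectors are drawn from multivariate normal
populations (one bivariate normal per parameter: the participant's value in
task A and in task B).  A scenario imposes a known correlation on a named
subset of parameters and leaves the rest independent across tasks.  Each
participant is then simulated in both tasks and the emergent between-task
Spearman correlations of RT costs and error costs are measured — the
simulation analogue of a two-task individual-differences study with no
measurement noise beyond trial sampling.

Population defaults: amplitude 27.5 (SD 4.17), time-to-peak 72/135/505 for
Simon/flanker/Stroop-like dynamics (SD 16.67), upper boundary 62.5 (SD 5.83),
nondecision 335 (SD 21.67), drift 0.5 (SD 0.1), start shape 2.5 (SD 0.167),
nondecision variability fixed at 0.  The SDs are one sixth of the uniform
fitting ranges, so the range edges sit three population SDs from the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import DMCParameters, simulate_condition

__all__ = [
    "CORRELATABLE_PARAMETERS",
    "SCENARIOS",
    "TASK_TAU_MEANS",
    "PopulationSpec",
    "ScenarioSpec",
    "ScenarioResult",
    "generate_parameter_pairs",
    "simulate_cohort",
    "run_scenario",
    "scenario_grid",
]

# Parameters that vary across participants (gamma shape and TerSD are fixed).
_VARYING = ("amplitude", "time_to_peak", "drift", "boundary", "nondecision_mean", "start_shape")
CORRELATABLE_PARAMETERS = ("amplitude", "time_to_peak", "drift", "boundary")

#: time-to-peak population means representing the three task dynamics
TASK_TAU_MEANS = {"simon": 72.0, "flanker": 135.0, "stroop": 505.0}

#: the four correlation scenarios: which parameters share variance across tasks
SCENARIOS = {
    "amplitude": ("amplitude",),
    "time_to_peak": ("time_to_peak",),
    "both_conflict": ("amplitude", "time_to_peak"),
    "nonconflict": ("drift", "boundary"),
}

# lower bounds enforced by rejection resampling of invalid draws
_LOWER = {
    "amplitude": 0.0,
    "time_to_peak": 1e-9,
    "drift": -np.inf,
    "boundary": 1e-9,
    "nondecision_mean": 0.0,
    "start_shape": 1.0,
}


@dataclass(frozen=True)
class PopulationSpec:
    """Population means and SDs for participant-level parameter draws."""

    amplitude: tuple[float, float] = (27.5, 25.0 / 6.0)
    time_to_peak: tuple[float, float] = (72.0, 100.0 / 6.0)
    drift: tuple[float, float] = (0.5, 0.6 / 6.0)
    boundary: tuple[float, float] = (62.5, 35.0 / 6.0)
    nondecision_mean: tuple[float, float] = (335.0, 130.0 / 6.0)
    start_shape: tuple[float, float] = (2.5, 1.0 / 6.0)
    nondecision_sd: tuple[float, float] = (0.0, 0.0)
    gamma_shape: float = 2.0
    diffusion_constant: float = 4.0

    def __post_init__(self) -> None:
        for name in _VARYING:
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"{name} SD must be >= 0")

    @classmethod
    def for_task(cls, task: str, **overrides) -> "PopulationSpec":
        """Population for a Simon-, flanker-, or Stroop-like task (tau mean)."""
        tau = TASK_TAU_MEANS[task]
        return cls(time_to_peak=(tau, 100.0 / 6.0), **overrides)


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the scenario grid: what is correlated, how strongly."""

    correlated_parameters: tuple[str, ...]
    imposed_r: float
    n_participants: int = 2000
    n_trials_per_condition: int = 5000
    task_labels: tuple[str, str] = ("task_a", "task_b")

    def __post_init__(self) -> None:
        if not -1.0 <= self.imposed_r <= 1.0:
            raise ValueError("imposed_r must lie in [-1, 1]")
        unknown = set(self.correlated_parameters) - set(CORRELATABLE_PARAMETERS)
        if unknown:
            raise ValueError(f"cannot impose correlation on {sorted(unknown)}")
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if self.n_trials_per_condition < 1:
            raise ValueError("n_trials_per_condition must be >= 1")


@dataclass
class ScenarioResult:
    """Per-participant costs for both tasks plus between-task correlations."""

    costs: pd.DataFrame  # columns: rt_cost_a, rt_cost_b, error_cost_a, error_cost_b
    rho_rt_cost: float
    rho_error_cost: float
    realized_parameter_rho: dict[str, float]
    spec: ScenarioSpec


def generate_parameter_pairs(
    spec: PopulationSpec,
    scenario: ScenarioSpec,
    rng: np.random.Generator,
    *,
    spec_b: PopulationSpec | None = None,
) -> tuple[list[DMCParameters], list[DMCParameters]]:
    """Draw paired (task A, task B) participant parameter vectors.

    Each parameter is drawn from a bivariate normal with the population mean
    and SD and cross-task correlation ``imposed_r`` if the parameter is named
    in the scenario, else 0; distinct parameters are mutually independent.
    Draws violating positivity constraints are rejected and redrawn.

    ``spec_b`` allows a different population for task B (e.g. cross-task-type
    pairs with different time-to-peak means); defaults to ``spec``.
    """
    spec_b = spec_b or spec
    n = scenario.n_participants
    draws: dict[str, np.ndarray] = {}
    n_rejected = 0
    for name in _VARYING:
        mean_a, sd_a = getattr(spec, name)
        mean_b, sd_b = getattr(spec_b, name)
        r = scenario.imposed_r if name in scenario.correlated_parameters else 0.0
        cov = np.array(
            [[sd_a**2, r * sd_a * sd_b], [r * sd_a * sd_b, sd_b**2]]
        )
        mean = np.array([mean_a, mean_b])
        vals = rng.multivariate_normal(mean, cov, size=n, method="svd")
        lo = _LOWER[name]
        bad = np.any(vals < lo, axis=1)
        while bad.any():
            n_rejected += int(bad.sum())
            vals[bad] = rng.multivariate_normal(mean, cov, size=int(bad.sum()), method="svd")
            bad = np.any(vals < lo, axis=1)
        draws[name] = vals
    if n_rejected > 0.01 * n * len(_VARYING):
        import warnings

        warnings.warn(
            f"rejection-resampled {n_rejected} invalid parameter draws; the "
            "imposed correlation structure may be distorted",
            stacklevel=2,
        )
    fixed = dict(
        gamma_shape=spec.gamma_shape,
        diffusion_constant=spec.diffusion_constant,
        nondecision_sd=spec.nondecision_sd[0],
    )
    task_a = [
        DMCParameters(**{k: draws[k][i, 0] for k in _VARYING}, **fixed) for i in range(n)
    ]
    task_b = [
        DMCParameters(**{k: draws[k][i, 1] for k in _VARYING}, **fixed) for i in range(n)
    ]
    return task_a, task_b


def _participant_costs(
    params: DMCParameters, n_trials: int, rng: np.random.Generator
) -> tuple[float, float]:
    """RT cost (ms, correct trials) and error cost (proportion) for one
    simulated participant; censored trials are excluded."""
    con = simulate_condition("congruent", n_trials, params, rng)
    inc = simulate_condition("incongruent", n_trials, params, rng)
    rt_cost = float(inc.correct_rts().mean() - con.correct_rts().mean())
    error_cost = float((1.0 - inc.accuracy()) - (1.0 - con.accuracy()))
    return rt_cost, error_cost


def simulate_cohort(
    param_pairs: tuple[Sequence[DMCParameters], Sequence[DMCParameters]],
    n_trials_per_condition: int,
    rng: np.random.Generator,
    *,
    task_labels: tuple[str, str] = ("task_a", "task_b"),
    conditions: Sequence[str] = ("congruent", "incongruent"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate raw trial tables for both tasks of a parameter-paired cohort.

    Returns two tidy trial tables (participant, task, condition, rt_ms,
    correct) consumable by the preprocessing and fitting stages.
    """
    if n_trials_per_condition < 1:
        raise ValueError("n_trials_per_condition must be >= 1")
    tables = []
    for task_params, label in zip(param_pairs, task_labels):
        frames = []
        for pid, p in enumerate(task_params):
            for cond in conditions:
                batch = simulate_condition(cond, n_trials_per_condition, p, rng).valid()
                frames.append(
                    pd.DataFrame(
                        {
                            "participant": pid,
                            "task": label,
                            "condition": cond,
                            "rt_ms": batch.rt,
                            "correct": batch.correct.astype(int),
                        }
                    )
                )
        tables.append(pd.concat(frames, ignore_index=True))
    return tables[0], tables[1]


def run_scenario(
    spec: PopulationSpec,
    scenario: ScenarioSpec,
    rng: np.random.Generator,
    *,
    spec_b: PopulationSpec | None = None,
) -> ScenarioResult:
    """Generate a correlated cohort, simulate both tasks, correlate the costs.

    Costs are computed directly on the raw simulator output (no trimming), as
    appropriate for noise-free synthetic data; Spearman correlations are taken
    across participants between tasks.
    """
    params_a, params_b = generate_parameter_pairs(spec, scenario, rng, spec_b=spec_b)
    n = scenario.n_participants
    costs = np.empty((n, 4))
    for i in range(n):
        costs[i, 0], costs[i, 2] = _participant_costs(
            params_a[i], scenario.n_trials_per_condition, rng
        )
        costs[i, 1], costs[i, 3] = _participant_costs(
            params_b[i], scenario.n_trials_per_condition, rng
        )
    df = pd.DataFrame(costs, columns=["rt_cost_a", "rt_cost_b", "error_cost_a", "error_cost_b"])
    rho_rt = float(stats.spearmanr(df.rt_cost_a, df.rt_cost_b).statistic)
    rho_err = float(stats.spearmanr(df.error_cost_a, df.error_cost_b).statistic)
    realized = {
        name: float(
            stats.pearsonr(
                [getattr(p, name) for p in params_a],
                [getattr(p, name) for p in params_b],
            ).statistic
        )
        for name in CORRELATABLE_PARAMETERS
    }
    return ScenarioResult(
        costs=df,
        rho_rt_cost=rho_rt,
        rho_error_cost=rho_err,
        realized_parameter_rho=realized,
        spec=scenario,
    )


def scenario_grid(
    task_types: Sequence[str],
    magnitudes: Sequence[float],
    scenarios: Sequence[str],
    n_participants: int,
    n_trials_per_condition: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Full factorial task-type x scenario x magnitude grid of scenario runs.

    Returns one row per cell with the between-task Spearman correlations of
    error costs and RT costs, plus the run sizes so scaled-down runs are
    self-documenting.
    """
    if not (len(task_types) and len(magnitudes) and len(scenarios)):
        raise ValueError("task_types, magnitudes and scenarios must be non-empty")
    rows = []
    for task in task_types:
        pop = PopulationSpec.for_task(task)
        for name in scenarios:
            for r in magnitudes:
                sc = ScenarioSpec(
                    correlated_parameters=SCENARIOS[name],
                    imposed_r=r,
                    n_participants=n_participants,
                    n_trials_per_condition=n_trials_per_condition,
                )
                res = run_scenario(pop, sc, rng)
                rows.append(
                    {
                        "task_type": task,
                        "scenario": name,
                        "imposed_r": r,
                        "rho_error_cost": res.rho_error_cost,
                        "rho_rt_cost": res.rho_rt_cost,
                        "n_participants": n_participants,
                        "n_trials_per_condition": n_trials_per_condition,
                    }
                )
    return pd.DataFrame(rows)
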