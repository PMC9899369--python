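"""Simulation-based fitting of the DMC to one participant and task.

The model has no tractable likelihood, so fitting minimizes a quantile-based
G-squared discrepancy between observed data and data simulated under
candidate parameters.  For each condition the observed correct-RT
distribution is cut at its .1/.3/.5/.7/.9 quantiles into six bins whose
expected shares (.1/.2/.2/.2/.2/.1) are scaled by the observed accuracy;
error RTs get the same treatment when there are enough of them and a single
collapsed bin otherwise.  The statistic is

    G2 = 2 * sum O * ln(O / E)

over all bins of all conditions, with predicted bin proportions estimated by
Monte-Carlo simulation and floored at a small epsilon to stay finite.

Minimization uses differential evolution within the standard uniform fitting
bounds (a population initialized uniformly inside the box, recombined and
truncated by objective value).  One simulation seed is drawn per fit and
reused for every objective evaluation (common random numbers), which makes
the objective deterministic and the whole fit reproducible bit-for-bit.
The boundary may vary over condition groups (e.g. speed/accuracy instruction
blocks) while all other parameters are shared.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import CONDITIONS, DMCParameters, TrialBatch, simulate_condition

__all__ = [
    "FitBounds",
    "FitConfig",
    "FitResult",
    "RecoveryReport",
    "ConditionSummary",
    "fit_summary",
    "gsquared",
    "objective",
    "fit_participant",
    "parameter_recovery",
    "evaluate_fit",
    "trials_from_frame",
]

#: parameter order in the search vector (boundary handled per group)
SHARED_PARAMS = ("amplitude", "time_to_peak", "drift", "nondecision_mean", "nondecision_sd", "start_shape")
RECOVERY_PARAMS = SHARED_PARAMS + ("boundary",)


@dataclass(frozen=True)
class FitBounds:
    """Uniform fitting box per parameter; gamma shape and diffusion constant
    are fixed (2 and 4)."""

    amplitude: tuple[float, float] = (15.0, 40.0)
    time_to_peak: tuple[float, float] = (20.0, 120.0)
    drift: tuple[float, float] = (0.2, 0.8)
    boundary: tuple[float, float] = (45.0, 80.0)
    nondecision_mean: tuple[float, float] = (270.0, 400.0)
    nondecision_sd: tuple[float, float] = (20.0, 50.0)
    start_shape: tuple[float, float] = (1.0, 3.0)

    def __post_init__(self) -> None:
        for name in RECOVERY_PARAMS:
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: lower bound exceeds upper bound")

    @classmethod
    def two_choice(cls) -> "FitBounds":
        return cls()

    @classmethod
    def four_choice(cls) -> "FitBounds":
        """Wider ranges used for four-choice and Stroop-type tasks."""
        return cls(
            time_to_peak=(100.0, 600.0),
            nondecision_mean=(270.0, 500.0),
            start_shape=(1.0, 10.0),
        )


@dataclass(frozen=True)
class FitConfig:
    quantile_probs: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)
    n_sim: int = 10_000
    min_errors: int = 11
    epsilon: float = 1e-5
    popsize: int = 10           # population members per free parameter
    maxiter: int = 200
    tol: float = 1e-3
    mutation: tuple[float, float] = (0.5, 1.0)
    recombination: float = 0.7
    boundary_by: str | None = None  # column defining per-group boundaries


@dataclass
class ConditionSummary:
    """Observed summary of one condition used by the objective.

    Bin counts are the actual observed trial counts inside the inter-quantile
    bins (not the nominal quantile shares), so that evaluating the observed
    data against itself yields a discrepancy of exactly zero.
    """

    n: int
    accuracy: float
    correct_quantiles: np.ndarray
    error_quantiles: np.ndarray | None  # None when errors are too few
    n_errors: int
    correct_bin_counts: np.ndarray | None = None
    error_bin_counts: np.ndarray | None = None

    @property
    def error_quantiles_available(self) -> bool:
        return self.error_quantiles is not None


@dataclass
class FitResult:
    params: DMCParameters
    boundaries: dict[str, float]  # per condition-group boundary
    objective: float
    n_evaluations: int
    converged: bool
    seed: int

    def as_dict(self) -> dict[str, float]:
        out = {name: getattr(self.params, name) for name in RECOVERY_PARAMS}
        for group, b in self.boundaries.items():
            out[f"boundary[{group}]"] = b
        out["objective"] = self.objective
        return out


@dataclass
class RecoveryReport:
    """Generating-vs-recovered Pearson correlations across participants."""

    correlations: dict[str, float]
    n_participants: int
    n_trials_per_condition: int
    n_failed: int
    zero_variance: list[str] = field(default_factory=list)


def trials_from_frame(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Split a one-participant trial frame into {condition: (rts, correct)}."""
    out = {}
    for cond, sub in df.groupby("condition", sort=False):
        out[str(cond)] = (
            sub["rt_ms"].to_numpy(dtype=float),
            sub["correct"].to_numpy(dtype=bool),
        )
    return out


def _as_rt_correct(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, TrialBatch):
        v = data.valid()
        return v.rt, v.correct.astype(bool)
    rts, correct = data
    return np.asarray(rts, dtype=float), np.asarray(correct, dtype=bool)


def fit_summary(
    trials: Mapping[str, object],
    quantile_probs: Sequence[float] = (0.1, 0.3, 0.5, 0.7, 0.9),
    min_errors: int = 11,
) -> dict[str, ConditionSummary]:
    """Deterministic per-condition summary: accuracy plus correct- and
    error-RT quantiles (error quantiles omitted below ``min_errors``)."""
    probs = np.asarray(quantile_probs, dtype=float)
    out = {}
    for cond, data in trials.items():
        rts, correct = _as_rt_correct(data)
        if rts.size == 0:
            raise ValueError(f"condition {cond!r} has no trials")
        crt, ert = rts[correct], rts[~correct]
        if crt.size == 0:
            raise ValueError(f"condition {cond!r} has no correct trials")
        cq = np.quantile(crt, probs)
        eq = np.quantile(ert, probs) if ert.size >= min_errors else None
        c_counts = np.histogram(crt, bins=np.concatenate(([-np.inf], cq, [np.inf])))[0]
        e_counts = (
            np.histogram(ert, bins=np.concatenate(([-np.inf], eq, [np.inf])))[0]
            if eq is not None
            else None
        )
        out[cond] = ConditionSummary(
            n=int(rts.size),
            accuracy=float(correct.mean()),
            correct_quantiles=cq,
            error_quantiles=eq,
            n_errors=int(ert.size),
            correct_bin_counts=c_counts,
            error_bin_counts=e_counts,
        )
    return out


def gsquared(observed: np.ndarray, expected: np.ndarray, epsilon: float = 1e-5) -> float:
    """Likelihood-ratio statistic 2*sum O*ln(O/E) with E floored at
    ``epsilon`` times the total count; zero-count cells contribute nothing."""
    observed = np.asarray(observed, dtype=float)
    expected = np.maximum(np.asarray(expected, dtype=float), epsilon * observed.sum())
    mask = observed > 0
    return float(2.0 * np.sum(observed[mask] * np.log(observed[mask] / expected[mask])))


def _condition_gsquared(
    summary: ConditionSummary,
    sim: TrialBatch,
    probs: Sequence[float],
    epsilon: float,
) -> float:
    n_sim = max(len(sim), 1)
    v = sim.valid()
    sim_crt, sim_ert = v.rt[v.correct], v.rt[~v.correct]

    o_counts = [summary.correct_bin_counts.astype(float)]
    crt_counts = np.histogram(
        sim_crt, bins=np.concatenate(([-np.inf], summary.correct_quantiles, [np.inf]))
    )[0]
    e_props = [crt_counts / n_sim]

    if summary.error_quantiles_available:
        o_counts.append(summary.error_bin_counts.astype(float))
        ert_counts = np.histogram(
            sim_ert, bins=np.concatenate(([-np.inf], summary.error_quantiles, [np.inf]))
        )[0]
        e_props.append(ert_counts / n_sim)
    else:
        o_counts.append(np.array([summary.n_errors], dtype=float))
        e_props.append(np.array([sim_ert.size / n_sim]))

    observed = np.concatenate(o_counts)
    expected = summary.n * np.concatenate(e_props)
    return gsquared(observed, expected, epsilon)


def objective(
    params: DMCParameters,
    observed: Mapping[str, ConditionSummary],
    n_sim: int,
    rng_or_seed,
    *,
    quantile_probs: Sequence[float] = (0.1, 0.3, 0.5, 0.7, 0.9),
    epsilon: float = 1e-5,
) -> float:
    """G-squared discrepancy between observed summaries and ``n_sim``
    simulated trials per condition under ``params``; non-negative, zero when
    predicted bin proportions match the observed ones exactly."""
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    total = 0.0
    for cond, summary in observed.items():
        sim = simulate_condition(cond, n_sim, params, rng)
        total += _condition_gsquared(summary, sim, quantile_probs, epsilon)
    return total


def _make_params(values: dict[str, float]) -> DMCParameters:
    return DMCParameters(
        amplitude=values["amplitude"],
        time_to_peak=values["time_to_peak"],
        drift=values["drift"],
        boundary=values["boundary"],
        nondecision_mean=values["nondecision_mean"],
        nondecision_sd=values["nondecision_sd"],
        start_shape=max(values["start_shape"], 1.0),
    )


def fit_participant(
    trials,
    bounds: FitBounds = FitBounds(),
    config: FitConfig = FitConfig(),
    rng: np.random.Generator | None = None,
) -> FitResult:
    """Fit one participant x task by differential evolution.

    ``trials`` is a one-participant DataFrame (columns condition, rt_ms,
    correct, and the optional grouping column named by
    ``config.boundary_by``) or a {condition: (rts, correct)} mapping.  When a
    grouping column is given, each group receives its own boundary while all
    other parameters are shared across groups, mirroring designs where only
    response caution changes between instruction blocks.
    """
    rng = rng or np.random.default_rng()
    if isinstance(trials, pd.DataFrame):
        group_col = config.boundary_by
        if group_col is not None and group_col in trials.columns:
            groups = {
                str(g): trials_from_frame(sub)
                for g, sub in trials.groupby(group_col, sort=False)
            }
        else:
            groups = {"all": trials_from_frame(trials)}
    else:
        groups = {"all": dict(trials)}
    group_names = list(groups)

    summaries = {
        g: fit_summary(data, config.quantile_probs, config.min_errors)
        for g, data in groups.items()
    }
    for g, data in groups.items():
        for cond, d in data.items():
            rts, _ = _as_rt_correct(d)
            if rts.size < 200:
                warnings.warn(
                    f"condition {cond!r} (group {g!r}) has {rts.size} trials; "
                    "at least 200 per condition are recommended for stable "
                    "estimation",
                    stacklevel=2,
                )

    # search vector: shared params then one boundary per group; degenerate
    # (lo == hi) entries are fixed and excluded from the search
    spec: list[tuple[str, str | None, float, float]] = [
        (name, None, *getattr(bounds, name)) for name in SHARED_PARAMS
    ]
    spec += [(f"boundary", g, *bounds.boundary) for g in group_names]
    free_idx = [i for i, (_, _, lo, hi) in enumerate(spec) if lo < hi]
    fixed = {i: spec[i][2] for i in range(len(spec)) if i not in free_idx}

    seed = int(rng.integers(2**31 - 1))
    sim_seed = int(rng.integers(2**31 - 1))

    def unpack(x: np.ndarray) -> tuple[dict[str, float], dict[str, float]]:
        full = np.empty(len(spec))
        for j, i in enumerate(free_idx):
            full[i] = x[j]
        for i, v in fixed.items():
            full[i] = v
        shared = {name: full[i] for i, (name, g, *_r) in enumerate(spec) if g is None}
        boundaries = {g: full[i] for i, (name, g, *_r) in enumerate(spec) if g is not None}
        return shared, boundaries

    def de_objective(x: np.ndarray) -> float:
        shared, boundaries = unpack(x)
        total = 0.0
        for g in group_names:
            params = _make_params({**shared, "boundary": boundaries[g]})
            total += objective(
                params,
                summaries[g],
                config.n_sim,
                np.random.default_rng(sim_seed),
                quantile_probs=config.quantile_probs,
                epsilon=config.epsilon,
            )
        return total

    de_bounds = [(spec[i][2], spec[i][3]) for i in free_idx]
    result = optimize.differential_evolution(
        de_objective,
        de_bounds,
        seed=seed,
        popsize=config.popsize,
        maxiter=config.maxiter,
        tol=config.tol,
        mutation=config.mutation,
        recombination=config.recombination,
        polish=False,
        init="sobol",
        updating="immediate",
    )
    if not math.isfinite(result.fun):
        raise RuntimeError(f"fit failed: non-finite objective ({result.message})")
    shared, boundaries = unpack(result.x)
    params = _make_params({**shared, "boundary": boundaries[group_names[0]]})
    return FitResult(
        params=params,
        boundaries={g: float(b) for g, b in boundaries.items()},
        objective=float(result.fun),
        n_evaluations=int(result.nfev),
        converged=bool(result.success),
        seed=seed,
    )


def parameter_recovery(
    generating: Sequence[DMCParameters],
    n_trials_per_condition: int,
    bounds: FitBounds = FitBounds(),
    config: FitConfig = FitConfig(),
    rng: np.random.Generator | None = None,
    conditions: Sequence[str] = ("congruent", "incongruent"),
) -> RecoveryReport:
    """Simulate each generating parameter set, refit, and correlate the
    recovered with the generating values parameter by parameter."""
    if len(generating) < 2:
        raise ValueError("need at least 2 generating parameter sets")
    rng = rng or np.random.default_rng()
    recovered: list[FitResult | None] = []
    n_failed = 0
    for p in generating:
        trials = {
            c: simulate_condition(c, n_trials_per_condition, p, rng) for c in conditions
        }
        try:
            recovered.append(fit_participant(trials, bounds, config, rng))
        except RuntimeError:
            recovered.append(None)
            n_failed += 1
    correlations: dict[str, float] = {}
    zero_variance: list[str] = []
    ok = [(g, f) for g, f in zip(generating, recovered) if f is not None]
    for name in RECOVERY_PARAMS:
        gen = np.array([getattr(g, name) for g, _ in ok])
        fit = np.array([getattr(f.params, name) for _, f in ok])
        if np.ptp(gen) == 0 or np.ptp(fit) == 0:
            correlations[name] = math.nan
            zero_variance.append(name)
        else:
            correlations[name] = float(stats.pearsonr(gen, fit).statistic)
    return RecoveryReport(
        correlations=correlations,
        n_participants=len(generating),
        n_trials_per_condition=n_trials_per_condition,
        n_failed=n_failed,
        zero_variance=zero_variance,
    )


def evaluate_fit(
    observed: Sequence[Mapping[str, object]],
    fitted: Sequence[DMCParameters],
    n_sim: int,
    rng: np.random.Generator | None = None,
    quantile_probs: Sequence[float] = (0.25, 0.5, 0.75),
) -> pd.DataFrame:
    """Posterior-predictive fit quality across participants.

    For each participant, simulate ``n_sim`` trials per condition from the
    fitted parameters and compare observed against simulated accuracy and
    RT quantiles (correct and error RTs separately).  Returns the Pearson
    correlation across participants for every condition x correctness x
    statistic cell; cells where either side is constant or undefined for
    some participants are reported with the available pairs.
    """
    if len(observed) != len(fitted):
        raise ValueError("observed and fitted must align")
    if len(observed) < 3:
        raise ValueError("need at least 3 participants")
    rng = rng or np.random.default_rng()
    probs = tuple(quantile_probs)

    def summarize(data) -> dict:
        rts, correct = _as_rt_correct(data)
        out = {"accuracy": float(correct.mean())}
        for is_c, label in ((True, "correct"), (False, "error")):
            sub = rts[correct == is_c]
            for p in probs:
                out[f"{label}_q{int(p * 100)}"] = (
                    float(np.quantile(sub, p)) if sub.size else math.nan
                )
        return out

    rows = []
    for i, (obs, params) in enumerate(zip(observed, fitted)):
        for cond, data in obs.items():
            o = summarize(data)
            s = summarize(simulate_condition(cond, n_sim, params, rng))
            for key in o:
                rows.append(
                    {"participant": i, "condition": cond, "stat": key,
                     "observed": o[key], "simulated": s[key]}
                )
    df = pd.DataFrame(rows)
    out_rows = []
    for (cond, stat), sub in df.groupby(["condition", "stat"], sort=False):
        sub = sub.dropna()
        r = math.nan
        if len(sub) >= 3 and np.ptp(sub.observed) > 0 and np.ptp(sub.simulated) > 0:
            r = float(stats.pearsonr(sub.observed, sub.simulated).statistic)
        out_rows.append(
            {"condition": cond, "stat": stat, "pearson_r": r, "n_participants": len(sub)}
        )
    return pd.DataFrame(out_rows)
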