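"""Generative diffusion model for conflict tasks (DMC).

The DMC extends the standard two-boundary drift-diffusion model with a
transient "automatic" evidence contribution from the task-irrelevant stimulus
feature.  The mean automatic activation follows a rescaled gamma function

    E[X_a(t)] = A * exp(-t / tau) * (t * e / (tau * (a - 1)))**(a - 1)

which peaks at value ``A`` (amplitude) at time ``tau * (a - 1)`` and then
decays.  Its time derivative is added to (congruent) or subtracted from
(incongruent) a constant controlled drift ``mu_c``; neutral trials carry the
controlled drift alone.  Accumulation starts from a symmetric-beta distributed
start point between the boundaries ``-b`` and ``+b`` and is integrated by
Euler-Maruyama with within-trial noise ``sigma``.  A uniform nondecision time
is added to the first-passage time to produce the observed RT.

This module owns the parameter container, the activation/drift functions, the
stochastic trial simulator, and the two standard distributional summaries of
conflict-task data: conditional accuracy functions (CAFs) and delta plots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, asdict
from typing import Iterator, Sequence

import numpy as np

from ._kernels import simulate_first_passage

__all__ = [
    "CONDITIONS",
    "DMCParameters",
    "TrialOutcome",
    "TrialBatch",
    "CAF",
    "DeltaFunction",
    "automatic_activation",
    "automatic_drift",
    "superimposed_drift",
    "sample_start_point",
    "sample_nondecision",
    "simulate_trial",
    "simulate_condition",
    "compute_caf",
    "compute_delta",
]

CONDITIONS = ("congruent", "incongruent", "neutral")

_MAX_KERNEL_SEED = 2**31 - 1


@dataclass(frozen=True)
class DMCParameters:
    """One participant's generative parameter vector.

    Units: evidence in arbitrary "evidence units", time in milliseconds.

    amplitude
        Peak of the automatic activation (A), evidence units.
    time_to_peak
        Scale of the automatic-activation gamma (tau), ms; equals the peak
        latency when ``gamma_shape`` is 2.
    gamma_shape
        Shape of the automatic-activation gamma (a); fixed at 2 by convention.
    drift
        Controlled-route drift rate (mu_c), evidence units per ms.
    boundary
        Upper decision boundary (b); the decision field spans -b..+b.
        Reported "boundary separation" is 2*b.
    nondecision_mean / nondecision_sd
        Mean (Ter) and SD (TerSD) of the uniform nondecision time, ms.
    start_shape
        Shape of the symmetric beta start-point distribution (alpha >= 1);
        ``math.inf`` degenerates to a fixed start at 0.
    diffusion_constant
        Within-trial noise sigma, evidence units per sqrt(ms); fixed at 4.
    dt / max_time
        Euler integration step and simulation horizon, ms.
    """

    amplitude: float = 27.5
    time_to_peak: float = 72.0
    gamma_shape: float = 2.0
    drift: float = 0.5
    boundary: float = 62.5
    nondecision_mean: float = 335.0
    nondecision_sd: float = 0.0
    start_shape: float = 2.5
    diffusion_constant: float = 4.0
    dt: float = 1.0
    max_time: float = 3000.0

    def __post_init__(self) -> None:
        checks = (
            (self.amplitude >= 0, "amplitude must be >= 0"),
            (self.time_to_peak > 0, "time_to_peak must be > 0"),
            (self.gamma_shape > 1, "gamma_shape must be > 1"),
            (self.boundary > 0, "boundary must be > 0"),
            (self.nondecision_mean >= 0, "nondecision_mean must be >= 0"),
            (self.nondecision_sd >= 0, "nondecision_sd must be >= 0"),
            (self.start_shape >= 1, "start_shape must be >= 1"),
            (self.diffusion_constant >= 0, "diffusion_constant must be >= 0"),
            (self.dt > 0, "dt must be > 0"),
            (self.max_time > self.dt, "max_time must exceed dt"),
        )
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)
        for name, value in asdict(self).items():
            if name != "start_shape" and not math.isfinite(value):
                raise ValueError(f"{name} must be finite")

    @property
    def boundary_separation(self) -> float:
        """Boundary separation as conventionally reported (upper boundary x 2)."""
        return 2.0 * self.boundary

    def with_(self, **kwargs) -> "DMCParameters":
        """Return a copy with some fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict[str, float]:
        """Flat key-value form suitable for YAML/JSON configs."""
        return asdict(self)

    @classmethod
    def from_dict(cls, values: dict) -> "DMCParameters":
        """Inverse of :meth:`to_dict`; unknown keys are rejected."""
        return cls(**values)


@dataclass(frozen=True)
class TrialOutcome:
    """A single simulated trial."""

    rt: float
    correct: bool
    condition: str
    decision_time: float
    censored: bool


@dataclass
class TrialBatch:
    """A vectorized batch of simulated trials from one condition.

    Censored trials (no boundary reached within ``max_time``) keep
    ``decision_time == max_time`` and should be excluded from behavioural
    summaries; all summary functions here do so.
    """

    condition: str
    rt: np.ndarray
    decision_time: np.ndarray
    correct: np.ndarray
    censored: np.ndarray

    def __len__(self) -> int:
        return self.rt.shape[0]

    def __iter__(self) -> Iterator[TrialOutcome]:
        for i in range(len(self)):
            yield TrialOutcome(
                rt=float(self.rt[i]),
                correct=bool(self.correct[i]),
                condition=self.condition,
                decision_time=float(self.decision_time[i]),
                censored=bool(self.censored[i]),
            )

    @property
    def n_censored(self) -> int:
        return int(self.censored.sum())

    def valid(self) -> "TrialBatch":
        """Drop censored trials."""
        keep = ~self.censored
        return TrialBatch(
            condition=self.condition,
            rt=self.rt[keep],
            decision_time=self.decision_time[keep],
            correct=self.correct[keep],
            censored=self.censored[keep],
        )

    def accuracy(self) -> float:
        v = self.valid()
        if len(v) == 0:
            return math.nan
        return float(v.correct.mean())

    def correct_rts(self) -> np.ndarray:
        v = self.valid()
        return v.rt[v.correct]

    def error_rts(self) -> np.ndarray:
        v = self.valid()
        return v.rt[~v.correct]


@dataclass(frozen=True)
class CAF:
    """Conditional accuracy function: accuracy within RT quantile bins."""

    bin_edges: np.ndarray
    accuracy_per_bin: np.ndarray

    def __post_init__(self) -> None:
        acc = np.asarray(self.accuracy_per_bin, dtype=float)
        if np.any((acc < 0) | (acc > 1)):
            raise ValueError("accuracy_per_bin must lie in [0, 1]")
        if len(self.bin_edges) != len(acc) + 1:
            raise ValueError("bin_edges must have one more entry than bins")


@dataclass(frozen=True)
class DeltaFunction:
    """Incongruent-minus-congruent RT differences at matched quantiles."""

    quantile_probs: np.ndarray
    delta_values: np.ndarray
    mean_rts: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.quantile_probs) != len(self.delta_values):
            raise ValueError("quantile_probs and delta_values lengths differ")


# ---------------------------------------------------------------------------
# Deterministic model components
# ---------------------------------------------------------------------------


def _check_time(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)) or np.any(t < 0):
        raise ValueError("t must be finite and >= 0")
    return t


def automatic_activation(t, params: DMCParameters):
    """Mean automatic activation E[X_a(t)] of the gamma-shaped conflict route.

    Vectorized over ``t``; returns 0 at t = 0 and peaks at ``amplitude`` at
    t = time_to_peak * (gamma_shape - 1).
    """
    t = _check_time(t)
    a = params.gamma_shape
    tau = params.time_to_peak
    scaled = np.where(t > 0, t * math.e / (tau * (a - 1.0)), 0.0)
    out = params.amplitude * np.exp(-t / tau) * scaled ** (a - 1.0)
    return out if out.ndim else float(out)


def automatic_drift(t, params: DMCParameters):
    """Time derivative of the mean automatic activation.

    d/dt E[X_a(t)] = E[X_a(t)] * ((a-1)/t - 1/tau); at t = 0 the analytic
    limit is A*e/tau for shape 2, 0 for shape > 2.
    """
    t = _check_time(t)
    a = params.gamma_shape
    tau = params.time_to_peak
    with np.errstate(divide="ignore", invalid="ignore"):
        deriv = automatic_activation(t, params) * ((a - 1.0) / t - 1.0 / tau)
    if a == 2.0:
        limit = params.amplitude * math.e / tau
    elif a > 2.0:
        limit = 0.0
    else:  # 1 < a < 2: derivative diverges at the origin
        limit = math.inf
    deriv = np.where(np.asarray(t) == 0.0, limit, deriv)
    return deriv if deriv.ndim else float(deriv)


def superimposed_drift(t, condition: str, params: DMCParameters):
    """Total mean drift: controlled drift plus the signed automatic component.

    Congruent trials add the automatic derivative, incongruent trials subtract
    it, neutral trials carry the controlled drift alone.
    """
    t = _check_time(t)
    if condition == "congruent":
        out = params.drift + automatic_drift(t, params)
    elif condition == "incongruent":
        out = params.drift - automatic_drift(t, params)
    elif condition == "neutral":
        out = np.full_like(t, params.drift) if t.ndim else params.drift
    else:
        raise ValueError(f"unknown condition {condition!r}")
    return out if np.ndim(out) else float(out)


def sample_start_point(params: DMCParameters, rng: np.random.Generator, size=None):
    """Draw start points b*(2*Beta(alpha, alpha) - 1), symmetric on (-b, +b).

    ``start_shape = inf`` degenerates to a fixed start at 0.
    """
    if not math.isfinite(params.start_shape):
        return np.zeros(size if size is not None else ()) if size is not None else 0.0
    beta = rng.beta(params.start_shape, params.start_shape, size=size)
    return params.boundary * (2.0 * beta - 1.0)


def sample_nondecision(params: DMCParameters, rng: np.random.Generator, size=None):
    """Uniform nondecision times with mean Ter and SD TerSD, truncated at 0.

    The uniform half-width is sqrt(3)*TerSD so that the SD parameterization
    matches the distribution actually sampled.
    """
    if params.nondecision_sd == 0.0:
        if size is None:
            return params.nondecision_mean
        return np.full(size, params.nondecision_mean)
    half = math.sqrt(3.0) * params.nondecision_sd
    draws = rng.uniform(params.nondecision_mean - half, params.nondecision_mean + half, size=size)
    return np.maximum(draws, 0.0)


# ---------------------------------------------------------------------------
# Stochastic simulation
# ---------------------------------------------------------------------------


def _drift_profile(condition: str, params: DMCParameters, n_steps: int) -> np.ndarray:
    times = np.arange(n_steps, dtype=float) * params.dt
    return np.asarray(superimposed_drift(times, condition, params), dtype=float)


def simulate_condition(
    condition: str,
    n_trials: int,
    params: DMCParameters,
    rng: np.random.Generator,
) -> TrialBatch:
    """Simulate ``n_trials`` trials of one condition.

    Euler-Maruyama integration X(t+dt) = X(t) + v(t)*dt + sigma*sqrt(dt)*N(0,1)
    from a random start point, absorbed at +/-b (upper = correct).  Trials not
    absorbed by ``max_time`` are flagged censored.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    n_steps = int(round(params.max_time / params.dt))
    profile = _drift_profile(condition, params, n_steps)
    starts = np.asarray(sample_start_point(params, rng, size=n_trials), dtype=float)
    kernel_seed = int(rng.integers(_MAX_KERNEL_SEED))
    decision_steps, correct, censored = simulate_first_passage(
        profile,
        params.boundary,
        params.diffusion_constant,
        params.dt,
        starts,
        kernel_seed,
    )
    decision_time = decision_steps.astype(float) * params.dt
    ter = np.asarray(sample_nondecision(params, rng, size=n_trials), dtype=float)
    rt = decision_time + ter
    return TrialBatch(
        condition=condition,
        rt=rt,
        decision_time=decision_time,
        correct=correct,
        censored=censored,
    )


def simulate_trial(
    condition: str, params: DMCParameters, rng: np.random.Generator
) -> TrialOutcome:
    """Simulate a single trial (convenience wrapper over the batch simulator)."""
    batch = simulate_condition(condition, 1, params, rng)
    return next(iter(batch))


# ---------------------------------------------------------------------------
# Distributional summaries
# ---------------------------------------------------------------------------


def _as_rt_correct(outcomes) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(outcomes, TrialBatch):
        v = outcomes.valid()
        return v.rt, v.correct
    outcomes = [o for o in outcomes if not o.censored]
    rt = np.array([o.rt for o in outcomes], dtype=float)
    correct = np.array([o.correct for o in outcomes], dtype=bool)
    return rt, correct


def compute_caf(outcomes, n_bins: int = 5) -> CAF:
    """Conditional accuracy function over equal-count RT quantile bins.

    All (correct and error) non-censored trials are ranked by RT and split
    into ``n_bins`` equal-count bins; the CAF is the accuracy within each bin.
    """
    rt, correct = _as_rt_correct(outcomes)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if rt.size < n_bins:
        raise ValueError("fewer outcomes than bins")
    order = np.argsort(rt, kind="stable")
    acc = np.array([chunk.mean() for chunk in np.array_split(correct[order], n_bins)])
    return CAF(bin_edges=np.linspace(0.0, 1.0, n_bins + 1), accuracy_per_bin=acc)


def compute_delta(
    congruent,
    incongruent,
    quantile_probs: Sequence[float] = (0.1, 0.3, 0.5, 0.7, 0.9),
) -> DeltaFunction:
    """Delta function: incongruent minus congruent correct-RT quantiles."""
    probs = np.asarray(quantile_probs, dtype=float)
    rt_c, correct_c = _as_rt_correct(congruent)
    rt_i, correct_i = _as_rt_correct(incongruent)
    cc, ci = rt_c[correct_c], rt_i[correct_i]
    if cc.size == 0 or ci.size == 0:
        raise ValueError("each condition needs at least one correct trial")
    qc = np.quantile(cc, probs)
    qi = np.quantile(ci, probs)
    return DeltaFunction(
        quantile_probs=probs, delta_values=qi - qc, mean_rts=(qi + qc) / 2.0
    )
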