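"""Multilevel random-effects meta-analysis of cross-task correlations.

Correlations (Spearman's rho across participants for one task pair and one
measure) are pooled on the Fisher-z scale, where the sampling variance of a
transformed correlation from n participants is approximately 1/(n - 3).  The
pooling model is a two-level normal model: effects from the same dataset
share a dataset-level random intercept (variance tau2_between), and each
effect additionally carries its own heterogeneity (tau2_within),

    z_i = mu + u_{dataset(i)} + w_i + e_i,
    u ~ N(0, tau2_between),  w ~ N(0, tau2_within),  e_i ~ N(0, v_i).

Variance components are estimated by restricted maximum likelihood; the
pooled estimate is the GLS mean with a normal-approximation CI, back-
transformed to the correlation scale.  Heterogeneity is summarized by the
Higgins-Thompson I^2 using the typical sampling variance computed from the
inverse-variance weights.  A sensitivity power analysis reports the smallest
average correlation detectable at a given power for a planned k, average n,
and assumed I^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "MetaEffect",
    "MetaResult",
    "spearman_rho",
    "fisher_z",
    "fisher_z_inverse",
    "meta_random_effects",
    "i_squared",
    "sensitivity_power",
]


@dataclass(frozen=True)
class MetaEffect:
    """One correlation entering the meta-analysis."""

    rho: float
    n: int
    dataset_id: str
    measure: str = ""

    def __post_init__(self) -> None:
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        if self.n < 4:
            raise ValueError("n must be >= 4")

    @property
    def z(self) -> float:
        return fisher_z(self.rho)

    def sampling_variance(self, spearman_adjust: bool = False) -> float:
        v = 1.0 / (self.n - 3)
        return 1.06 * v if spearman_adjust else v


@dataclass(frozen=True)
class MetaResult:
    """Pooled correlation with variance components and heterogeneity."""

    pooled_r: float
    ci_low: float
    ci_high: float
    p_value: float
    tau2_between_dataset: float
    tau2_within: float
    i_squared: float
    k: int
    pooled_z: float
    se_z: float
    typical_sampling_variance: float

    @property
    def tau2_total(self) -> float:
        return self.tau2_between_dataset + self.tau2_within


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and of equal length")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    rho = stats.spearmanr(x, y).statistic
    if not math.isfinite(rho):
        raise ValueError("Spearman correlation undefined (zero rank variance)")
    return float(rho)


def fisher_z(r: float) -> float:
    """Variance-stabilizing transform z = atanh(r)."""
    if not abs(r) < 1:
        raise ValueError("|r| must be < 1")
    return math.atanh(r)


def fisher_z_inverse(z: float) -> float:
    """Back-transform tanh(z)."""
    return math.tanh(z)


def _reml_neg2ll(
    tau2: tuple[float, float], y: np.ndarray, v: np.ndarray, clusters: np.ndarray
) -> float:
    """-2 x restricted log-likelihood of the two-level model (constants dropped)."""
    tau2_b, tau2_w = tau2
    marg = v + tau2_w + tau2_b  # diagonal of V
    # V = diag(v + tau2_w) + tau2_b * Z Z^T with Z the cluster indicator;
    # build V explicitly (k is small in meta-analytic applications)
    V = np.diag(v + tau2_w) + tau2_b * (clusters[:, None] == clusters[None, :])
    sign, logdet = np.linalg.slogdet(V)
    if sign <= 0:
        return np.inf
    Vinv = np.linalg.inv(V)
    one = np.ones_like(y)
    xvx = one @ Vinv @ one
    mu = (one @ Vinv @ y) / xvx
    resid = y - mu
    return float(logdet + math.log(xvx) + resid @ Vinv @ resid)


def meta_random_effects(
    effects: Sequence[MetaEffect],
    *,
    spearman_adjust: bool = False,
    ci_level: float = 0.95,
) -> MetaResult:
    """Pool correlations with a two-level REML random-effects model.

    With every effect in its own cluster the between- and within-level
    variances are not separately identified and only their sum matters; the
    fit then coincides with the standard single-level REML random-effects
    model.
    """
    effects = list(effects)
    k = len(effects)
    if k < 2:
        raise ValueError("need at least 2 effects")
    y = np.array([e.z for e in effects])
    v = np.array([e.sampling_variance(spearman_adjust) for e in effects])
    _, clusters = np.unique([e.dataset_id for e in effects], return_inverse=True)

    obj = lambda t2: _reml_neg2ll((t2[0], t2[1]), y, v, clusters)
    best = None
    scale = max(float(np.var(y, ddof=1)), float(v.mean()))
    for x0 in ([0.0, 0.0], [scale / 2, scale / 2], [0.0, scale], [scale, 0.0]):
        res = optimize.minimize(
            obj, x0, method="L-BFGS-B", bounds=[(0.0, None), (0.0, None)]
        )
        if best is None or res.fun < best.fun:
            best = res
    tau2_b, tau2_w = (max(0.0, float(t)) for t in best.x)

    V = np.diag(v + tau2_w) + tau2_b * (clusters[:, None] == clusters[None, :])
    Vinv = np.linalg.inv(V)
    one = np.ones(k)
    xvx = float(one @ Vinv @ one)
    mu = float((one @ Vinv @ y) / xvx)
    se = math.sqrt(1.0 / xvx)
    zcrit = stats.norm.ppf(0.5 + ci_level / 2.0)
    p = 2.0 * stats.norm.sf(abs(mu) / se)

    w = 1.0 / v
    v_typical = (k - 1) * w.sum() / (w.sum() ** 2 - (w**2).sum())
    tau2_total = tau2_b + tau2_w
    i2 = 100.0 * tau2_total / (tau2_total + v_typical) if tau2_total > 0 else 0.0

    return MetaResult(
        pooled_r=fisher_z_inverse(mu),
        ci_low=fisher_z_inverse(mu - zcrit * se),
        ci_high=fisher_z_inverse(mu + zcrit * se),
        p_value=float(p),
        tau2_between_dataset=tau2_b,
        tau2_within=tau2_w,
        i_squared=float(i2),
        k=k,
        pooled_z=mu,
        se_z=se,
        typical_sampling_variance=float(v_typical),
    )


def i_squared(result: MetaResult) -> float:
    """Higgins-Thompson I^2 (percent) of a fitted meta-analysis.

    I^2 = 100 * tau2_total / (tau2_total + v_typical), with v_typical the
    typical within-study sampling variance computed from the weights.
    """
    t2 = result.tau2_total
    if t2 <= 0:
        return 0.0
    return 100.0 * t2 / (t2 + result.typical_sampling_variance)


def sensitivity_power(
    k: int,
    n_avg: float,
    i2: float,
    alpha: float = 0.05,
    target_power: float = 0.80,
    *,
    grid: float | None = 0.01,
) -> float:
    """Smallest average correlation detectable with the target power.

    On the Fisher-z scale the pooled estimate of a random-effects
    meta-analysis of k effects with average sample size n_avg has variance
    (v + tau2)/k, where v = 1/(n_avg - 3) and the heterogeneity variance is
    set from the assumed I^2 via tau2 = v * I2/(100 - I2).  The upper-tail
    power for a true correlation r under a two-sided alpha-level test is
    Phi(atanh(r)/SE - z_{1-alpha/2}) (the lower tail is negligible), so the
    minimal detectable correlation solves

        atanh(r) = (z_{1-alpha/2} + z_{power}) * SE.

    The result is reported at ``grid`` resolution (default 0.01, the
    conventional reporting precision for correlations); pass ``grid=None``
    for the exact solution.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_avg < 5:
        raise ValueError("n_avg must be >= 5")
    if not 0 <= i2 < 100:
        raise ValueError("i2 must lie in [0, 100)")
    if not 0 < alpha < 1 or not 0 < target_power < 1:
        raise ValueError("alpha and target_power must lie in (0, 1)")
    v = 1.0 / (n_avg - 3.0)
    tau2 = v * i2 / (100.0 - i2)
    se = math.sqrt((v + tau2) / k)
    z_needed = (stats.norm.ppf(1.0 - alpha / 2.0) + stats.norm.ppf(target_power)) * se
    r = math.tanh(z_needed)
    if grid is not None:
        r = round(r / grid) * grid
    return float(r)
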