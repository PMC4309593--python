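"""Misclassification correction for incomplete linkage disequilibrium.

A rare mutation that arose once sits on a founder haplotype that is
perfectly specific (non-founder carriers do not exist) but imperfectly
sensitive: only a proportion ``t = P(mutation | founder haplotype)`` of
founder copies carry it.  An analysis classifying individuals by the
haplotype instead of the mutation therefore dilutes the carrier group with
``1 - t`` mutation-free founder carriers, biasing relative risks toward the
null.  Writing a, b for disease risks of mutation carriers/non-carriers and
f, g for risks of haplotype carriers/non-carriers, f = a*t + b*(1 - t) and
g = b, so the observed ratio w = f/g relates to the true ratio v = a/b by
w = t*v + 1 - t, hence::

    v = 1 + (w - 1) / t

Carrier *frequencies* estimated by imputation are instead corrected by the
imputation r² (multiplicative), and cumulative-risk curves pointwise by
a(age) = g(age) + (f(age) - g(age)) / t.  Confidence intervals for v come
from a parametric bootstrap over the effect (normal on the log scale) and
the sensitivity estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import ConcordanceTable, RiskCurve


@dataclass
class CorrectionParams:
    """Sensitivity t and imputation r², each with a standard error.

    These are distinct quantities: relative-risk correction uses t (the
    proportion of predicted carriers confirmed to carry the mutation), while
    frequency adjustment uses the imputation r².
    """

    t: float
    r2: float
    se_t: float = 0.0
    se_r2: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.t <= 1:
            raise ValueError("t must lie in (0, 1]")
        if not 0 < self.r2 <= 1:
            raise ValueError("r2 must lie in (0, 1]")

    @classmethod
    def from_validation(cls, table: ConcordanceTable, r2: float, **kw) -> "CorrectionParams":
        """t as the positive predictive value tp/(tp+fp) of a validation table."""
        denom = table.tp + table.fp
        if denom == 0:
            raise ValueError("no predicted carriers in validation table")
        return cls(t=table.tp / denom, r2=r2, **kw)


def correct_relative_risk(w: float, t: float) -> float:
    """Adjusted relative risk v = 1 + (w - 1)/t for sensitivity t."""
    if w <= 0:
        raise ValueError("w must be positive")
    if not 0 < t <= 1:
        raise ValueError("t must lie in (0, 1]")
    return 1.0 + (w - 1.0) / t


def correct_frequency(freq_imputed: float, r2: float) -> float:
    """Imputation-based carrier frequency multiplied by the imputation r²."""
    if not 0 <= freq_imputed <= 1 or not 0 <= r2 <= 1:
        raise ValueError("inputs must lie in [0, 1]")
    return freq_imputed * r2


def correct_risk_curve(f: RiskCurve, g: RiskCurve, t: float) -> RiskCurve:
    """Corrected carrier cumulative-risk curve a = g + (f - g)/t.

    ``f`` is the observed haplotype-carrier curve, ``g`` the non-carrier
    curve (which is unchanged by the correction, since non-haplotype
    carriers are never mutation carriers).  Values are clipped to [0, 1]
    with a warning when clipping occurs; callers needing the unclipped
    values can recompute ``g.risk + (f.risk - g.risk)/t`` directly.
    """
    if not 0 < t <= 1:
        raise ValueError("t must lie in (0, 1]")
    if f.age.shape != g.age.shape or np.any(f.age != g.age):
        raise ValueError("risk curves must share a common age grid")
    a = g.risk + (f.risk - g.risk) / t
    if np.any(a > 1.0) or np.any(a < 0.0):
        warnings.warn("corrected cumulative risk clipped to [0, 1]")
        a = np.clip(a, 0.0, 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return RiskCurve(age=f.age.copy(), risk=a, label=f"{f.label} (LD-adjusted)")


def bootstrap_ci(
    beta_hat: float,
    se_beta: float,
    t_hat: float,
    se_t: float,
    n_iter: int = 1_000_000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Parametric bootstrap CI for the corrected relative risk v.

    Draws the effect on the log scale, beta* ~ N(beta_hat, se_beta), and the
    sensitivity t* ~ N(t_hat, se_t) truncated to (1e-6, 1], forms
    v* = 1 + (exp(beta*) - 1)/t*, and returns the percentile interval.
    Deterministic under the seed.
    """
    if se_beta < 0 or se_t < 0:
        raise ValueError("standard errors must be non-negative")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    beta = rng.normal(beta_hat, se_beta, size=n_iter) if se_beta > 0 else np.full(n_iter, beta_hat)
    if se_t > 0:
        t = rng.normal(t_hat, se_t, size=n_iter)
        t = np.clip(t, 1e-6, 1.0)
    else:
        t = np.full(n_iter, np.clip(t_hat, 1e-6, 1.0))
    v = 1.0 + (np.exp(beta) - 1.0) / t
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(v, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
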