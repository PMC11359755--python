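"""Calibration outlier screening via Q-residuals and Hotelling's T-squared.

A sample is suspicious either because it lies far from the latent
subspace (large Q, reconstruction residual) or far from the centre
within the subspace (large T-squared).  Control limits at a chosen
confidence level come from the classical F-distribution formula for
T-squared and, for Q, either the empirical calibration quantile
(default, distribution-free) or the Jackson-Mudholkar closed form.

The default combination rule requires a sample to exceed *both* limits
before it is flagged: conservative, removing fewer borderline samples.
Screening is a single pass; flagged samples are meant to be dropped from
the calibration set only, never from validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pls import PLS1, PLS1Results

__all__ = [
    "OutlierReport",
    "q_residuals",
    "hotelling_t2",
    "control_limits",
    "flag_outliers",
]

RULES = ("both_exceed", "either_exceeds")


def q_residuals(results: PLS1Results, X) -> np.ndarray:
    """Per-row squared distance from the model's latent subspace."""
    return results.q_residuals(X)


def hotelling_t2(results: PLS1Results, X) -> np.ndarray:
    """Per-row Mahalanobis-type distance within the latent subspace."""
    return results.hotelling_t2(X)


def t2_limit(n: int, n_lv: int, confidence: float) -> float:
    """F-distribution control limit for T-squared on calibration data."""
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie in (0, 1)")
    if n <= n_lv:
        raise ValueError(f"need n > n_lv for the T2 limit (n={n}, A={n_lv})")
    A = n_lv
    factor = A * (n - 1) * (n + 1) / (n * (n - A))
    return factor * stats.f.ppf(confidence, A, n - A)


def q_limit_empirical(q_cal: np.ndarray, confidence: float) -> float:
    """Empirical confidence-quantile of calibration Q residuals."""
    if not 0.0 < confidence <= 1.0:
        raise ValueError("confidence must lie in (0, 1]")
    return float(np.quantile(np.asarray(q_cal, dtype=float), confidence))

def q_limit_jackson_mudholkar(results: PLS1Results, X_cal, confidence: float) -> float:
    """Closed-form Q limit from the residual covariance spectrum."""
    X0 = (np.atleast_2d(np.asarray(X_cal, float)) - results.x_mean) / results.x_std
    T = X0 @ results.weights @ np.linalg.inv(
        results.x_loadings.T @ results.weights
    )
    E = X0 - T @ results.x_loadings.T
    n = E.shape[0]
    eig = np.linalg.eigvalsh(E.T @ E / (n - 1))
    eig = eig[eig > 1e-12 * max(eig.max(), 1e-300)]
    th1, th2, th3 = eig.sum(), np.sum(eig**2), np.sum(eig**3)
    if th1 <= 0 or th2 <= 0:
        return 0.0
    h0 = 1.0 - 2.0 * th1 * th3 / (3.0 * th2**2)
    if h0 <= 0:
        h0 = 1e-4
    z = stats.norm.ppf(confidence)
    term = (
        z * np.sqrt(2.0 * th2 * h0**2) / th1
        + 1.0
        + th2 * h0 * (h0 - 1.0) / th1**2
    )
    return float(th1 * term ** (1.0 / h0))


def control_limits(
    results: PLS1Results,
    X_cal,
    confidence: float = 0.95,
    q_method: str = "empirical",
) -> tuple[float, float]:
    """(q_limit, t2_limit) at the given confidence for the calibration set."""
    n = np.atleast_2d(np.asarray(X_cal)).shape[0]
    t2l = t2_limit(n, results.n_lv, confidence)
    if q_method == "empirical":
        ql = q_limit_empirical(results.q_residuals(X_cal), confidence)
    elif q_method == "jackson_mudholkar":
        ql = q_limit_jackson_mudholkar(results, X_cal, confidence)
    else:
        raise ValueError(f"unknown q_method {q_method!r}")
    return ql, t2l


@dataclass
class OutlierReport:
    """Screening outcome for one calibration set."""

    q_values: np.ndarray
    t2_values: np.ndarray
    q_limit: float
    t2_limit: float
    flags: np.ndarray
    rule: str
    confidence: float
    sample_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.q_values < 0) or np.any(self.t2_values < 0):
            raise ValueError("Q and T2 must be non-negative")
        expected = _combine(
            self.q_values > self.q_limit, self.t2_values > self.t2_limit, self.rule
        )
        if not np.array_equal(expected, self.flags):
            raise ValueError("flags inconsistent with rule and limits")

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())

    def to_frame(self) -> pd.DataFrame:
        ids = self.sample_ids or list(range(len(self.q_values)))
        return pd.DataFrame(
            {
                "sample_id": ids,
                "Q": self.q_values,
                "T2": self.t2_values,
                "q_limit": self.q_limit,
                "t2_limit": self.t2_limit,
                "flagged": self.flags,
            }
        )


def _combine(q_exceeds: np.ndarray, t2_exceeds: np.ndarray, rule: str) -> np.ndarray:
    if rule == "both_exceed":
        return q_exceeds & t2_exceeds
    if rule == "either_exceeds":
        return q_exceeds | t2_exceeds
    raise ValueError(f"unknown rule {rule!r}; expected one of {RULES}")


def flag_outliers(
    X,
    y,
    n_lv: int,
    confidence: float = 0.95,
    rule: str = "both_exceed",
    q_method: str = "empirical",
    sample_ids=None,
) -> OutlierReport:
    """Fit a PLS-1 model and screen its calibration rows in a single pass."""
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}; expected one of {RULES}")
    res = PLS1(y, X).fit(n_lv)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    q = res.q_residuals(X)
    t2 = res.hotelling_t2(X)
    ql, t2l = control_limits(res, X, confidence, q_method)
    flags = _combine(q > ql, t2 > t2l, rule)
    return OutlierReport(
        q_values=q,
        t2_values=t2,
        q_limit=ql,
        t2_limit=t2l,
        flags=flags,
        rule=rule,
        confidence=confidence,
        sample_ids=list(sample_ids) if sample_ids is not None else [],
    )
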