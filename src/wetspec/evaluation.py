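"""Splitting, cross-validation, latent-variable search and calibration metrics.

Splits are group-aware throughout: a farm/bunker (group) contributes
samples to exactly one side of the calibration/validation split and to
exactly one cross-validation fold, so that near-duplicate samples from
the same silage bunker can never leak between training and testing.

Metric conventions
------------------
bias   = mean(yhat - y)
rmse   = sqrt(mean((yhat - y)^2))
se     = sqrt(sum((e - bias)^2) / (n - 1))        (bias-corrected)
r2     = 1 - SSE/SST                               (not squared correlation)
rpd    = SD(y; n-1 denominator) / se
slope, intercept : least-squares fit of predicted on reference,
    yhat = slope * y + intercept.

These satisfy the identity se^2 = n (rmse^2 - bias^2) / (n - 1).

Calibrations are graded on two published tier schemes: a level-of-success
scale on R^2 (<0.80 not useful, 0.80-0.90 moderately successful,
0.90-0.95 successful, >=0.95 excellent) and an RPD application scale
(<2.0 very poor ... >=4.0 excellent), both implemented as half-open
step functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pls import PLS1, RankError

__all__ = [
    "SplitPlan",
    "EvaluationReport",
    "LVSearchResult",
    "group_split",
    "kfold_cv",
    "compute_metrics",
    "se_from_rmse_bias",
    "classify_success",
    "classify_rpd",
    "grid_search_lvs",
    "secv_metrics",
]


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


@dataclass
class SplitPlan:
    calibration_ids: list
    validation_ids: list
    cv_folds: list  # list of (train_ids, held_ids)
    seed: int


def group_split(sample_ids, groups, validation_fraction: float, seed: int) -> SplitPlan:
    """Assign whole groups to validation until its share first reaches the target.

    Groups are visited in seeded random order; the validation set grows by
    whole groups until it holds at least ``validation_fraction`` of the
    samples.  Deterministic given the seed.  ``cv_folds`` is left empty;
    fill it with :func:`kfold_cv`.
    """
    if not 0.0 < validation_fraction < 1.0:
        raise ValueError("validation_fraction must lie in (0, 1)")
    sample_ids = list(sample_ids)
    groups = np.asarray(groups)
    if len(sample_ids) != groups.size:
        raise ValueError("sample_ids and groups must align")
    uniq = pd.unique(groups)
    if uniq.size < 2:
        raise ValueError("need >= 2 distinct groups to split without leakage")
    rng = np.random.default_rng(seed)
    order = rng.permutation(uniq.size)
    target = validation_fraction * len(sample_ids)
    val_groups: set = set()
    n_val = 0
    for gi in order:
        if n_val >= target:
            break
        g = uniq[gi]
        val_groups.add(g)
        n_val += int(np.sum(groups == g))
    if len(val_groups) == uniq.size:  # keep at least one calibration group
        val_groups.discard(uniq[order[-1]])
    in_val = np.isin(groups, list(val_groups))
    return SplitPlan(
        calibration_ids=[s for s, v in zip(sample_ids, in_val) if not v],
        validation_ids=[s for s, v in zip(sample_ids, in_val) if v],
        cv_folds=[],
        seed=seed,
    )


def kfold_cv(calibration_ids, groups, k: int, seed: int) -> list:
    """Group-aware k-fold partition of the calibration set.

    Groups are shuffled, then greedily assigned (largest first) to the
    currently smallest fold, balancing sample counts while keeping each
    group intact.  Returns ``[(train_ids, held_ids), ...]``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    calibration_ids = list(calibration_ids)
    groups = np.asarray(groups)
    if len(calibration_ids) != groups.size:
        raise ValueError("calibration_ids and groups must align")
    uniq = pd.unique(groups)
    if uniq.size < k:
        raise ValueError(f"need >= k={k} groups for group-aware folds, have {uniq.size}")
    rng = np.random.default_rng(seed)
    shuffled = uniq[rng.permutation(uniq.size)]
    sizes = {g: int(np.sum(groups == g)) for g in shuffled}
    # stable sort by size descending preserves the seeded order among ties
    by_size = sorted(shuffled, key=lambda g: -sizes[g])
    fold_of: dict = {}
    fold_counts = [0] * k
    for g in by_size:
        f = int(np.argmin(fold_counts))
        fold_of[g] = f
        fold_counts[f] += sizes[g]
    folds = []
    assignment = np.array([fold_of[g] for g in groups])
    for f in range(k):
        held = [s for s, a in zip(calibration_ids, assignment) if a == f]
        train = [s for s, a in zip(calibration_ids, assignment) if a != f]
        folds.append((train, held))
    return folds


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    n: int
    rmse: float
    bias: float
    se: float
    r2: float
    slope: float
    intercept: float
    rpd: float
    secv: float | None = None
    r2cv: float | None = None
    rpdcv: float | None = None
    n_lv: int | None = None
    success_label: str | None = None
    class_label: str | None = None
    corr2: float | None = None  # squared Pearson correlation, auxiliary

    def __post_init__(self) -> None:
        if self.se < 0 or self.rpd < 0:
            raise ValueError("se and rpd must be non-negative")
        if self.rmse + 1e-12 < abs(self.bias):
            raise ValueError("rmse must be >= |bias|")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def compute_metrics(y_ref, y_pred, sd_reference: float | None = None) -> EvaluationReport:
    """Accuracy metrics for one prediction set; see the module docstring."""
    y = np.asarray(y_ref, dtype=float).ravel()
    yh = np.asarray(y_pred, dtype=float).ravel()
    if y.size != yh.size:
        raise ValueError("y_ref and y_pred lengths differ")
    n = y.size
    if n < 2:
        raise ValueError("need n >= 2")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(yh))):
        raise ValueError("non-finite values")
    e = yh - y
    bias = float(e.mean())
    rmse = float(np.sqrt(np.mean(e**2)))
    se = float(np.sqrt(np.sum((e - bias) ** 2) / (n - 1)))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("zero variance in reference values: r2/rpd undefined")
    r2 = 1.0 - float(np.sum(e**2)) / sst
    sd = sd_reference if sd_reference is not None else float(np.std(y, ddof=1))
    rpd = math.inf if se == 0 else sd / se
    slope, intercept = np.polyfit(y, yh, 1)
    cy = y - y.mean()
    cyh = yh - yh.mean()
    denom = np.sqrt(np.sum(cy**2) * np.sum(cyh**2))
    corr2 = float((np.sum(cy * cyh) / denom) ** 2) if denom > 0 else None
    return EvaluationReport(
        n=n,
        rmse=rmse,
        bias=bias,
        se=se,
        r2=r2,
        slope=float(slope),
        intercept=float(intercept),
        rpd=rpd,
        corr2=corr2,
    )


def se_from_rmse_bias(rmse: float, bias: float, n: int) -> float:
    """Bias-corrected standard error implied by RMSE, bias and n.

    se = sqrt(n (rmse^2 - bias^2) / (n - 1)); the identity linking the
    three error summaries reported for every calibration.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    # tolerate half-ulp violations (rmse == |bias| when errors are constant)
    if rmse < abs(bias) * (1.0 - 1e-9):
        raise ValueError("rmse must be >= |bias|")
    return math.sqrt(max(0.0, n * (rmse**2 - bias**2)) / (n - 1))


def secv_metrics(y_cal, cv_pred) -> tuple[float, float, float]:
    """(secv, r2cv, rpdcv) from pooled held-out cross-validation predictions."""
    cv_pred = np.asarray(cv_pred, dtype=float).ravel()
    if np.any(~np.isfinite(cv_pred)):
        raise ValueError("cross-validation predictions do not cover the calibration set")
    rep = compute_metrics(y_cal, cv_pred)
    return rep.se, rep.r2, rep.rpd


def classify_success(r2: float) -> str:
    """Level-of-success tier from R^2 (half-open boundaries on the left)."""
    if not np.isfinite(r2):
        raise ValueError("r2 must be finite")
    if r2 < 0.80:
        return "Not Useful"
    if r2 < 0.90:
        return "Moderately Successful"
    if r2 < 0.95:
        return "Successful"
    return "Excellent"


def classify_rpd(rpd: float) -> str:
    """RPD application tier (half-open boundaries on the left)."""
    if rpd < 0:
        raise ValueError("rpd must be non-negative")
    if rpd < 2.0:
        return "Very poor"
    if rpd < 2.5:
        return "Poor"
    if rpd < 3.0:
        return "Fair"
    if rpd < 3.5:
        return "Good"
    if rpd < 4.0:
        return "Very good"
    return "Excellent"


# ---------------------------------------------------------------------------
# Latent-variable grid search
# ---------------------------------------------------------------------------


@dataclass
class LVSearchResult:
    lvs: np.ndarray
    rmse_cal: np.ndarray
    rmse_cv: np.ndarray
    selected_lv: int
    criterion: str
    cv_predictions: np.ndarray = field(repr=False, default=None)  # at selected_lv
    warnings: list = field(default_factory=list)


def grid_search_lvs(
    X,
    y,
    cv_folds,
    max_lv: int = 20,
    criterion: str = "min",
) -> LVSearchResult:
    """Scan 1..max_lv latent variables under cross-validation.

    ``cv_folds`` is a list of (train_idx, held_idx) integer index pairs
    into the rows of X.  For each component count the calibration RMSE
    comes from the full-calibration fit and the CV RMSE from held-out
    predictions pooled over folds; each fold is fitted once at the
    largest feasible count and truncated.  ``criterion='min'`` picks the
    RMSE-CV argmin (ties toward fewer components); ``'one_se'`` picks the
    smallest count whose RMSE-CV is within one standard error (over
    folds) of the minimum.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    cap = min(max_lv, n - 1, X.shape[1])
    warns = []
    if cap < max_lv:
        warns.append(f"max_lv truncated from {max_lv} to {cap} by data size")

    def _fit_capped(Xs, ys, a_max):
        """Fit with as many components as the data admit, up to a_max."""
        a = min(a_max, Xs.shape[0] - 1, Xs.shape[1])
        while a >= 1:
            try:
                return PLS1(ys, Xs).fit(a)
            except RankError:
                a -= 1
        raise RankError("no latent variable could be extracted")

    full = _fit_capped(X, y, cap)
    if full.n_lv < cap:
        warns.append(f"calibration fit rank-limited at {full.n_lv} components")
        cap = full.n_lv
    lvs = np.arange(1, cap + 1)
    path = full.coef_path()
    rmse_cal = np.empty(cap)
    for a in lvs:
        b, b0 = path[a]
        rmse_cal[a - 1] = np.sqrt(np.mean((b0 + X @ b - y) ** 2))

    pooled = np.full((cap, n), np.nan)
    fold_rmse = np.full((cap, len(cv_folds)), np.nan)
    for f, (tr, he) in enumerate(cv_folds):
        tr = np.asarray(tr, dtype=int)
        he = np.asarray(he, dtype=int)
        res = _fit_capped(X[tr], y[tr], cap)
        if res.n_lv < cap:
            warns.append(f"fold {f} rank-limited at {res.n_lv} components")
        fpath = res.coef_path()
        for a in range(1, res.n_lv + 1):
            b, b0 = fpath[a]
            pred = b0 + X[he] @ b
            pooled[a - 1, he] = pred
            fold_rmse[a - 1, f] = np.sqrt(np.mean((pred - y[he]) ** 2))
        for a in range(res.n_lv + 1, cap + 1):  # truncated fold: reuse deepest
            pooled[a - 1, he] = pooled[res.n_lv - 1, he]
            fold_rmse[a - 1, f] = fold_rmse[res.n_lv - 1, f]
    if np.isnan(pooled).any():
        raise ValueError("cv_folds do not cover all calibration rows")
    rmse_cv = np.sqrt(np.nanmean((pooled - y) ** 2, axis=1))

    if criterion == "min":
        sel = int(lvs[np.argmin(rmse_cv)])  # argmin takes the first -> fewer LVs
    elif criterion == "one_se":
        i_min = int(np.argmin(rmse_cv))
        se_min = float(np.std(fold_rmse[i_min], ddof=1) / np.sqrt(len(cv_folds)))
        ok = np.flatnonzero(rmse_cv <= rmse_cv[i_min] + se_min)
        sel = int(lvs[ok[0]])
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return LVSearchResult(
        lvs=lvs,
        rmse_cal=rmse_cal,
        rmse_cv=rmse_cv,
        selected_lv=sel,
        criterion=criterion,
        cv_predictions=pooled[sel - 1].copy(),
        warnings=warns,
    )
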