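"""End-to-end calibration workflow.

One *stream* is an (instrument, scan mode) pair.  For each stream and
constituent the workflow is: resample to the harmonized grid (default
1454-2446 nm, 4 nm step) -> absorbance -> Savitzky-Golay first
derivative -> replicate averaging -> group-wise 90/10 split -> Q/T2
outlier screening of the calibration set -> latent-variable grid search
(1..20) under group-aware five-fold cross-validation -> final fit and
calibration/validation reports.

All randomness flows from one seed in the configuration; rerunning with
the same config and inputs reproduces every output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .diagnostics import OutlierReport, flag_outliers
from .evaluation import (
    EvaluationReport,
    LVSearchResult,
    classify_rpd,
    classify_success,
    compute_metrics,
    grid_search_lvs,
    group_split,
    kfold_cv,
    secv_metrics,
)
from .pls import PLS1, PLS1Results
from .preprocess import SGParams, apply_sg
from .spectra import (
    CONSTITUENTS,
    ReferenceTable,
    SpectraSet,
    aggregate_replicates,
    resample_to_grid,
    to_absorbance,
)

__all__ = [
    "PipelineConfig",
    "StreamCalibration",
    "preprocess_stream",
    "calibrate_stream",
    "run_calibrate",
    "run_validate",
    "best_per_constituent",
]

CAL_COLUMNS = [
    "Instrument", "Mode", "Variable", "RMSE", "Bias", "SE", "SECV",
    "R2", "R2CV", "RPD", "RPDCV", "LVs",
]
VAL_COLUMNS = [
    "Instrument", "Mode", "Variable", "RMSE", "Bias", "SE", "R2",
    "Slope", "Intercept", "RPD",
]


@dataclass
class PipelineConfig:
    """Parameters of the calibration workflow (defaults follow the study protocol)."""

    grid_start_nm: float = 1454.0
    grid_stop_nm: float = 2446.0
    grid_step_nm: float = 4.0
    sg: SGParams = field(default_factory=SGParams)  # window 4, polyorder 3, deriv 1
    replicate_policy: str = "mean"
    validation_fraction: float = 0.10
    cv_folds: int = 5
    seed: int = 0
    max_lv: int = 20
    recommended_lv_cap: int = 10
    lv_criterion: str = "min"
    outlier_screening: bool = True
    outlier_lv: int = 10
    outlier_confidence: float = 0.95
    outlier_rule: str = "both_exceed"
    constituents: tuple = CONSTITUENTS

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        kw = {}
        pre = doc.get("preprocess", {})
        if pre:
            kw["sg"] = SGParams(
                window=pre.get("window", 4),
                polyorder=pre.get("polyorder", 3),
                deriv=pre.get("deriv", 1),
                promote_even_window=pre.get("promote_even_window", False),
            )
            for k in ("grid_start_nm", "grid_stop_nm", "grid_step_nm",
                      "replicate_policy"):
                if k in pre:
                    kw[k] = pre[k]
        split = doc.get("split", {})
        for src, dst in (
            ("validation_fraction", "validation_fraction"),
            ("k", "cv_folds"),
            ("seed", "seed"),
        ):
            if src in split:
                kw[dst] = split[src]
        search = doc.get("search", {})
        for k in ("max_lv", "recommended_lv_cap", "lv_criterion"):
            if k in search:
                kw[k] = search[k]
        out = doc.get("outliers", {})
        for src, dst in (
            ("enabled", "outlier_screening"),
            ("n_lv", "outlier_lv"),
            ("confidence", "outlier_confidence"),
            ("rule", "outlier_rule"),
        ):
            if src in out:
                kw[dst] = out[src]
        if "constituents" in doc:
            kw["constituents"] = tuple(doc["constituents"])
        return cls(**kw)

    def provenance_hash(self) -> str:
        text = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def preprocess_stream(s: SpectraSet, cfg: PipelineConfig) -> SpectraSet:
    """Harmonized grid -> absorbance -> SG derivative -> replicate averaging."""
    s = resample_to_grid(s, cfg.grid_start_nm, cfg.grid_stop_nm, cfg.grid_step_nm)
    s = to_absorbance(s)
    s = apply_sg(s, cfg.sg)
    return aggregate_replicates(s, cfg.replicate_policy)


@dataclass
class StreamCalibration:
    """Everything produced by calibrating one stream x constituent."""

    instrument: str
    scan_mode: str
    constituent: str
    results: PLS1Results
    lv_search: LVSearchResult
    outlier_report: OutlierReport | None
    calibration_ids: list
    validation_ids: list
    n_removed: int
    cal_report: EvaluationReport
    seed: int

    def calibration_row(self) -> dict:
        r = self.cal_report
        return {
            "Instrument": self.instrument,
            "Mode": self.scan_mode,
            "Variable": self.constituent,
            "RMSE": r.rmse, "Bias": r.bias, "SE": r.se, "SECV": r.secv,
            "R2": r.r2, "R2CV": r.r2cv, "RPD": r.rpd, "RPDCV": r.rpdcv,
            "LVs": r.n_lv,
        }


def calibrate_stream(
    spectra: SpectraSet,
    refs: ReferenceTable,
    constituent: str,
    cfg: PipelineConfig,
    preprocessed: bool = False,
) -> StreamCalibration:
    """Run the full calibration protocol for one stream and constituent."""
    inst = str(spectra.meta["instrument"].iloc[0])
    mode = str(spectra.meta["scan_mode"].iloc[0])
    s = spectra if preprocessed else preprocess_stream(spectra, cfg)

    ids = s.meta["sample_id"].tolist()
    groups = s.meta["group"].to_numpy()
    plan = group_split(ids, groups, cfg.validation_fraction, cfg.seed)
    id_to_row = {sid: i for i, sid in enumerate(ids)}
    cal_ids = list(plan.calibration_ids)
    cal_idx = np.array([id_to_row[i] for i in cal_ids])
    y_all = refs.values_for(constituent, ids)
    X_cal = s.values[cal_idx]
    y_cal = y_all[cal_idx]

    outlier_report = None
    n_removed = 0
    if cfg.outlier_screening:
        screen_lv = min(cfg.outlier_lv, len(cal_ids) - 1, s.values.shape[1])
        outlier_report = flag_outliers(
            X_cal, y_cal, screen_lv,
            confidence=cfg.outlier_confidence, rule=cfg.outlier_rule,
            sample_ids=cal_ids,
        )
        keep = ~outlier_report.flags
        n_removed = int(outlier_report.flags.sum())
        if keep.sum() < 2:
            raise ValueError("outlier screening removed nearly all calibration samples")
        cal_ids = [sid for sid, k in zip(cal_ids, keep) if k]
        X_cal, y_cal = X_cal[keep], y_cal[keep]

    cal_groups = refs.groups_for(cal_ids)
    folds_ids = kfold_cv(cal_ids, cal_groups, cfg.cv_folds, cfg.seed)
    pos = {sid: i for i, sid in enumerate(cal_ids)}
    folds_idx = [
        (np.array([pos[i] for i in tr]), np.array([pos[i] for i in he]))
        for tr, he in folds_ids
    ]
    search = grid_search_lvs(
        X_cal, y_cal, folds_idx, max_lv=cfg.max_lv, criterion=cfg.lv_criterion
    )
    res = PLS1(y_cal, X_cal, wavelengths_nm=s.wavelengths_nm).fit(search.selected_lv)

    cal_rep = compute_metrics(y_cal, res.predict(X_cal))
    secv, r2cv, rpdcv = secv_metrics(y_cal, search.cv_predictions)
    cal_rep.secv, cal_rep.r2cv, cal_rep.rpdcv = secv, r2cv, rpdcv
    cal_rep.n_lv = search.selected_lv
    return StreamCalibration(
        instrument=inst,
        scan_mode=mode,
        constituent=constituent,
        results=res,
        lv_search=search,
        outlier_report=outlier_report,
        calibration_ids=cal_ids,
        validation_ids=list(plan.validation_ids),
        n_removed=n_removed,
        cal_report=cal_rep,
        seed=cfg.seed,
    )


def run_calibrate(
    streams: dict,
    refs: ReferenceTable,
    cfg: PipelineConfig | None = None,
    log=None,
) -> tuple[dict, pd.DataFrame]:
    """Calibrate every stream x constituent.

    ``streams`` maps (instrument, scan_mode) to a raw reflectance
    SpectraSet.  Returns the StreamCalibration objects keyed by
    (instrument, scan_mode, constituent) and a calibration report table.
    A stage failure aborts that stream x constituent only; the error is
    recorded in the log and the remaining combinations continue.
    """
    cfg = cfg or PipelineConfig()
    rows = []
    fitted = {}
    lines = [f"config hash {cfg.provenance_hash()}  seed {cfg.seed}"]
    for (inst, mode), spectra in streams.items():
        pre = preprocess_stream(spectra, cfg)
        for constituent in cfg.constituents:
            try:
                sc = calibrate_stream(pre, refs, constituent, cfg, preprocessed=True)
            except Exception as exc:  # keep other streams alive
                lines.append(f"FAILED {inst}/{mode}/{constituent}: {exc}")
                continue
            fitted[(inst, mode, constituent)] = sc
            lines.append(
                f"{inst}/{mode}/{constituent}: removed {sc.n_removed} outlier(s), "
                f"selected {sc.lv_search.selected_lv} LV(s)"
                + (
                    "  [above recommended cap]"
                    if sc.lv_search.selected_lv > cfg.recommended_lv_cap
                    else ""
                )
            )
            rows.append(sc.calibration_row())
    if log is not None:
        log.extend(lines)
    table = pd.DataFrame(rows, columns=CAL_COLUMNS)
    return fitted, table


def run_validate(
    fitted: dict,
    streams: dict,
    refs: ReferenceTable,
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Score every fitted model on its held-out validation bunkers."""
    cfg = cfg or PipelineConfig()
    pre_cache = {}
    rows = []
    for (inst, mode, constituent), sc in fitted.items():
        key = (inst, mode)
        if key not in pre_cache:
            pre_cache[key] = preprocess_stream(streams[key], cfg)
        s = pre_cache[key]
        if s.wavelengths_nm.size != sc.results.coef.size:
            raise ValueError(
                f"validation grid has {s.wavelengths_nm.size} points, model "
                f"expects {sc.results.coef.size}; resample to the model grid"
            )
        id_to_row = {sid: i for i, sid in enumerate(s.meta["sample_id"])}
        idx = np.array([id_to_row[i] for i in sc.validation_ids])
        y = refs.values_for(constituent, sc.validation_ids)
        pred = sc.results.predict(s.values[idx])
        rep = compute_metrics(y, pred)
        rep.n_lv = sc.results.n_lv
        rep.success_label = classify_success(rep.r2)
        rep.class_label = classify_rpd(rep.rpd)
        rows.append(
            {
                "Instrument": inst, "Mode": mode, "Variable": constituent,
                "RMSE": rep.rmse, "Bias": rep.bias, "SE": rep.se, "R2": rep.r2,
                "Slope": rep.slope, "Intercept": rep.intercept, "RPD": rep.rpd,
                "Success": rep.success_label, "Classification": rep.class_label,
                "LVs": sc.results.n_lv,
            }
        )
    return pd.DataFrame(rows, columns=VAL_COLUMNS + ["Success", "Classification", "LVs"])


def best_per_constituent(validation: pd.DataFrame) -> pd.DataFrame:
    """Best stream per constituent by minimum validation RMSE."""
    idx = validation.groupby("Variable")["RMSE"].idxmin()
    cols = ["Instrument", "Mode", "Variable", "RMSE", "SE", "R2", "RPD",
            "Success", "Classification"]
    return validation.loc[idx, cols].reset_index(drop=True)
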