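"""Containers and I/O for multi-instrument NIR spectra.

A :class:`SpectraSet` holds a batch of spectra that share one wavelength
grid and one domain (reflectance ``R``, absorbance ``log10(1/R)``, or a
derivative thereof), together with per-spectrum metadata: sample id,
replicate number, instrument label, scan mode and the group (farm/bunker)
label that drives leakage-free splitting downstream.

The exchange format is a wide CSV: five metadata columns followed by one
column per wavelength, the header of which is the wavelength in nm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectraSet",
    "ReferenceTable",
    "read_spectra",
    "write_spectra",
    "read_reference",
    "write_reference",
    "to_absorbance",
    "resample_to_grid",
    "aggregate_replicates",
    "CONSTITUENTS",
    "SCAN_MODES",
    "DOMAIN_KINDS",
]

#: Forage constituents handled throughout the package, in reporting order.
CONSTITUENTS = ("IVTD", "aNDF", "NDFD", "ADF", "ADL", "CP")

SCAN_MODES = ("static", "moving", "turntable")
DOMAIN_KINDS = ("reflectance", "absorbance", "derivative")

META_COLUMNS = ("sample_id", "replicate", "instrument", "scan_mode", "group")

#: Tolerance (nm) for declaring two wavelength grids equal.
GRID_TOL_NM = 1e-6


class SpectraFormatError(ValueError):
    """Malformed spectra file or table."""


@dataclass(frozen=True)
class Spectrum:
    """A single scan: intensities on a strictly increasing wavelength grid."""

    wavelengths_nm: np.ndarray
    values: np.ndarray
    domain_kind: str
    sample_id: str
    replicate: int
    instrument: str
    scan_mode: str
    group: str

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "values", v)
        _validate_grid(w)
        if v.shape != w.shape or w.size < 2:
            raise ValueError("values and wavelengths_nm must have equal length >= 2")
        if self.domain_kind not in DOMAIN_KINDS:
            raise ValueError(f"unknown domain_kind {self.domain_kind!r}")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite values in spectrum {self.sample_id!r}")
        if self.domain_kind == "reflectance" and (np.any(v <= 0) or np.any(v > 1)):
            raise ValueError(
                f"reflectance values of sample {self.sample_id!r} must lie in (0, 1]"
            )
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        if self.scan_mode not in SCAN_MODES:
            raise ValueError(f"unknown scan_mode {self.scan_mode!r}")


def _validate_grid(w: np.ndarray) -> None:
    if w.ndim != 1 or w.size < 2:
        raise ValueError("wavelength grid must be 1-D with >= 2 points")
    if not np.all(np.isfinite(w)):
        raise ValueError("wavelength grid contains non-finite entries")
    if np.any(np.diff(w) <= 0):
        raise ValueError("wavelength grid must be strictly increasing")


@dataclass
class SpectraSet:
    """Spectra on a shared grid plus aligned metadata.

    Parameters
    ----------
    wavelengths_nm : (p,) array, strictly increasing.
    values : (n, p) array of intensities, one row per scan.
    meta : DataFrame with columns sample_id, replicate, instrument,
        scan_mode, group (one row per scan, positionally aligned).
    domain_kind : "reflectance", "absorbance" or "derivative".
    provenance : free-text log of the transforms applied so far.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    meta: pd.DataFrame
    domain_kind: str
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        _validate_grid(self.wavelengths_nm)
        if self.domain_kind not in DOMAIN_KINDS:
            raise ValueError(f"unknown domain_kind {self.domain_kind!r}")
        if self.values.shape[1] != self.wavelengths_nm.size:
            raise ValueError("values column count must match wavelength grid")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise SpectraFormatError(f"missing metadata column(s): {missing}")
        if len(self.meta) != self.values.shape[0]:
            raise ValueError("meta rows must match value rows")
        self.meta = self.meta.reset_index(drop=True)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite spectral values")
        if self.domain_kind == "reflectance" and (
            np.any(self.values <= 0) or np.any(self.values > 1)
        ):
            raise ValueError("reflectance values must lie in (0, 1]")
        key = self.meta[["sample_id", "replicate", "instrument", "scan_mode"]]
        if key.duplicated().any():
            dupes = key[key.duplicated()].to_dict("records")
            raise SpectraFormatError(
                f"duplicate (sample_id, replicate, instrument, scan_mode): {dupes[:3]}"
            )

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return self.values.shape[0]

    def __getitem__(self, i: int) -> Spectrum:
        row = self.meta.iloc[i]
        return Spectrum(
            wavelengths_nm=self.wavelengths_nm,
            values=self.values[i],
            domain_kind=self.domain_kind,
            sample_id=str(row["sample_id"]),
            replicate=int(row["replicate"]),
            instrument=str(row["instrument"]),
            scan_mode=str(row["scan_mode"]),
            group=str(row["group"]),
        )

    def with_values(
        self, values: np.ndarray, domain_kind: str | None = None, note: str | None = None
    ) -> "SpectraSet":
        """Copy with new values (and optionally a new domain), same metadata."""
        prov = list(self.provenance)
        if note:
            prov.append(note)
        return SpectraSet(
            wavelengths_nm=self.wavelengths_nm.copy(),
            values=np.asarray(values, dtype=float),
            meta=self.meta.copy(),
            domain_kind=domain_kind or self.domain_kind,
            provenance=prov,
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame: metadata columns then one column per wavelength."""
        wide = pd.DataFrame(
            self.values, columns=[_format_wavelength(w) for w in self.wavelengths_nm]
        )
        return pd.concat([self.meta.reset_index(drop=True), wide], axis=1)


def _format_wavelength(w: float) -> str:
    return f"{w:.6f}".rstrip("0").rstrip(".")


# ---------------------------------------------------------------------------
# Reference chemistry
# ---------------------------------------------------------------------------

#: Default plausibility bounds for each constituent (%DM): observed min/max of
#: the calibration population the generator emulates.
DEFAULT_BOUNDS = {
    "IVTD": (38.13, 92.92),
    "aNDF": (28.81, 81.60),
    "NDFD": (11.40, 80.87),
    "ADF": (24.22, 59.06),
    "ADL": (3.12, 20.60),
    "CP": (6.12, 27.72),
}


@dataclass
class ReferenceTable:
    """Per-sample laboratory constituent values (%DM) with a group label."""

    table: pd.DataFrame
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))

    def __post_init__(self) -> None:
        need = ["sample_id", "group", *CONSTITUENTS]
        missing = [c for c in need if c not in self.table.columns]
        if missing:
            raise SpectraFormatError(f"reference table missing column(s): {missing}")
        self.table = self.table.reset_index(drop=True)
        self.table[list(CONSTITUENTS)] = self.table[list(CONSTITUENTS)].astype(float)
        vals = self.table[list(CONSTITUENTS)].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite constituent values")
        if self.table["sample_id"].duplicated().any():
            raise SpectraFormatError("duplicate sample_id in reference table")
        for name, (lo, hi) in self.bounds.items():
            if name not in CONSTITUENTS:
                continue
            col = self.table[name].to_numpy(dtype=float)
            bad = (col < lo) | (col > hi)
            if bad.any():
                raise ValueError(
                    f"{name} values outside plausibility bounds [{lo}, {hi}] "
                    f"for sample(s) {self.table['sample_id'][bad].tolist()[:5]}"
                )

    def __len__(self) -> int:
        return len(self.table)

    def values_for(self, constituent: str, sample_ids) -> np.ndarray:
        """Constituent values aligned to the given sample id order."""
        if constituent not in CONSTITUENTS:
            raise KeyError(f"unknown constituent {constituent!r}")
        lut = self.table.set_index("sample_id")[constituent]
        return lut.loc[list(sample_ids)].to_numpy(dtype=float)

    def groups_for(self, sample_ids) -> np.ndarray:
        lut = self.table.set_index("sample_id")["group"]
        return lut.loc[list(sample_ids)].to_numpy()


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_spectra(path, domain_kind: str = "reflectance") -> SpectraSet:
    """Read a wide CSV of spectra.

    Metadata columns come first (sample_id, replicate, instrument,
    scan_mode, group), followed by wavelength columns whose headers parse
    as numbers in nm and increase left to right.  Rows containing cells
    that do not parse as numbers are dropped, with their indices reported
    in a warning and in the set's provenance log.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "group": str})
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise SpectraFormatError(f"missing metadata column(s): {missing}")
    wl_cols = [c for c in df.columns if c not in META_COLUMNS]
    try:
        wavelengths = np.array([float(c) for c in wl_cols], dtype=float)
    except ValueError as exc:
        raise SpectraFormatError(f"non-numeric wavelength header: {exc}") from exc
    if np.any(np.diff(wavelengths) <= 0):
        raise SpectraFormatError("wavelength headers must be strictly increasing")
    numeric = df[wl_cols].apply(pd.to_numeric, errors="coerce")
    bad_rows = numeric.isna().any(axis=1)
    prov = [f"read_spectra({path})"]
    if bad_rows.any():
        idx = [int(i) for i in np.flatnonzero(bad_rows.to_numpy())]
        warnings.warn(
            f"rejected {len(idx)} row(s) with unparseable numeric cells: {idx[:10]}",
            stacklevel=2,
        )
        prov.append(f"rejected rows {idx}")
        df = df.loc[~bad_rows]
        numeric = numeric.loc[~bad_rows]
    return SpectraSet(
        wavelengths_nm=wavelengths,
        values=numeric.to_numpy(dtype=float),
        meta=df[list(META_COLUMNS)].copy(),
        domain_kind=domain_kind,
        provenance=prov,
    )


def write_spectra(s: SpectraSet, path, sidecar_log: bool = True) -> None:
    """Write a SpectraSet as wide CSV; provenance goes to ``<path>.log``."""
    s.to_frame().to_csv(path, index=False, float_format="%.17g")
    if sidecar_log:
        with open(f"{path}.log", "w", encoding="utf-8") as fh:
            fh.write(f"domain_kind: {s.domain_kind}\n")
            for line in s.provenance:
                fh.write(line + "\n")


def read_reference(path, bounds: dict | None = None) -> ReferenceTable:
    df = pd.read_csv(path, dtype={"sample_id": str, "group": str})
    return ReferenceTable(df, bounds=bounds or dict(DEFAULT_BOUNDS))


def write_reference(r: ReferenceTable, path) -> None:
    r.table.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------


def to_absorbance(s: SpectraSet) -> SpectraSet:
    """Convert reflectance to absorbance, A = log10(1/R)."""
    if s.domain_kind != "reflectance":
        raise ValueError(f"expected reflectance domain, got {s.domain_kind!r}")
    nonpos = np.any(s.values <= 0, axis=1)
    if nonpos.any():
        who = s.meta["sample_id"][nonpos].tolist()[:5]
        raise ValueError(f"non-positive reflectance for sample(s) {who}")
    return s.with_values(
        -np.log10(s.values), domain_kind="absorbance", note="to_absorbance: log10(1/R)"
    )


def resample_to_grid(
    s: SpectraSet, start_nm: float, stop_nm: float, step_nm: float
) -> SpectraSet:
    """Piecewise-linear resampling onto the arithmetic grid start, start+step, ...

    The requested range must lie within the source grid's span; no
    extrapolation is performed.
    """
    if step_nm <= 0:
        raise ValueError("step_nm must be > 0")
    lo, hi = s.wavelengths_nm[0], s.wavelengths_nm[-1]
    if start_nm < lo - GRID_TOL_NM or stop_nm > hi + GRID_TOL_NM:
        raise ValueError(
            f"requested range [{start_nm}, {stop_nm}] exceeds source span [{lo}, {hi}]"
        )
    n_pts = int(np.floor((stop_nm - start_nm) / step_nm + GRID_TOL_NM)) + 1
    target = start_nm + step_nm * np.arange(n_pts)
    target = np.clip(target, lo, hi)  # guard float fuzz at the endpoints
    if s.wavelengths_nm.size == target.size and np.allclose(
        s.wavelengths_nm, target, atol=GRID_TOL_NM, rtol=0.0
    ):
        out_vals = s.values.copy()
    else:
        out_vals = np.empty((len(s), target.size))
        for i in range(len(s)):
            out_vals[i] = np.interp(target, s.wavelengths_nm, s.values[i])
    out = SpectraSet(
        wavelengths_nm=target,
        values=out_vals,
        meta=s.meta.copy(),
        domain_kind=s.domain_kind,
        provenance=list(s.provenance)
        + [f"resample_to_grid({start_nm}, {stop_nm}, {step_nm})"],
    )
    return out


def aggregate_replicates(s: SpectraSet, policy: str = "mean") -> SpectraSet:
    """Collapse replicate scans per (sample_id, instrument, scan_mode).

    ``mean`` averages the replicates (replicate renumbered to 1);
    ``keep_all`` returns the set unchanged.
    """
    if policy == "keep_all":
        return s
    if policy != "mean":
        raise ValueError(f"unknown replicate policy {policy!r}")
    keys = ["sample_id", "instrument", "scan_mode"]
    grouped = s.meta.groupby(keys, sort=False).indices
    n_out = len(grouped)
    vals = np.empty((n_out, s.values.shape[1]))
    rows = []
    for j, (key, idx) in enumerate(grouped.items()):
        vals[j] = s.values[np.asarray(idx)].mean(axis=0)
        row = s.meta.iloc[np.asarray(idx)[0]].to_dict()
        row["replicate"] = 1
        rows.append(row)
    return SpectraSet(
        wavelengths_nm=s.wavelengths_nm.copy(),
        values=vals,
        meta=pd.DataFrame(rows),
        domain_kind=s.domain_kind,
        provenance=list(s.provenance) + ["aggregate_replicates(mean)"],
    )
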