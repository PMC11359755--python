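"""Seeded generator of haylage-like reference chemistry and NIR spectra.

The generator emulates the statistical structure of a multi-instrument
field campaign on undried, ensiled mixed forage: 600 samples drawn from
111 farm bunkers, each scanned five times per instrument and scan mode.
Reference chemistry (six constituents, %DM) is drawn from a truncated
multivariate normal whose means, standard deviations and hard bounds
match the laboratory population the analysis targets, with bunker-level
random intercepts so that samples from one bunker are correlated and
group-wise splitting is consequential.

Spectra are built additively in absorbance from Gaussian component
bands::

    A(l) = sum_k c_k * B_k(l) + w * W(l) + baseline(l)

where ``B_k`` is the band profile of constituent ``k`` (amplitude per
%DM), ``w`` the fresh-basis moisture fraction and ``W`` the water
profile built from the five main O-H bands with intensity ratios
very_small : large : very_large = 1 : 10 : 25 so that the 1904 nm band
dominates.  Digestibility traits (IVTD, NDFD) have no bands of their
own — they are not chemical species — and are predictable only through
their correlation with the fiber constituents, which mirrors their
weaker real-world calibrations.

Sample presentation is modelled through sub-spots: a replicate scan of a
heterogeneous sample averages 1 (static), 5 (moving) or 10 (turntable)
sub-spots whose constituent concentrations are independently perturbed
with relative sd ``tau``.  Each sub-spot also receives a multiplicative
scatter factor; the replicate is the sub-spot average, convolved with
the instrument line shape (Gaussian, 16 nm FWHM for the variable-step
instrument), sampled onto the instrument grid, and corrupted with white
noise before conversion to reflectance ``R = 10^(-A)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .spectra import CONSTITUENTS, DEFAULT_BOUNDS, ReferenceTable, SpectraSet
from .water import WaterBandTable

__all__ = [
    "GaussianBand",
    "ConstituentBandSpec",
    "InstrumentDef",
    "SyntheticConfig",
    "generate_reference",
    "generate_spectra",
    "make_campaign",
]


@dataclass(frozen=True)
class GaussianBand:
    center_nm: float
    sigma_nm: float
    amplitude: float  # absorbance per unit concentration

    def __post_init__(self) -> None:
        if self.sigma_nm <= 0:
            raise ValueError("band width must be > 0")
        if not 1300.0 <= self.center_nm <= 2600.0:
            raise ValueError("band centre must lie within 1300-2600 nm")


@dataclass(frozen=True)
class ConstituentBandSpec:
    name: str
    bands: tuple

    def profile(self, wavelengths: np.ndarray) -> np.ndarray:
        out = np.zeros_like(wavelengths)
        for b in self.bands:
            out += b.amplitude * np.exp(
                -((wavelengths - b.center_nm) ** 2) / (2.0 * b.sigma_nm**2)
            )
        return out


@dataclass(frozen=True)
class InstrumentDef:
    name: str
    grid: np.ndarray
    lineshape_fwhm_nm: float | None = None  # None -> delta line shape


def _fixed_grid(start: float = 1454.0, stop: float = 2446.0, step: float = 4.0):
    return start + step * np.arange(int(round((stop - start) / step)) + 1)


def _variable_grid(
    start: float = 1350.0,
    stop: float = 2550.0,
    step_min: float = 2.5,
    step_max: float = 8.8,
) -> np.ndarray:
    """Grid whose step ramps from step_min to step_max across the range."""
    pts = [start]
    while pts[-1] < stop:
        frac = (pts[-1] - start) / (stop - start)
        pts.append(pts[-1] + step_min + (step_max - step_min) * frac)
    pts[-1] = min(pts[-1], stop)
    return np.array(pts)


def default_instruments() -> dict:
    return {
        "AgroCares": InstrumentDef("AgroCares", _fixed_grid()),
        "Trinamix": InstrumentDef("Trinamix", _fixed_grid()),
        "NeoSpectra": InstrumentDef("NeoSpectra", _variable_grid(), 16.0),
    }


#: Laboratory population the reference generator matches (%DM):
#: per-constituent mean and SD plus the hard min/max truncation bounds.
DEFAULT_MEANS = {
    "IVTD": 79.22, "aNDF": 50.13, "NDFD": 58.84, "ADF": 37.18, "ADL": 7.35, "CP": 17.62,
}
DEFAULT_SDS = {
    "IVTD": 7.31, "aNDF": 10.42, "NDFD": 9.39, "ADF": 5.80, "ADL": 2.18, "CP": 4.43,
}

#: Plausible inter-constituent correlations (true campaign correlations are
#: not published; these are configurable and no test depends on exact values).
DEFAULT_CORRELATION = np.array(
    [
        # IVTD  aNDF   NDFD   ADF    ADL    CP
        [1.00, -0.75, 0.65, -0.70, -0.55, 0.45],
        [-0.75, 1.00, -0.40, 0.90, 0.50, -0.65],
        [0.65, -0.40, 1.00, -0.35, -0.55, 0.30],
        [-0.70, 0.90, -0.35, 1.00, 0.60, -0.55],
        [-0.55, 0.50, -0.55, 0.60, 1.00, -0.30],
        [0.45, -0.65, 0.30, -0.55, -0.30, 1.00],
    ]
)


def default_band_library() -> dict:
    """Invented pure-component band sets (no public pure spectra exist).

    Protein carries N-H combination bands near 2055/2180 nm; the fiber
    fractions carry C-H/C-O bands near 1730/2100/2270-2330 nm, lignin the
    same family at lower amplitude plus a band at 1940 nm that overlaps
    the very large 1904 nm water band (making it water-sensitive by
    construction); the digestibility traits have no bands at all.
    """
    g = GaussianBand
    return {
        "CP": ConstituentBandSpec(
            "CP", (g(2055, 24, 0.0045), g(2180, 22, 0.0040), g(1690, 30, 0.0015))
        ),
        "aNDF": ConstituentBandSpec(
            "aNDF",
            (g(1730, 26, 0.0022), g(2100, 32, 0.0026), g(2270, 26, 0.0018),
             g(2330, 24, 0.0014)),
        ),
        "ADF": ConstituentBandSpec(
            "ADF", (g(1730, 26, 0.0016), g(2100, 32, 0.0020), g(2270, 26, 0.0022))
        ),
        "ADL": ConstituentBandSpec(
            "ADL", (g(1730, 26, 0.0003), g(1940, 30, 0.0005), g(2330, 24, 0.0004))
        ),
        "IVTD": ConstituentBandSpec("IVTD", ()),
        "NDFD": ConstituentBandSpec("NDFD", ()),
    }


DEFAULT_STREAMS = (
    ("AgroCares", "static"),
    ("AgroCares", "moving"),
    ("NeoSpectra", "static"),
    ("NeoSpectra", "moving"),
    ("NeoSpectra", "turntable"),
    ("Trinamix", "static"),
)


@dataclass
class SyntheticConfig:
    """All knobs of the campaign generator; defaults are the study conditions."""

    n_samples: int = 600
    n_groups: int = 111
    replicates: int = 5
    seed: int = 0

    means: dict = field(default_factory=lambda: dict(DEFAULT_MEANS))
    sds: dict = field(default_factory=lambda: dict(DEFAULT_SDS))
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    correlation: np.ndarray = field(default_factory=lambda: DEFAULT_CORRELATION.copy())
    group_sd_fraction: float = 0.30  # bunker share of the total SD

    band_library: dict = field(default_factory=default_band_library)
    water_bands: WaterBandTable = field(default_factory=WaterBandTable)
    water_unit_amplitude: float = 0.032  # very_small band at moisture 1.0
    water_intensity_ratios: dict = field(
        default_factory=lambda: {"very_small": 1.0, "large": 10.0, "very_large": 25.0}
    )
    water_sigma_nm: float = 45.0
    #: hydrogen-bond band shift: water band centres move by this many nm per
    #: unit moisture (relative to moisture 0.5).  The shift makes the water
    #: interference nonlinear in moisture, which is what degrades
    #: constituents whose bands overlap the 1904 nm region; set to 0 for an
    #: exactly linear (finite-rank) generator.
    water_shift_nm_per_moisture: float = 30.0
    moisture_range: tuple = (0.45, 0.70)  # fresh-basis water fraction

    baseline_offset_range: tuple = (0.05, 0.15)
    baseline_slope_range: tuple = (-5e-5, 5e-5)  # absorbance per nm
    scatter_sd: float = 0.02
    noise_sd: float = 0.0015
    heterogeneity_tau: float = 0.10  # relative sub-spot concentration sd
    #: relative sd of the mismatch between the scanned material and the
    #: subsample sent to the laboratory; unlike sub-spot heterogeneity it is
    #: not reduced by replicate scans or dynamic scan modes
    sample_mismatch_sd: float = 0.05
    subspot_counts: dict = field(
        default_factory=lambda: {"static": 1, "moving": 5, "turntable": 10}
    )

    instruments: dict = field(default_factory=default_instruments)
    streams: tuple = DEFAULT_STREAMS

    fine_grid_start: float = 1300.0
    fine_grid_stop: float = 2600.0
    fine_grid_step: float = 2.0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_groups < 1 or self.replicates < 1:
            raise ValueError("n_samples, n_groups and replicates must be >= 1")
        if self.n_groups > self.n_samples:
            raise ValueError("cannot have more groups than samples")
        C = np.asarray(self.correlation, dtype=float)
        if C.shape != (6, 6) or not np.allclose(C, C.T):
            raise ValueError("correlation must be a symmetric 6x6 matrix")
        if np.linalg.eigvalsh(C).min() < -1e-8:
            raise ValueError("correlation matrix must be positive semi-definite")
        self.correlation = C
        for name in CONSTITUENTS:
            lo, hi = self.bounds[name]
            if lo >= hi:
                raise ValueError(f"infeasible truncation for {name}: min >= max")
            if self.sds[name] < 0:
                raise ValueError("standard deviations must be >= 0")
        if min(self.heterogeneity_tau, self.noise_sd, self.scatter_sd,
               self.sample_mismatch_sd) < 0:
            raise ValueError("noise parameters must be >= 0")
        for inst, mode in self.streams:
            if inst not in self.instruments:
                raise ValueError(f"stream references unknown instrument {inst!r}")
            if mode not in self.subspot_counts:
                raise ValueError(f"stream references unknown scan mode {mode!r}")

    @property
    def fine_grid(self) -> np.ndarray:
        n = int(round((self.fine_grid_stop - self.fine_grid_start) / self.fine_grid_step))
        return self.fine_grid_start + self.fine_grid_step * np.arange(n + 1)

    def water_profile(
        self, wavelengths: np.ndarray, shift_nm: float | np.ndarray = 0.0
    ) -> np.ndarray:
        """Water absorbance profile at moisture 1.0, optionally centre-shifted.

        ``shift_nm`` may be an array of per-sample shifts, in which case
        the result has one row per sample.
        """
        shift = np.asarray(shift_nm, dtype=float)
        vector = shift.ndim > 0
        lam = wavelengths[None, :] if vector else wavelengths
        delta = shift[:, None] if vector else shift
        out = np.zeros((shift.size, wavelengths.size)) if vector else np.zeros_like(
            wavelengths
        )
        for band in self.water_bands:
            amp = self.water_unit_amplitude * self.water_intensity_ratios[
                band.relative_intensity
            ]
            out += amp * np.exp(
                -((lam - band.center_nm - delta) ** 2)
                / (2.0 * self.water_sigma_nm**2)
            )
        return out


# ---------------------------------------------------------------------------
# Reference chemistry
# ---------------------------------------------------------------------------


def _group_assignment(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Every group gets at least one sample; the rest land uniformly."""
    extra = rng.integers(0, cfg.n_groups, cfg.n_samples - cfg.n_groups)
    idx = np.concatenate([np.arange(cfg.n_groups), extra])
    return np.sort(idx)


def _truncation_compensated_moments(
    mu: float, sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """Input (mean, sd) whose truncation to [lo, hi] restores the targets.

    Truncating a normal shrinks its spread and drags its mean toward the
    centre of the interval; a short fixed-point iteration on the
    closed-form truncated-normal moments undoes both so the generated
    population matches the configured statistics after truncation.
    """
    if sd == 0:
        return mu, sd
    from scipy.stats import truncnorm

    m, s = mu, sd
    for _ in range(40):
        a, b = (lo - m) / s, (hi - m) / s
        tm, tv = truncnorm.stats(a, b, loc=m, scale=s, moments="mv")
        m += mu - float(tm)
        s *= sd / float(np.sqrt(tv))
        if abs(tm - mu) < 1e-10 * max(1.0, abs(mu)) and abs(
            np.sqrt(tv) - sd
        ) < 1e-10 * sd:
            break
    return m, s


def generate_reference(
    cfg: SyntheticConfig, rng: np.random.Generator | int | None = None
) -> ReferenceTable:
    """Draw the per-sample constituent table from a truncated MVN.

    Bunker-level random intercepts carry ``group_sd_fraction**2`` of the
    total variance; the within-bunker part is redrawn (up to 50 rounds)
    for samples that land outside the configured bounds, then clipped.
    Pre-truncation moments are inflated (see
    :func:`_truncation_compensated_moments`) so the emitted population
    matches the configured means and sds.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(cfg.seed if rng is None else rng)
    comp = [
        _truncation_compensated_moments(
            cfg.means[c], cfg.sds[c], cfg.bounds[c][0], cfg.bounds[c][1]
        )
        for c in CONSTITUENTS
    ]
    mu = np.array([m for m, _ in comp])
    sd = np.array([s for _, s in comp])
    cov = cfg.correlation * np.outer(sd, sd)
    f2 = cfg.group_sd_fraction**2
    lo = np.array([cfg.bounds[c][0] for c in CONSTITUENTS])
    hi = np.array([cfg.bounds[c][1] for c in CONSTITUENTS])

    group_idx = _group_assignment(cfg, rng)
    g_eff = rng.multivariate_normal(
        np.zeros(6), f2 * cov, size=cfg.n_groups, method="eigh"
    )
    base = mu + g_eff[group_idx]
    within = rng.multivariate_normal(
        np.zeros(6), (1.0 - f2) * cov, size=cfg.n_samples, method="eigh"
    )
    vals = base + within
    for _ in range(50):
        bad = np.any((vals < lo) | (vals > hi), axis=1)
        if not bad.any():
            break
        redraw = rng.multivariate_normal(
            np.zeros(6), (1.0 - f2) * cov, size=int(bad.sum()), method="eigh"
        )
        vals[bad] = base[bad] + redraw
    vals = np.clip(vals, lo, hi)

    width = len(str(cfg.n_samples))
    gwidth = len(str(cfg.n_groups))
    table = pd.DataFrame(vals, columns=list(CONSTITUENTS))
    table.insert(0, "sample_id", [f"S{i + 1:0{width}d}" for i in range(cfg.n_samples)])
    table.insert(1, "group", [f"G{g + 1:0{gwidth}d}" for g in group_idx])
    return ReferenceTable(table, bounds=dict(cfg.bounds))


def draw_moisture(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.moisture_range
    return rng.uniform(lo, hi, cfg.n_samples)


def draw_mismatch(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Scanned-vs-analysed subsample factors, (n, constituents + moisture)."""
    return 1.0 + rng.normal(
        0.0, cfg.sample_mismatch_sd, size=(cfg.n_samples, len(CONSTITUENTS) + 1)
    )


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------


def generate_spectra(
    refs: ReferenceTable,
    cfg: SyntheticConfig,
    instrument: str,
    scan_mode: str,
    rng: np.random.Generator | int | None = None,
    moisture: np.ndarray | None = None,
    mismatch: np.ndarray | None = None,
) -> SpectraSet:
    """Reflectance spectra for one instrument x scan-mode stream.

    ``moisture`` (per sample) and ``mismatch`` (per sample x constituent
    +moisture factors, see :func:`draw_mismatch`) are sample properties;
    a campaign shares them across its streams, because every instrument
    scans the same vacuum-packed bag while the laboratory analyses one
    common subsample.  When omitted they are drawn from ``rng``.
    """
    if instrument not in cfg.instruments:
        raise ValueError(f"instrument {instrument!r} not defined in config")
    if scan_mode not in cfg.subspot_counts:
        raise ValueError(f"scan mode {scan_mode!r} not defined in config")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(cfg.seed if rng is None else rng)
    inst = cfg.instruments[instrument]
    fine = cfg.fine_grid
    if inst.grid[0] < fine[0] or inst.grid[-1] > fine[-1]:
        raise ValueError("instrument grid exceeds the internal fine grid")

    active = [c for c in CONSTITUENTS if cfg.band_library[c].bands]
    missing = [c for c in CONSTITUENTS if c not in cfg.band_library]
    if missing:
        raise ValueError(f"constituent(s) without a band spec: {missing}")
    B = np.array([cfg.band_library[c].profile(fine) for c in active])  # (K, nf)
    conc = refs.table[active].to_numpy(dtype=float)  # (n, K)
    n = conc.shape[0]
    if moisture is None:
        moisture = draw_moisture(replace(cfg, n_samples=n), rng)
    moisture = np.asarray(moisture, dtype=float)
    if moisture.size != n:
        raise ValueError("moisture must have one value per sample")

    comp = np.concatenate([conc, moisture[:, None]], axis=1)  # (n, K+1)
    if mismatch is None:
        mismatch = draw_mismatch(replace(cfg, n_samples=n), rng)
    mismatch = np.atleast_2d(np.asarray(mismatch, dtype=float))
    if mismatch.shape != (n, len(CONSTITUENTS) + 1):
        raise ValueError("mismatch must have shape (n_samples, n_constituents + 1)")
    cols = [CONSTITUENTS.index(c) for c in active] + [len(CONSTITUENTS)]
    # what the scanner sees is a different subsample than the laboratory
    # analysed; this error floor survives replicate and sub-spot averaging
    comp = comp * mismatch[:, cols]
    # hydrogen-bond shift of the water bands follows the scanned moisture
    shift = cfg.water_shift_nm_per_moisture * (comp[:, -1] - 0.5)
    Wprof = cfg.water_profile(fine, shift)  # (n, nf)
    n_sub = int(cfg.subspot_counts[scan_mode])
    reps = cfg.replicates

    offset = rng.uniform(*cfg.baseline_offset_range, size=n)
    slope = rng.uniform(*cfg.baseline_slope_range, size=n)
    baseline = offset[:, None] + slope[:, None] * (fine - 1950.0)[None, :]  # (n, nf)

    # sub-spot composition perturbations and scatter factors; the replicate
    # averages the sub-spots, and both operations are linear in composition,
    # so the effective composition is averaged before the profile products
    eps = rng.normal(0.0, cfg.heterogeneity_tau, size=(n, reps, n_sub, comp.shape[1]))
    scatter = 1.0 + rng.normal(0.0, cfg.scatter_sd, size=(n, reps, n_sub))
    comp_sub = comp[:, None, None, :] * (1.0 + eps)  # (n, reps, n_sub, K+1)
    comp_eff = np.mean(scatter[..., None] * comp_sub, axis=2)  # (n, reps, K+1)
    scatter_eff = scatter.mean(axis=2)  # (n, reps)

    A = comp_eff[..., :-1].reshape(n * reps, -1) @ B  # (n*reps, nf)
    A += (comp_eff[..., -1][..., None] * Wprof[:, None, :]).reshape(n * reps, -1)
    A += (scatter_eff[..., None] * baseline[:, None, :]).reshape(n * reps, -1)

    if inst.lineshape_fwhm_nm:
        sigma_pts = inst.lineshape_fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        sigma_pts /= cfg.fine_grid_step
        A = gaussian_filter1d(A, sigma_pts, axis=1, mode="nearest")

    # linear sampling of the fine grid onto the instrument grid
    pos = (inst.grid - fine[0]) / cfg.fine_grid_step
    j = np.clip(np.floor(pos).astype(int), 0, fine.size - 2)
    frac = pos - j
    Ag = A[:, j] * (1.0 - frac) + A[:, j + 1] * frac

    if cfg.noise_sd > 0:
        Ag = Ag + rng.normal(0.0, cfg.noise_sd, size=Ag.shape)
    Ag = np.clip(Ag, 0.0, None)  # reflectance must stay within (0, 1]

    ids = refs.table["sample_id"].to_numpy()
    grp = refs.table["group"].to_numpy()
    meta = pd.DataFrame(
        {
            "sample_id": np.repeat(ids, reps),
            "replicate": np.tile(np.arange(1, reps + 1), n),
            "instrument": instrument,
            "scan_mode": scan_mode,
            "group": np.repeat(grp, reps),
        }
    )
    return SpectraSet(
        wavelengths_nm=inst.grid.copy(),
        values=np.power(10.0, -Ag),
        meta=meta,
        domain_kind="reflectance",
        provenance=[f"generate_spectra({instrument}, {scan_mode})"],
    )


def make_campaign(cfg: SyntheticConfig) -> tuple[dict, ReferenceTable]:
    """Full campaign: one reference table, spectra per configured stream.

    Every random stream draws from its own child of the master seed, so
    each output is individually reproducible and the whole campaign is
    byte-identical across runs with the same config.
    """
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(3 + len(cfg.streams))
    refs = generate_reference(cfg, np.random.default_rng(children[0]))
    moisture = draw_moisture(cfg, np.random.default_rng(children[1]))
    mismatch = draw_mismatch(cfg, np.random.default_rng(children[2]))
    out = {}
    for i, (inst, mode) in enumerate(cfg.streams):
        out[(inst, mode)] = generate_spectra(
            refs, cfg, inst, mode,
            rng=np.random.default_rng(children[3 + i]),
            moisture=moisture,
            mismatch=mismatch,
        )
    return out, refs
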