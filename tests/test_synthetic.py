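import io

import numpy as np
import pytest

from wetspec.pipeline import PipelineConfig, run_calibrate, run_validate
from wetspec.spectra import CONSTITUENTS, write_spectra
from wetspec.synthetic import (
    ConstituentBandSpec,
    GaussianBand,
    SyntheticConfig,
    generate_reference,
    generate_spectra,
    make_campaign,
)

ZERO = {c: 0.0 for c in CONSTITUENTS}
UNIT_BOUNDS = {c: (-1.0, 1.0) for c in CONSTITUENTS}


class TestReference:
    def test_population_moments_match_targets(self):
        cfg = SyntheticConfig(seed=1, n_samples=2000, n_groups=111)
        t = generate_reference(cfg).table
        assert t["CP"].mean() == pytest.approx(17.62, abs=0.3)
        assert t["CP"].std(ddof=1) == pytest.approx(4.43, abs=0.3)

    def test_hard_bounds_never_violated(self):
        cfg = SyntheticConfig(seed=2, n_samples=2000, n_groups=50)
        t = generate_reference(cfg).table
        for c in CONSTITUENTS:
            lo, hi = cfg.bounds[c]
            assert t[c].min() >= lo and t[c].max() <= hi

    def test_zero_sd_collapses_to_mean_vector(self):
        cfg = SyntheticConfig(seed=3, n_samples=50, n_groups=5, sds=dict(ZERO))
        t = generate_reference(cfg).table
        for c in CONSTITUENTS:
            np.testing.assert_allclose(t[c], cfg.means[c])

    def test_groups_induce_within_bunker_correlation(self):
        cfg = SyntheticConfig(seed=4, n_samples=1500, n_groups=50)
        t = generate_reference(cfg).table
        grand = t["CP"].var(ddof=1)
        between = t.groupby("group")["CP"].mean().var(ddof=1)
        assert between > 0.02 * grand  # bunker means genuinely spread out

    def test_determinism(self):
        cfg = SyntheticConfig(seed=5, n_samples=100, n_groups=10)
        a = generate_reference(cfg).table
        b = generate_reference(cfg).table
        assert a.equals(b)

    def test_infeasible_truncation_rejected(self):
        bounds = dict(SyntheticConfig().bounds)
        bounds["CP"] = (30.0, 10.0)
        with pytest.raises(ValueError, match="min >= max"):
            SyntheticConfig(bounds=bounds)

    def test_non_psd_correlation_rejected(self):
        corr = np.eye(6)
        corr[0, 1] = corr[1, 0] = 0.9
        corr[0, 2] = corr[2, 0] = 0.9
        corr[1, 2] = corr[2, 1] = -0.9
        with pytest.raises(ValueError, match="semi-definite"):
            SyntheticConfig(correlation=corr)


def quiet_config(**overrides):
    kw = dict(
        seed=0,
        n_samples=5,
        n_groups=2,
        replicates=1,
        means=dict(ZERO),
        sds=dict(ZERO),
        bounds=dict(UNIT_BOUNDS),
        moisture_range=(0.0, 0.0),
        baseline_offset_range=(0.0, 0.0),
        baseline_slope_range=(0.0, 0.0),
        scatter_sd=0.0,
        noise_sd=0.0,
        heterogeneity_tau=0.0,
        sample_mismatch_sd=0.0,
        water_shift_nm_per_moisture=0.0,
    )
    kw.update(overrides)
    return SyntheticConfig(**kw)


class TestSpectra:
    def test_all_zero_composition_gives_unit_reflectance(self):
        cfg = quiet_config()
        refs = generate_reference(cfg)
        s = generate_spectra(refs, cfg, "Trinamix", "static", 0)
        np.testing.assert_allclose(s.values, 1.0, atol=1e-12)

    def test_moisture_only_peak_at_1904_band(self):
        cfg = quiet_config(moisture_range=(0.6, 0.6))
        refs = generate_reference(cfg)
        s = generate_spectra(refs, cfg, "Trinamix", "static", 0)
        absorb = -np.log10(s.values[0])
        peak = s.wavelengths_nm[np.argmax(absorb)]
        assert abs(peak - 1904.0) <= cfg.instruments["Trinamix"].grid[1] - \
            cfg.instruments["Trinamix"].grid[0]

    def test_replicate_variance_shrinks_with_subspot_count(self):
        # at a strong band centre the replicate-to-replicate variance of a
        # moving scan (5 sub-spots) is ~1/5 of a static scan's
        cfg = quiet_config(
            n_samples=3,
            replicates=300,
            means={**ZERO, "CP": 0.5},
            bounds=dict(UNIT_BOUNDS),
            moisture_range=(0.0, 0.0),
            heterogeneity_tau=0.1,
        )
        refs = generate_reference(cfg)
        ratios = []
        for sample in range(3):
            out = {}
            for mode in ("static", "moving"):
                s = generate_spectra(refs, cfg, "Trinamix", mode, 123)
                band_idx = np.argmin(np.abs(s.wavelengths_nm - 2055.0))
                mask = s.meta["sample_id"] == refs.table["sample_id"][sample]
                absorb = -np.log10(s.values[mask.to_numpy(), band_idx])
                out[mode] = absorb.var(ddof=1)
            ratios.append(out["moving"] / out["static"])
        assert np.mean(ratios) == pytest.approx(1.0 / 5.0, rel=0.35)

    def test_instrument_grids(self):
        cfg = quiet_config(moisture_range=(0.5, 0.5))
        refs = generate_reference(cfg)
        fixed = generate_spectra(refs, cfg, "Trinamix", "static", 0)
        assert fixed.wavelengths_nm[0] == 1454.0
        assert fixed.wavelengths_nm[-1] == 2446.0
        np.testing.assert_allclose(np.diff(fixed.wavelengths_nm), 4.0)
        var = generate_spectra(refs, cfg, "NeoSpectra", "static", 0)
        steps = np.diff(var.wavelengths_nm)
        assert var.wavelengths_nm[0] == 1350.0
        assert steps.min() >= 2.5 - 1e-9 and steps.max() <= 8.8 + 1e-9

    def test_lineshape_smooths_variable_step_instrument(self):
        cfg = quiet_config(moisture_range=(0.5, 0.5), water_sigma_nm=10.0)
        refs = generate_reference(cfg)
        sharp = generate_spectra(refs, cfg, "Trinamix", "static", 0)
        smooth = generate_spectra(refs, cfg, "NeoSpectra", "static", 0)
        a_sharp = (-np.log10(sharp.values[0])).max()
        a_smooth = (-np.log10(smooth.values[0])).max()
        assert a_smooth < a_sharp  # 16 nm FWHM convolution lowers sharp peaks

    def test_unknown_instrument_and_mode_rejected(self):
        cfg = quiet_config()
        refs = generate_reference(cfg)
        with pytest.raises(ValueError, match="instrument"):
            generate_spectra(refs, cfg, "Unknown", "static", 0)
        with pytest.raises(ValueError, match="scan mode"):
            generate_spectra(refs, cfg, "Trinamix", "hovering", 0)


class TestCampaign:
    def test_default_shape_counts(self):
        cfg = SyntheticConfig(seed=6)
        streams, refs = make_campaign(cfg)
        assert len(refs) == 600
        assert refs.table["group"].nunique() == 111
        assert set(streams) == set(cfg.streams)
        s = streams[("NeoSpectra", "turntable")]
        assert len(s) == 600 * 5
        assert s.meta.groupby("sample_id")["replicate"].count().eq(5).all()

    def test_byte_identical_reruns(self):
        cfg = SyntheticConfig(seed=7, n_samples=40, n_groups=8, replicates=2,
                              streams=(("Trinamix", "static"),))
        buffers = []
        for _ in range(2):
            streams, refs = make_campaign(cfg)
            buf = io.StringIO()
            streams[("Trinamix", "static")].to_frame().to_csv(buf, index=False)
            refs.table.to_csv(buf, index=False)
            buffers.append(buf.getvalue())
        assert buffers[0] == buffers[1]

    def test_streams_share_sample_properties(self):
        cfg = SyntheticConfig(seed=8, n_samples=30, n_groups=6, replicates=1,
                              heterogeneity_tau=0.0, scatter_sd=0.0,
                              baseline_offset_range=(0.1, 0.1),
                              baseline_slope_range=(0.0, 0.0),
                              streams=(("Trinamix", "static"),
                                       ("AgroCares", "static")))
        streams, refs = make_campaign(cfg)
        a = streams[("Trinamix", "static")]
        b = streams[("AgroCares", "static")]
        assert a.meta["sample_id"].tolist() == b.meta["sample_id"].tolist()
        # same bag, same water: absorbance at the 1904 nm point must agree
        # closely across instruments on the shared fixed grid
        ia = np.argmin(np.abs(a.wavelengths_nm - 1904))
        corr = np.corrcoef(-np.log10(a.values[:, ia]), -np.log10(b.values[:, ia]))
        assert corr[0, 1] > 0.99


def test_constituent_hierarchy_reproduced():
    """Strongly expressed constituents calibrate better than lignin, which
    shares weak fiber bands and sits on the 1904 nm water shoulder."""
    cfg = SyntheticConfig(seed=9, streams=(("Trinamix", "static"),))
    streams, refs = make_campaign(cfg)
    pcfg = PipelineConfig(seed=9, constituents=("CP", "aNDF", "ADL"))
    fitted, _ = run_calibrate(streams, refs, pcfg)
    val = run_validate(fitted, streams, refs, pcfg)
    r2 = dict(zip(val["Variable"], val["R2"]))
    assert r2["CP"] > r2["ADL"]
    assert r2["aNDF"] > r2["ADL"]


def test_water_interference_targets_overlapping_bands():
    """Widening the moisture spread hurts the water-overlapping constituent
    (ADL) more than the spectrally distant one (CP)."""

    def val_r2(moisture_range):
        cfg = SyntheticConfig(seed=10, streams=(("Trinamix", "static"),),
                              moisture_range=moisture_range)
        streams, refs = make_campaign(cfg)
        pcfg = PipelineConfig(seed=10, constituents=("CP", "ADL"))
        fitted, _ = run_calibrate(streams, refs, pcfg)
        val = run_validate(fitted, streams, refs, pcfg)
        return dict(zip(val["Variable"], val["R2"]))

    narrow = val_r2((0.55, 0.60))
    wide = val_r2((0.40, 0.75))
    drop_adl = narrow["ADL"] - wide["ADL"]
    drop_cp = narrow["CP"] - wide["CP"]
    assert drop_adl > drop_cp
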