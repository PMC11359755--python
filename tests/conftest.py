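import numpy as np
import pandas as pd
import pytest

from wetspec.pipeline import PipelineConfig
from wetspec.spectra import SpectraSet
from wetspec.synthetic import SyntheticConfig, make_campaign


def build_set(
    values,
    wavelengths=None,
    domain_kind="reflectance",
    sample_ids=None,
    replicates=None,
    instrument="InstA",
    scan_mode="static",
    groups=None,
):
    """Small SpectraSet with auto-filled metadata for unit tests."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, p = values.shape
    if wavelengths is None:
        wavelengths = 1454.0 + 4.0 * np.arange(p)
    if sample_ids is None:
        sample_ids = [f"S{i:03d}" for i in range(n)]
    if replicates is None:
        replicates = [1] * n
    if groups is None:
        groups = [f"G{i % max(2, n // 2)}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "replicate": replicates,
            "instrument": instrument,
            "scan_mode": scan_mode,
            "group": groups,
        }
    )
    return SpectraSet(
        wavelengths_nm=np.asarray(wavelengths, dtype=float),
        values=values,
        meta=meta,
        domain_kind=domain_kind,
    )


@pytest.fixture
def make_spectra_set():
    return build_set


@pytest.fixture(scope="session")
def small_campaign():
    """A reduced campaign shared by the pipeline tests: 150 samples from
    25 bunkers, 2 replicate scans, two streams."""
    cfg = SyntheticConfig(
        seed=42,
        n_samples=150,
        n_groups=25,
        replicates=2,
        streams=(("Trinamix", "static"), ("NeoSpectra", "moving")),
    )
    streams, refs = make_campaign(cfg)
    return cfg, streams, refs


@pytest.fixture(scope="session")
def small_pipeline_config():
    return PipelineConfig(seed=42, constituents=("CP", "aNDF", "ADL"))
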