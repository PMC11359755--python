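# wetspec

Near-infrared spectroscopy (NIRS) calibration for **undried forage**.

Handheld NIR spectrometers promise on-farm estimation of haylage quality —
crude protein (CP), fiber fractions (aNDF, ADF, ADL) and digestibility
(IVTD, NDFD), all in % of dry matter — without drying or grinding the
sample. The catch is water: an undried sample is roughly half water, and
the O–H absorption bands at ~1460 nm and especially ~1904 nm dominate the
spectrum and interfere with the constituent signal. `wetspec` implements
the complete calibration methodology for this setting and a synthetic
multi-instrument campaign generator, so every stage of the analysis can be
exercised and tested without access to field data.

## What it does

Given wide-format CSVs of reflectance spectra (rows = sample × replicate,
columns = wavelengths in nm) and a reference-chemistry table, the workflow
per instrument × scan-mode stream and constituent is:

1. **Harmonize** — resample every instrument onto a common grid
   (default 1454–2446 nm, 4 nm step) by linear interpolation and convert
   reflectance to absorbance, A = log10(1/R).
2. **Preprocess** — Savitzky–Golay first-derivative filtering
   (window 4, polynomial order 3; even windows are supported with the
   evaluation point at index ⌊w/2⌋), derivatives scaled per nm.
3. **Split without leakage** — farms/bunkers (groups) are assigned
   whole to either the 90 % calibration or the 10 % validation side, and
   the five cross-validation folds are group-aware too.
4. **Screen outliers** — Q-residuals and Hotelling's T² with 95 %
   control limits (F-distribution limit for T², empirical quantile or
   Jackson–Mudholkar for Q); flagged samples leave the calibration set only.
5. **Calibrate** — from-scratch NIPALS PLS-1. For mean-centred X, y and
   components a = 1…A:

   w_a = X'y/‖X'y‖, t_a = Xw_a, p_a = X't_a/(t_a't_a), q_a = y't_a/(t_a't_a),

   deflating X ← X − t_a p_a' and y ← y − t_a q_a; the collapsed regression
   vector is b = W(P'W)⁻¹q. The component count is chosen by a 1–20 grid
   search minimising the pooled cross-validated RMSE.
6. **Evaluate** — RMSE, bias, bias-corrected SE (se² = n(rmse²−bias²)/(n−1)),
   SECV, R², R²CV, RPD = SD(y)/SE, prediction-vs-reference slope and
   intercept, plus the standard R²-based level-of-success tiers and
   RPD application tiers.
7. **Diagnose water interference** — per-latent-variable loading spectra
   annotated against the water band table
   (1460 large, 1778/2208/2384 very small, 1904 very large) with
   `band_loading_summary`.

The synthetic module (`wetspec.synthetic`) emulates the study conditions
end to end: 600 samples from 111 bunkers, five replicate scans, three
instruments (two fixed 4 nm grids; one variable-step 1350–2550 nm
instrument with a 16 nm-FWHM line shape) and three scan modes that average
1/5/10 heterogeneous sub-spots per scan. See `docs/methods.md` for the
generative model and every default.

## Worked example

```python
from wetspec import (SyntheticConfig, PipelineConfig, make_campaign,
                     run_calibrate, run_validate)

cfg = SyntheticConfig(seed=1, streams=(("NeoSpectra", "moving"),))
streams, reference = make_campaign(cfg)

pipeline = PipelineConfig(seed=1, constituents=("CP", "aNDF", "ADL"))
fitted, calibration = run_calibrate(streams, reference, pipeline)
validation = run_validate(fitted, streams, reference, pipeline)
print(validation.round(3).to_string(index=False))
```

prints

```
Instrument   Mode Variable  RMSE   Bias    SE    R2  Slope  Intercept   RPD    Success Classification  LVs
NeoSpectra moving       CP 0.999 -0.109 1.001 0.944  0.912      1.428 4.251 Successful      Excellent    3
NeoSpectra moving     aNDF 2.606  0.472 2.584 0.932  0.980      1.539 3.899 Successful      Very good    4
NeoSpectra moving      ADL 1.004  0.042 1.012 0.721  1.006     -0.004 1.896 Not Useful      Very poor   20
```

Each row scores one fitted model on its held-out bunkers: protein and
neutral-detergent fiber calibrate well (R² ≈ 0.93–0.94, RPD ≈ 4), while
lignin — whose weak bands sit on the shoulder of the very large 1904 nm
water band — fails validation (R² 0.72, RPD < 2, "Not Useful"/"Very
poor"), reproducing the qualitative constituent hierarchy seen with real
undried forage. The fitted model object exposes the chemometric internals:

```python
res = fitted[("NeoSpectra", "moving", "CP")].results
print(res.summary())          # per-LV explained variance, score variances
lam, p1 = res.loading_spectrum(1)
```

A command-line interface mirrors the library
(`wetspec simulate|calibrate|validate|report -c config.toml`); see
`wetspec --help`.

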