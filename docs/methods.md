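# Methods

This note documents the models, algorithms, numerical choices and
synthetic-data assumptions behind `wetspec`, in the order the pipeline
applies them.

## Spectra model and harmonization

Spectra are stored per (sample, replicate, instrument, scan mode) on a
strictly increasing wavelength grid in nm, in one of three domains:
reflectance R ∈ (0, 1], absorbance A = log10(1/R), or derivative (per nm).
Multi-instrument data are harmonized by piecewise-linear interpolation
onto an arithmetic grid, 1454–2446 nm at 4 nm by default — the
intersection of the fixed-grid instruments' ranges. Linear interpolation
was chosen over splines because it is shape-preserving: it cannot
overshoot near the steep shoulders of the water bands at the range edges.
No extrapolation is ever performed; a request outside the source span is
an error. Grid equality is judged at 10⁻⁶ nm.

Replicate scans are averaged (per sample × instrument × mode) before
calibration by default. Whether replicates should enter the model
individually is a genuinely open choice; averaging avoids
pseudo-replication inflating the apparent sample count, and `keep_all` is
available for the other convention.

## Savitzky–Golay derivative

The filter fits a least-squares polynomial of degree `polyorder` to each
sliding window and evaluates its `deriv`-th derivative. The default
window of 4 points with a cubic polynomial is *even*, which most library
implementations reject; here general even windows are supported with the
evaluation point at index ⌊window/2⌋ (the later of the two central
points), which keeps the output on the sampling grid. With 4 points and
4 polynomial coefficients the fit interpolates, so first derivatives of
cubics are exact to machine precision — the basis of the exactness tests.
A `promote_even_window` switch maps 4 → 5 for users wanting the odd
convention. Derivatives are scaled per nm (divide by step^deriv) so that
loadings are comparable across instruments with different native steps.
Edges are handled by refitting the polynomial to the nearest full window
rather than by padding, avoiding reflection artefacts at the 1454/2446 nm
water-band shoulders; output length equals input length.

## NIPALS PLS-1

For a univariate response the NIPALS recursion is finite (no inner
iteration): per component, the weight is the normalised X–y covariance,
scores/loadings follow by projection, and both X and y are deflated.
Centring only is applied by default — for derivative spectra, amplitude
carries information — with autoscaling available behind a flag. The sign
of each weight vector is fixed so its largest-magnitude element is
positive, making loadings bit-reproducible across runs. Rank exhaustion
is declared when ‖X'y‖ falls below 10⁻¹² of ‖X₀‖_F·‖y₀‖ (an upper bound
on the initial covariance norm, so a response orthogonal to X triggers
the error already at the first component). At full rank the fitted values
coincide with the least-squares solution; this is asserted against a
pseudoinverse oracle and against an independent library implementation.

`PLS1Results.coef_path()` collapses one deep fit into regression vectors
for every smaller component count, so the 1–20 grid search costs one
NIPALS run per cross-validation fold rather than twenty.

Explained X-variance per component is ‖t_a p_a'‖²_F/‖X₀‖²_F; because the
score vectors are orthogonal, explained y-variance per component reduces
to q_a²·t_a't_a/‖y₀‖². Both are reported by `summary()`.

## Outlier screening

Q (squared reconstruction residual off the latent subspace) and
Hotelling's T² (score distance within it, using (n−1)-denominator score
variances, so calibration T² sums to A·(n−1)) are computed from a PLS-1
fit at a screening component count (default 10). Limits at 95 %:
T² uses the classical A(n−1)(n+1)/(n(n−A))·F(A, n−A) form; Q uses the
empirical calibration quantile by default — distribution-free and robust
to the non-Gaussian residuals of derivative spectra — with the
Jackson–Mudholkar closed form available for comparison.

The combination rule is a documented decision: by default a sample must
exceed **both** limits (`both_exceed`), the conservative choice that
removes fewer borderline samples; `either_exceeds` is available.
Screening is a single pass, and flagged samples are removed from the
calibration set only — validation data are never touched. Note that a
purely off-subspace artefact is, by construction, invisible to T²
(its scores are ≈ 0), so the positive-control detection experiments use
`either_exceeds`; the Q statistic is the one that sees such spikes.

## Splitting, model selection and metrics

Bunkers are atomic everywhere. The 90/10 split assigns whole groups to
validation, in seeded random order, until the validation share first
reaches 10 %; the five CV folds greedily balance group sizes
(largest-first into the currently smallest fold). With 600 samples this
yields ≈ 540/60, and fold held-out sizes ≈ 108.

The component count is selected as the argmin of the pooled held-out
RMSE over 1–20 components (ties toward fewer); a one-standard-error
parsimony criterion is selectable. SECV/R²CV/RPDCV are computed from the
*pooled* held-out predictions (fold-averaged SECV is a different, not
reported, convention).

Metric conventions: bias = mean(ŷ−y); RMSE; SE is the bias-corrected
error sd with n−1 denominator, so se² = n(rmse²−bias²)/(n−1) holds as an
identity; R² = 1 − SSE/SST (not squared correlation, which is reported as
an auxiliary column); RPD = SD(y; n−1)/SE computed on the subset being
evaluated (an explicit `sd_reference` override exists); slope/intercept
regress *predicted on reference*. Tier boundaries are half-open on the
left: R² tiers at 0.80/0.90/0.95 and RPD tiers at 2.0/2.5/3.0/3.5/4.0 —
an RPD of 3.452 therefore classifies as "Good".

## Synthetic campaign generator

The generator's defaults are the study conditions: 600 samples from 111
bunkers, five replicates, six streams (two fixed-grid instruments at
1454–2446 nm/4 nm; one variable-step instrument 1350–2550 nm whose step
ramps 2.5→8.8 nm and whose Gaussian line shape has 16 nm FWHM; scan modes
static/moving/turntable with 1/5/10 sub-spots).

**Reference chemistry.** The six constituents are drawn from a truncated
multivariate normal whose marginal means/sds (IVTD 79.22/7.31,
aNDF 50.13/10.42, NDFD 58.84/9.39, ADF 37.18/5.80, ADL 7.35/2.18,
CP 17.62/4.43 %DM) and hard min/max bounds match the target laboratory
population. Pre-truncation moments are inflated by a fixed-point
iteration on the closed-form truncated-normal moments so the *emitted*
population matches the configured statistics. Bunker random intercepts
carry 30 % of each sd (making group-wise splitting consequential); the
inter-constituent correlation matrix is a plausible, configurable default
(fiber fractions strongly positive, protein negative with fiber,
digestibility negatively tied to aNDF/ADL) — the true campaign
correlations are not published and nothing asserts their exact values.

**Spectra.** Absorbance is additive over Gaussian component bands:
protein near 2055/2180 (+1690) nm, aNDF/ADF near 1730/2100/2270–2330 nm,
lignin the same family at much lower amplitude plus a band at 1940 nm
deliberately overlapping the 1904 nm water band. The digestibility traits
have **no bands**: digestibility is not a chemical species, and making it
predictable only through its correlation with fiber reproduces its weaker
real-world calibrations. Water contributes bands at
1460/1778/1904/2208/2384 nm with intensity ratios 1:10:25
(very small : large : very large), σ = 45 nm, scaled by a fresh-basis
moisture fraction drawn uniform on 0.45–0.70 per sample. Band centres
shift with moisture (30 nm per unit moisture, i.e. ±4 nm over the default
range) to emulate hydrogen-bond shifts; this is the nonlinearity that
degrades water-overlapping constituents and it is switched off (together
with all noise) in the finite-rank parameter-recovery experiments.

Error structure, in decreasing order of importance:

* **Scanned-vs-analysed mismatch** (relative sd 0.05): the spot the
  scanner sees is not the subsample the laboratory digests. Drawn once
  per sample per campaign and shared across streams (every instrument
  scans the same bag), so it is the common error floor that no scan mode
  can average away.
* **Sub-spot heterogeneity** (relative sd τ = 0.10): each sub-spot of a
  scan perturbs the composition independently; a replicate averages its
  mode's sub-spots, so this error shrinks like 1/(sub-spots × replicates)
  — the mechanism behind the turntable ≥ moving ≥ static ordering.
* Per-sample baseline offset (0.05–0.15) and slope (±5·10⁻⁵ per nm),
  multiplicative scatter per sub-spot (sd 0.02), and white noise
  (sd 0.0015 absorbance) added on the instrument grid. Absorbance is
  clipped at zero so reflectance stays in (0, 1].

All randomness flows from one master seed through per-stream
`SeedSequence` children; campaigns are byte-identical across reruns.

**What the generator does not emulate.** Scattering physics
(Kubelka–Munk), temperature-dependent band shifts, instrument drift,
stray light, and real pure-component spectra (the band library is
invented). Passing tests therefore demonstrate that the *methodology* —
preprocessing, leakage-free selection, screening, metrics — behaves
correctly under a realistic error structure, not that any particular
real instrument will achieve these numbers.

## Designed experiments (tests and acceptance script)

Problem sizes were chosen so the full suite runs in minutes on one CPU;
each experiment states its own conditions:

* *Overfitting curve*: three active band constituents (lignin's bands
  removed), no moisture, mismatch 0.05, white noise 0.0015, n = 600.
  Calibration RMSE is monotone non-increasing; pooled CV RMSE bottoms out
  at 2–4 components and deteriorates beyond ten (per-step comparisons
  allow a 1 % Monte-Carlo wiggle).
* *Parameter recovery*: all noise and the band shift off. The spectra are
  then exact linear combinations of six profiles (four constituents,
  water, baseline slope), and a six-component model explains held-out
  groups with R² ≥ 0.999. The noise grid (0.001/0.005/0.02) extends this
  configuration so white noise is the only variable.
* *Scan-mode ordering*: mismatch off, isolating sub-spot heterogeneity —
  the mechanism being probed; ten campaigns, protein, full pipeline.
* *Water interference*: widening the moisture spread (0.55–0.60 vs
  0.40–0.75) must hurt lignin (bands overlapping 1904 nm) more than
  protein.
* *Screening rates*: 100 seeded spike injections (detection via
  `either_exceeds`, see above) and 30 clean campaigns (false-alarm rate
  under the default `both_exceed` stays within the 5 % confidence budget).

## Known limitations

* The Q/T² screen refits nothing after removal (single pass); iterative
  screening would need a config loop.
* Group-aware k-fold balances sample counts greedily; exact balance is
  not guaranteed when group sizes are very uneven.
* The even-window Savitzky–Golay convention (evaluation at ⌊w/2⌋) is one
  of two defensible choices; results with the promoted odd window differ
  slightly at band shoulders.
* RPD is reported as +∞ when predictions are exact (SE = 0).
* The CLI's `validate` command re-derives the split from the seed rather
  than reading it back from the serialized split files; both paths are
  deterministic and agree, but editing serialized splits by hand has no
  effect on it.
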