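# Methods

## The calibration problem

Soluble solids content (SSC, % Brix) of fruit is predicted from Vis–NIR
reflectance spectra. A study of n = 100 fruit on a combined 486-band grid is
emulated end to end: reflectance calibration and ROI extraction, five
pretreatments, SPA wavelength selection with consensus merging, and three
regression families evaluated on a held-out prediction set by R², MAPE and
RMSEP.

## Wavelength grid

Two cameras cover 400–1000 nm (visible, VL) and 900–1700 nm (NIR, native
step 4.65 nm, 172 bands from 900 nm). The fused grid takes a uniform
336-point VL segment over 400–1000 nm and the 150 native NIR wavelengths
strictly above 1000 nm (1002.3 … 1695.15 nm), 486 bands total, strictly
increasing. In the 900–1000 nm overlap the VL camera wins (finer sampling);
the cutoff is configurable in `fuse_vl_nir`, and target bands map to the
nearest source band within a 2.5 nm tolerance.

## Synthetic spectra generator

Per sample i with SSC value s_i, absorbance is a sum of Gaussian absorbers
A_i(λ) = Σ_k d_ik exp(−(λ−c_k)²/2w_k²); ideal reflectance is 10^(−A_i).
SSC-linked absorbers have d_ik = depth_k·s_i (Beer–Lambert, depth in
absorbance per % Brix); water bands have fixed depths. The observed spectrum
is g_i·R_i + o_i + b_i(λ) + ε, with per-sample gain g_i ~ U(0.95, 1.05),
offset o_i ~ N(0, 0.005), a random quadratic baseline with coefficient scale
0.003 (the drift that motivates the derivative pretreatments), and iid noise
ε ~ N(0, 0.002).

Defaults (all configurable in `SyntheticConfig`):

| parameter | default | rationale |
|---|---|---|
| n_samples | 100 | study size |
| SSC distribution | trunc-normal(17.33, 3.18) on [10.37, 23.85] | reported calibration statistics |
| absorbers (nm) | 680, 710, 980, 1180, 1360, 1420 | chlorophyll, red edge, water ×3, carbohydrate |
| SSC-linked | 680, 710, 1360 | pigment/maturity proxies + sugar band |
| linked depths (/% Brix) | 0.012, 0.009, 0.011 | balanced reflectance-domain sensitivity (~0.015–0.017 per % Brix at each centre) |
| water depths (absorbance) | 0.30, 0.20, 0.35 | strong NIR water absorption |
| gain / offset / baseline / noise | ±5 % / 0.005 / 0.003 / 0.002 | a well-calibrated reflectance rig |
| split | seed 42, 9:1 | 90 calibration / 10 prediction |

The nuisance magnitudes model a rig after good white/dark calibration; they
are deliberately mild so that the planted SSC signal is recoverable, which is
the generator's contract (the band at 680 nm is the global argmax of
|corr(−log₁₀R, SSC)| under the defaults). What the generator does **not**
emulate: radiative transfer, cultivar structure, chemically distinct
interferents, wavelength-correlated or heteroscedastic noise, instrument
artefacts. Consequences of that are discussed under *Limitations*.

## Pretreatments

All five operate on the reflectance matrix and preserve its shape; `MSC_A`
is the only stateful one (its reference spectrum is fitted on the calibration
set and reused on the test set).

* **MSC** — per sample, regress x_i on the reference m (default: calibration
  column mean), output (x_i − a_i)/b_i; slopes |b_i| < 1e−8 are an error.
  Removes any affine gain/offset distortion exactly.
* **SG** — Savitzky–Golay smoothing, default window 11 / polyorder 2 (the
  study states neither; these are common chemometric defaults). Interior
  points use the centred convolution weights; edge points use shrinking
  one-sided local polynomial fits so no padding data are fabricated. The
  filter runs on the band-index axis, as is conventional.
* **dA / ddA** — finite differences with respect to physical wavelength
  (three-point non-uniform interior stencils, one-sided edges); the fused
  VL/NIR grid is non-uniform, so index-based differencing would be wrong.
  ddA is dA applied twice.
* **lgA** — log₁₀(1/max(R, ε)), ε = 1e−6; the absorbance-style transform.
  The other pretreatments operate on reflectance directly; an absorbance
  pre-conversion flag was considered and left off as the default.

## SPA band selection

Chains are grown on the column-centred calibration matrix. Unit-variance
scaling is available (`scale=True`) but off by default: after autoscaling
every column has the same norm, so once one informative band is selected the
projected norms of the hundreds of noise bands dominate and the chain fills
with noise bands; on centred data variance-rich bands stay attractive, which
is the classic SPA geometry.

Every column is tried as the chain start (configurable subsampling for
speed). Each (start, size ∈ [3, 10]) candidate is scored by the RMSE of an
intercept-included OLS fit, trained on a seeded internal 80/20 split of the
calibration set — the held-out prediction samples are never touched by
selection or hyperparameter search. Ties break to the smaller size, then the
smaller start index.

Consensus merging pools the five per-pretreatment selections, single-linkage
clusters them along the wavelength axis (new cluster when a gap exceeds
15 nm — configurable), ranks clusters by number of contributing
pretreatments, then pooled count, then position, and retains unique
wavelengths greedily in that order up to floor(0.10·n) = 10. Within a
truncated cluster, wavelengths selected by more pretreatments are kept first.

## Models

All three are implemented from first principles; scikit-learn serves only as
an independent cross-check in the test suite.

* **PLSR (PLS1, NIPALS)** on centred X and y; full-band runs fix 10
  components, characteristic-band runs search 2–30 by internal-validation
  RMSE (ties → fewer components). Requested components beyond the residual
  rank are truncated with a warning.
* **Lasso** minimises (1/2n)‖y − Xβ − β₀‖² + α‖β‖₁ on internally
  standardised columns (population SD), returning coefficients on the
  original scale. Cyclic coordinate descent with active-set refinement;
  convergence when the largest coefficient change in a full cycle is below
  1e−6. The iteration cap defaults to 300,000 cycles: near-unregularised
  fits (α = 0.001) on hundreds of collinear bands genuinely need ~30k–115k
  cycles at this tolerance. The kernel is numba-compiled when numba is
  importable, with an identical pure-Python fallback. Full-band runs fix
  α = 0.001; characteristic-band runs search 50 log-spaced values on
  [1e−5, 1], ties preferring the larger (sparser) α.
* **Ridge** solves (XcᵀXc + αI)β = Xcᵀyc (intercept unpenalised, α on the
  unscaled quadratic objective, matching the common library convention);
  α = 0 with a rank-deficient design is an explicit error. Both grids fix
  α = 0.001.

Centring conventions: PLSR and Ridge centre only (chemometrics practice);
Lasso standardises internally because coordinate-descent thresholds are
scale-sensitive.

## Evaluation and pipeline

`random_split` draws a seeded permutation; the train size is
round(fraction·n), giving exactly 90/10 at the study settings. R² is
reported as a fraction, MAPE as a fraction, RMSEP in % Brix. The pipeline
fans one top-level seed out to named sub-seeds (generator, split, internal
validation), so identical configs produce byte-identical report files; a
failed grid cell is reported as missing with a logged reason rather than
aborting the grid.

`recovery_study` re-runs the whole selection + modelling chain across
generator seeds and reports (a) how often the consensus intervals cover each
planted SSC-linked centre within ±10 nm and (b) how often the best
characteristic-band PLSR test R² exceeds the best full-band Ridge test R²
("best" = maximum over the five pretreatments, mirroring how the grids'
headline cells are compared).

## Limitations

* **Collinear planted signal.** Because every SSC-linked absorber's depth is
  proportional to the same scalar s_i, the three signal bands are
  functionally collinear (pairwise r ≈ 0.999). SPA's projection step is
  designed to avoid collinearity, so each pretreatment's selection carries
  essentially one signal band, and the weaker 1360 nm band survives the
  consensus ranking only occasionally. Measured over 20 seeds at defaults:
  680 nm covered in 75 % of runs, 710 nm in 75 %, 1360 nm in 10 %. Full
  joint coverage would require planting partially independent constituents,
  which the generator's Beer–Lambert contract deliberately does not do.
* **Full-band models are unrealistically strong.** With iid band noise and a
  low-order baseline, a 486-band near-OLS ridge averages noise across bands
  and reaches test R² ≈ 0.999 on every seed, so a ≤10-band model cannot beat
  it here. On instrument data the ordering reverses because real spectra
  contain high-dimensional structure a 90-sample training set cannot span.
  Passing model-quality tests on this generator therefore demonstrates
  correctness of the machinery, not expected field performance.
* SG smoothing operates on band index, not wavelength, so its polynomial
  identity holds exactly on uniform grids only.
* The internal validation split is a single 80/20 partition; RMSE-based
  choices (SPA size, component count, α) inherit its sampling noise.
  Cross-validation would stabilise them at proportional cost.
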