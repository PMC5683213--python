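# Methods

`fermspec` implements a chemometric pipeline for quantifying a substrate
(glucose) and an extracellular metabolite (citric acid) in fungal
fermentation supernatants from mid-infrared (FTIR) spectra, for two
acquisition modes: liquid measurement on an ATR crystal, and dry-film
transmission measurement on a silicon microplate (high-throughput
screening, HTS).  Because no real spectral/HPLC dataset accompanies the
pipeline, it ships a synthetic-data generator that reproduces the
statistical structure the analysis assumes, so every downstream stage is
testable end to end.

## Synthetic spectra model

Spectra are built from a band library under the Beer–Lambert assumption.
A component is a list of Gaussian (default) or Lorentzian bands
`(center, FWHM, height)`; a band contributes `height` at its centre and
`height/2` at `center ± FWHM/2`.  Default components:

* **glucose** — fingerprint bands in 1200–900 cm⁻¹ (principal peak
  1035 cm⁻¹, FWHM 30–40 cm⁻¹), heights defined at the 80 g/L reference;
* **citric acid** — acid C=O stretch at 1725 cm⁻¹ plus weaker
  1500–1000 cm⁻¹ bands, heights defined at an 80 g/L reference;
* **water** — broad bands at 3300, 2110, 1635, 580 cm⁻¹ (FWHM
  100–400 cm⁻¹);
* **lipid** — C–H stretch, ester C=O and acyl bands (for biomass-type
  spectra; not used by the supernatant workflows);
* **background** — a few very broad weak bands lumping the remaining
  medium constituents (yeast extract, salts).  Individual salts are not
  modelled; no spectral data exists for them.

A technical-replicate spectrum is

```
A(ν) = m · [ Σ_c  conc_c / (dilution · ref_c) · s_c(ν) ]  (+ water, ATR only)
       + baseline(ν) + ε(ν)
```

with `m` a per-replicate multiplicative pathlength factor
(mean 1, sd `pathlength_jitter_sd`), `baseline` a random quadratic with
max amplitude `baseline_drift_amplitude`, and `ε` white noise of sd
`noise_sd`.  Water (the solvent) is not diluted; everything else is.
The absolute AU scale is a convention — no published absorbance values
exist for this system — anchored so undiluted 80 g/L glucose gives a
0.5 AU peak at 1035 cm⁻¹.

Acquisition defaults (chosen once as physically plausible values):

| parameter | ATR | HTS | rationale |
|---|---|---|---|
| grid | 4000–500 cm⁻¹, 2 cm⁻¹ | same | finer than the 4–6 cm⁻¹ instrument resolution so band shapes are well sampled |
| dilution | 1 | 10 | HTS samples are measured 10× diluted |
| pathlength jitter sd | 0 | 0.10 | ATR pathlength is controlled; dry-film formation is irreproducible |
| baseline drift | 0.01 AU | 0.005 AU | removable by offset correction / differentiation |
| noise sd | 2·10⁻⁴ AU | 2·10⁻⁴ AU | typical 100 %-line noise of a 32–64-scan FTIR measurement; calibrated so the benchmark's error floor sits in the regime the published calibrations report |
| water | included, weight 1 | off | dry films are essentially water-free |
| biological well CV | 0.02 | 0.02 | parallel wells differ slightly; the actual per-well concentration is recorded in the reference table |

Reference concentrations are recorded *before* spectral noise; an optional
additive "reference measurement error" (`reference_noise_sd`, default 0)
supports robustness studies.

## Fermentation kinetics

Per condition, glucose decays exponentially toward a floor
(`80 → ≈8 g/L` over 12 days by default, matching a 0.444 → ≈0.04 M range),
and for the producer strain (the *P. glabrum* analogue) citric acid tracks
a fixed yield of the consumed glucose until it saturates at a plateau
(7.5 g/L at 20 °C, 6.5 g/L at 30 °C, reached around day 5–6 and stable
afterwards).  Non-producers emit exactly zero acid.  The functional forms
are a deliberate simplification: real uptake curves are only known
empirically, so rates, yields and plateaus are all exposed parameters.

## Study design

3 strains × 2 temperatures × 12 days × 3 biological wells of supernatant
(216 samples) plus 6 starting-growth-medium samples (3 bottles per
temperature), each in 3 technical replicates → 648 + 18 spectra; the
optional biomass design omits two slow-growing strain×temperature
combinations on day 1 (210 samples, 630 spectra).  The 3-bottles-per-
temperature reading of the media is the only one consistent with the
74-segment cross-validation arithmetic below.

## Preprocessing

Two frozen plans mirror the two measurement tracks:

* `atr_media`: select 1900–700 cm⁻¹ (601 points on the 2 cm⁻¹ grid),
  per-spectrum baseline offset (subtract the regional minimum).
* `hts_media`: select 1900–700 cm⁻¹, Savitzky–Golay second derivative
  (window 15 points, polynomial order 2), average technical replicates
  (666 → 222 spectra).

Savitzky–Golay derivatives are taken with respect to wavenumber (scaled by
`spacing^deriv`), so models are comparable across grids.  Edge points with
incomplete windows are dropped, not padded — padding invents data and
biases derivatives near region edges.  No baseline step precedes the HTS
derivative: the second derivative annihilates affine baselines anyway
(verified to 1e-10).  SNV (ddof = 1) and EMSC (reference + quadratic
baseline model) are provided for absorbance-invariant spectral sets such
as biomass films, but are deliberately *not* part of the media plans: the
media spectra change total absorbance by an order of magnitude over a
cultivation, which internal normalisation would destroy.

## Modeling

PCA and PLS1 are implemented directly (SVD and non-iterative NIPALS
respectively), mean-centred, no variance scaling (standard for spectra).
Component signs are fixed deterministically (largest-magnitude loading
element positive).  The PLS1 regression vector is
`b = W (PᵀW)⁻¹ q`; requesting more components than the effective rank
raises.  One analyte per model (PLS1): glucose models use all strains,
citric-acid models the producer strain only.  Media spectra are excluded
from glucose models and included in citric-acid models (both overridable);
this reproduces the published train/test arithmetic (540 = 648 − 108 and
126 = 108 + 18 for the unaveraged track).

Metrics: `RMSE`, `R² = 1 − SSE/SST` on the validation predictions (the
"coefficient of determination" reading, not squared correlation), and
`RMSE% = 100·RMSE/scale` where `scale` defaults to the maximum reference
concentration (for glucose the 80 g/L initial concentration is exposed as
an explicit override, matching the printed-percentage convention).

Component-count selection (`A_opt`): the smallest A whose RMSECV is within
a relative tolerance τ (default 0.02) of the curve minimum — an
operationalisation of "insignificantly higher error than the best model",
which published tables leave undefined.  A one-standard-error alternative
(segment-level SE of the fold MSEs) is selectable.

## Validation

* **Segmented CV**: folds are segments per (strain, temperature, day) for
  supernatant and per temperature for media — 74 segments on the full
  design (9 spectra each unaveraged, 3 averaged).  Centring is recomputed
  on each training fold; fold order is sorted for determinism; a leakage
  assertion checks that no condition straddles a fold.
* **Independent-test validation (ITV)**: all supernatant spectra of one
  strain×temperature (default: producer at 30 °C; 108 unaveraged / 36
  averaged spectra) are held out; the component count is chosen by
  segmented CV *inside* the training portion only.

## Problem sizes and determinism

The default benchmark is the full design: 666 raw spectra × 1751 grid
points per mode; the complete acceptance computation (two modes, two
analytes, CV + ITV, PCA) runs in a few seconds on one CPU.  All
randomness flows from a single integer seed per synthetic acquisition;
identical seeds give byte-identical datasets.

## What the benchmark does and does not show

The generator reproduces the *structure* of the screening experiment —
design, replication, dilution, pathlength variability, band overlap,
water interference — but not the full chemistry of a real supernatant
(minor metabolites, pigments, matrix interactions, reference-method bias
are absent; the ATR track in particular, having a controlled pathlength
and purely linear signal, is recovered almost exactly).  Passing the
recovery tests therefore demonstrates correctness of the pipeline under
its stated assumptions, not instrument-level performance on real broths.
Published real-data figures are comparable only qualitatively: the
synthetic benchmark lands in the same regime (glucose R² ≈ 0.99 with 1–3
components, citric acid CV RMSE ≈ 4–5 % with ≤ 5 components) but is not a
reproduction of them.

## Known limitations

* No ATR penetration-depth physics, scattering artefacts, atmospheric
  correction or volatile-loss modelling.
* JCAMP-DX reading supports AFFN/PAC forms only; SQZ/DIF compression is
  rejected explicitly.
* Citric-acid ITV on the dry-film track is noticeably weaker than CV
  (the training set shrinks to 42 spectra of a single condition at the
  other temperature) — the same asymmetry direction the real study shows.
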