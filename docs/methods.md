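# Methods

## Overview

`dosicomp` implements a diffuse optical spectroscopic imaging (DOSI) analysis
chain for tissue and whole-body composition. The measurement model is a
semi-infinite photon-diffusion medium probed at a 28 mm source–detector
separation by (a) intensity-modulated laser diodes at 690/785/835 nm
(multi-frequency amplitude and phase) and (b) a broadband 650–1000 nm CW
reflectance spectrometer. From these the package recovers per-site absorption
and reduced scattering, unmixes absorption into four chromophores
(oxy/deoxy hemo+myoglobin, water, fat), computes the optical fat/lean
fractions, and fits two predictive models: an exponential map from optical
fat fraction to ultrasound skin+adipose tissue thickness (SATT) and a
four-region linear model for whole-body DXA fat%/LST%.

## Forward and inverse optical models

**Diffusion Green's function.** A photon density wave from an isotropic
source at depth `z0 = 1/(mua + mus')` with an extrapolated boundary
(image source at `-(z0 + 2 zb)`, `zb = 2D(1+R_eff)/(1-R_eff)`). The internal
reflection parameter uses the Groenhuis polynomial at tissue refractive index
1.4 (`R_eff ≈ 0.53`). Amplitude is the fluence modulus, phase the positive
lag; the CW model is the same expression at zero modulation frequency, which
keeps the FD and CW stages mutually consistent by construction.

**FD inversion.** Per wavelength, `(mua, mus')` are recovered by
Levenberg–Marquardt least squares on the concatenation of log-amplitude and
phase residuals, each normalized by its noise scale (defaults 1% amplitude,
0.1° phase). Parameters are log-transformed so iterates stay positive.
Amplitude is *self-normalized* (the log-amplitude residual is mean-centred):
absolute instrument throughput is not modelled, so the fit is invariant to
any constant amplitude scale; information comes from the amplitude shape
across frequency plus the phase. Synthetic instruments use modulation
frequencies 50–400 MHz in 50 MHz steps.

**Broadband absorption.** With `mus'(lambda)` extrapolated by the scattering
power law `mus' = A500 (lambda/500)^-b` fitted to the three FD wavelengths
(log–log linear least squares), the CW reflectance is inverted wavelength by
wavelength (bracketed root solve, `mua` in `[1e-7, 1] mm^-1`). The unknown
throughput factor is calibrated so the inversion reproduces the FD-derived
`mua` anchors (geometric-mean of the per-anchor exact-match scales).
Log-reflectance is pre-smoothed with a 5-point moving average before
inversion — the physical spectrum is smooth on the nm scale, so this
suppresses uncorrelated per-point noise with negligible bias (the flat- and
structured-spectrum round-trip tests bound it). Wavelengths whose
reflectance is unattainable by any positive `mua` are flagged as gaps and
filled by linear interpolation.

**Chromophore unmixing.** Absorption is a linear mixture
`mua = eps_HbMbO2·C_HbMbO2 + eps_HbMbR·C_HbMbR + (mua_water/100)·water% +
(mua_fat/100)·fat%` with heme in uM and water/fat as percent of the
pure-substance absorption. Decomposition is non-negative least squares
(active set) on the column-equilibrated basis — non-negativity is physically
forced. The bundled extinction library is a **synthetic compilation**:
monotone-cubic (PCHIP) curves through anchor points approximating the
published shapes of oxy/deoxy hemoglobin, pure water and pure lipid spectra.
It reproduces the features the analysis depends on — oxy/deoxy isosbestic
crossing near 800 nm, lipid peak near 930 nm, water peak near 970 nm,
non-negativity on a shared 650–1000 nm/1 nm grid — but is not a verbatim
literature table; all quantitative tests are round-trip/relative and hold
for any compliant library. External libraries can be supplied as CSV
(`wavelength_nm, eps_hbmbo2, eps_hbmbr, mua_water, mua_fat`).

**Scattering-power sign.** The power-law exponent is stored positive for
normal tissue (scattering decreases with wavelength). Published parameter
tables sometimes print the opposite sign; `ScatterParams.from_reported`
accepts that convention and negates on ingest. Tests avoid depending on the
sign choice except where the stored-positive convention is itself asserted.

## Composition metrics

The optical fat fraction and optical lean fraction,

    OFF = fat / (THbMb + water + fat)
    OLF = (THbMb + water) / (THbMb + water + fat),

are deliberately mixed-unit ratios (THbMb in uM, water/fat in percent) whose
terms share a 0–200 numeric range in tissue; a unit guard rejects inputs off
that scale (water/fat outside [0, 100], THbMb > 1000). OFF + OLF = 100% by
construction. Reported in percent by default with a fraction-scale option.
Sites (three replicates each) are averaged replicate → site → region
(biceps = {BS, BL}, abdomen = {LL, LR, UL, UR}, quadriceps = {VL, RF},
calf = {GM, GL}), and OFF/OLF are computed **from the region-averaged
chromophores** (a mean-of-metrics flag exists for sensitivity checks).
Replicates are averaged at the chromophore level; averaging at the
optical-property level first would differ only at second order.

## SATT model

`SATT = a·exp(b·OFF)` with OFF on the **fraction (0–1) scale** — forced by
the reference coefficients `(a, b) = (0.2856 cm, 2.214)`, which give
physically sensible thicknesses only on that scale. Fitting is plain
nonlinear least squares in SATT space (initialization `(0.3, 2)`, tolerance
1e-10, max 500 iterations); log-SATT-space fitting was not used because the
reference procedure's objective is unspecified and SATT-space is the
plainest reading. Predictions above ~1 cm (one third of the source–detector
separation, the rule-of-thumb penetration depth) are flagged as beyond the
depth-sensitivity limit. Synthetic SATT noise is multiplicative log-normal,
keeping thickness positive by construction.

## Whole-body model

"Generalized linear model" is implemented as Gaussian family with identity
link — ordinary least squares — matching a continuous percent outcome and
the linear scatter of regional OFF vs whole-body fat%. Predictors are the
four regional OFFs (percent scale) for fat%, the OLFs for LST%; one
intercept, four coefficients. Training uses a seeded random 80/20
participant split (the same split serves both targets); evaluation on the
held-out 20% is a Bland–Altman analysis (bias = mean of predicted − measured,
limits of agreement = bias ± 1.96 sample SD; LoA undefined and flagged at
n < 2). Evaluating any training participant raises a leakage error.

## Screening statistics

Candidate parameters (THbMb, StO2, water, fat, A500, scattering power,
mus'(800 nm)) are screened against SATT by Spearman rank correlation
(average ranks on ties), two-sided p by the t-approximation (adequate at
cohort n; a permutation option exists for small samples). Significance uses
a Bonferroni-corrected threshold `alpha/n_tests`; `n_tests` is an explicit
argument because the appropriate family size depends on the comparison set
(7 parameters gives 0.05/7 ≈ 0.0071). A parameter is *retained* only if
significant **and** r² > 0.5. The two-sample t-test is pooled-variance with
a `(t, p) = (0, 1)` convention for identical zero-variance groups.

## Synthetic cohort

The generator emulates a two-layer (adipose-over-muscle) tissue: each
site's composition is a convex mixture of a lean endmember
(THbMb 125.2 uM, StO2 67.1%, water 73.0%, fat 1.1%, A500 0.87, power 1.28)
and a fat endmember (19.4 uM, 63.0%, 11.3%, 67.3%, 0.85, 0.42), with weight
`w = 1 − exp(−SATT/0.93 cm)` increasing with the skin+adipose thickness.
Heme is mixed at the (HbMbO2, HbMbR) level, so StO2 is the THbMb-weighted
average of the endmember saturations; scattering parameters mix linearly.
Quadriceps SATT is log-normal (median 0.62 cm, log-SD 0.42, clipped to
0.2–1.6 cm); other regions scale it by factors 0.7 (biceps), 1.5 (abdomen),
0.8 (calf) with 10% jitter.

Noise has three multiplicative log-normal tiers: *field* variability per
participant-region (shared by the region's sites, because the downstream
screen averages sites within a region), a 3% per-site offset, and 3%
per-replicate noise. Field CVs are parameter-specific — 10% for
THbMb/water/fat, 5% for StO2, 10% for A500, 30% for scattering power —
derived once from the correlation pattern of real quadriceps data: the large
endmember spans of the chromophores keep their SATT correlations strong
(r² ≈ 0.8–0.9), the tiny StO2 span (63–67%) and nearly equal A500 endmembers
make those parameters noise-dominated, and 30% on the scattering power puts
its r² near 0.25, weakly correlated but below the 0.5 retention bar.

Whole-body DXA fat% is planted as
`fat% = 6 + 0.08·OFF_biceps + 0.16·OFF_abdomen + 0.10·OFF_quadriceps +
0.06·OFF_calf + N(0, 3%)` on the field-noised regional OFFs, so the
regression stage has a recoverable ground truth; bone% is ~N(5, 0.4),
LST% the remainder, and masses follow from a log-normal total body mass.
An alternative `satt_mode="exponential"` replaces the recorded quadriceps
SATT by `a·exp(b·OFF_true)`, planting the exponential SATT relationship
exactly for fit-recovery checks. Demographics (age 7–34, sex) are table
dressing only; no sub-cohort effects are planted.

What the generator does **not** emulate: real layered-tissue partial-volume
physics (the exponential depth weight is a modelling choice, not a measured
kernel), instrument calibration drift, anatomical covariance between
regions beyond the shared SATT scale, intramuscular fat, or demographic
effects. Passing tests therefore demonstrate the *pipeline's* correctness
and statistical behaviour under the stated noise model, not clinical
accuracy on real cohorts.

## Numerical choices and problem sizes

- FD inversion: LM with xtol/ftol/gtol 1e-14; NNLS on column-equilibrated
  basis; CW root solve bracketed in [1e-7, 1] mm^-1 at xtol 1e-14.
- Degenerate inputs: all-zero spectrum decomposes to all-zero (not an
  error); constant SATT fits to `(a=c, b=0)`; single held-out participant
  yields a flagged, LoA-undefined Bland–Altman; constant screening columns
  are flagged undefined and never retained.
- Test-suite problem sizes (chosen to keep the default run around 1–2 min
  on one CPU): spectral round-trips at 300 random compositions; noisy-chain
  recovery at 25 trials on a 3 nm grid; SATT coefficient recovery at 500
  replicates of n = 79; screening retention at 200 seeded 99-participant
  cohorts; Bland–Altman magnitudes at 200 seeded cohorts.
- In the noisy measurement chain (1% amplitude, 0.1° phase), the recovery
  metric is the per-trial mean relative error of (THbMb, water, fat);
  fat is the worst-recovered single component (median ≈ 5%) because
  scattering-power extrapolation error from only three FD wavelengths
  concentrates in the 930 nm lipid band.

## Known limitations

- Semi-infinite homogeneous forward model only: no two-layer or Monte
  Carlo transport, no instrument-response deconvolution.
- The synthetic extinction library approximates literature spectral shapes;
  absolute chromophore values from real measurements require a validated
  instrument library.
- The anchor-calibration scheme for broadband absorption is one defensible
  reading of standard DOSI processing; real instruments calibrate against
  phantoms of known optical properties.
- Depth sensitivity limits OFF-based thickness prediction to roughly
  SATT < 1 cm at 28 mm separation; beyond that, predictions are flagged.
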