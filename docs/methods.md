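# Methods

This note documents the models implemented in `odovis`, the assumptions
behind them, the defaults of the synthetic-data generator, and the
numerical choices that matter when reproducing or extending an analysis.

## Visual-pigment template fitting

A purified rhodopsin's absorbance curve is modelled as

    A(λ) = a · S(λ; λ_max) + b

where `S` is the Govardovskii A1 α+β-band template, a one-parameter curve
family standard in visual ecology, peak-normalized numerically on a 0.01-nm
grid so that max S = 1 within 1e-6. Fitting is a one-dimensional search:
for each candidate λ_max on a grid (default 330–620 nm, 1-nm step) the
amplitude `a` and constant baseline `b` are solved in closed form by linear
least squares, and the minimal-SSE candidate (ties resolved toward smaller
λ_max) is refined by golden-section search to 0.1 nm. The baseline can be
fixed at 0 by flag. A model-free alternative (`kind="polynomial_peak"`)
fits a quartic within ±40 nm of the raw maximum and reports its vertex; it
is useful as a template-agnostic cross-check but has no α/β-band structure.

Preprocessing subtracts the mean absorbance in a long-wavelength baseline
window (default 650–700 nm, where the pigment no longer absorbs) and
peak-normalizes within the fit window (default 330–650 nm, which avoids
the protein absorbance region below ~330 nm). Difference spectra
(dark − bleached) are formed on a shared 1-nm grid by linear
interpolation; extrapolation is never performed.

One caveat of the published α-band form: its analytic maximum drifts
slightly below the nominal λ_max parameter for λ_max ≲ 370 nm (about
1.25 nm at 360 nm). This does not bias fitting — the fit compares data to
template curves generated with the same convention, so the λ_max
*parameter* is recovered exactly in self-consistent tests — but the peak
of the *curve* and the parameter should not be conflated near the UV end.

### Bootstrap uncertainty

Uncertainty in λ_max comes from a residual-resampling bootstrap: residuals
of the fitted curve are resampled with replacement across wavelength
points, added back to the fitted curve, and each pseudo-spectrum is
refitted (default 1000 replicates); the 95% CI is the percentile interval.
Resampling wavelength-point residuals, rather than replicate spectra, was
chosen because replicate measurements are aliquots of a single protein
preparation with small and unequal replicate counts (1–6), too few to
resample at the replicate level. Bootstrap refits use the grid search with
three-point parabolic interpolation of the SSE minimum instead of the
golden-section step — this keeps bootstrap estimates continuous at a small
fraction of the cost, and the two refinements agree to well under the
0.1-nm refinement tolerance on smooth SSE profiles. At the generator's
default noise (sd 0.02 of peak height), measured coverage of the nominal
95% interval is 91–95%, the usual mild undercoverage of percentile
intervals.

## Efficiency-corrected qPCR expression

Primer efficiency comes from a dilution-series standard curve,
`E = 10^(−1/slope) − 1`, with slope from the least-squares fit of Ct on
log10 input amount; a non-negative slope signals a failed assay.
Efficiencies outside [0.7, 1.15] are rejected; outside [0.9, 1.1] they
warn. Relative expression uses the efficiency-corrected ΔΔCT family: per
individual and technical replicate, each gene's quantity `(1+E_g)^(−Ct_g)`
is divided by the geometric mean of two housekeeping-gene quantities (the
standard multi-reference normalization) and calibrated against the UV
opsin measured in the same individual and replicate, so UV relative
expression is 1 by construction. When all efficiencies are 1 this reduces
exactly to the classic `2^(−ΔΔCT)`.

Replicates are combined *after* the ΔΔCT step by averaging on the natural
log scale (the per-individual value is therefore the geometric mean across
replicates); the alternative of averaging Ct first is available by flag.
Logs are natural throughout, recorded in output metadata. Missing Ct
values are treated as missing, never imputed as a ceiling cycle;
individuals missing the calibrator are skipped with a logged warning, and
individuals missing more than two opsins are excluded. Proportional
expression divides each compound-eye opsin's relative expression by the
summed relative expression of the compound-eye set {UV, SW1, SW2, LWA,
LWF1–F4}; LWE is excluded from the proportion set by default because its
orthologues are ocellus-restricted, but the set is configurable.

## Receptor-noise-limited visual modelling

Quantum catch is the trapezoidal integral of sensitivity × reflectance ×
illuminant on a shared 1-nm grid (300–700 nm, intersected with the
spectra's supports; at least 100 nm of overlap is required). Catches are
von-Kries-adapted (divided by the catch of the adapting background), so
any rescaling of the illuminant cancels exactly. Receptor signals are
log-transformed (`Δf_i = ln(q_i^A/q_i^B)`), appropriate for contrasts well
above threshold. Channel noise is `ω_i = ν·sqrt(η_ref/η_i)` with Weber
fraction ν attached to the reference (most abundant) receptor class and η
the relative receptor abundances. Chromatic distance ΔS uses the closed
dichromat and trichromat receptor-noise forms, dispatched on receptor
count (2 or 3); both agree with the general quadratic-form formulation
`ΔS² = Δf'·(D − D11'D/1'D1)·Δf`, `D = diag(ω_i^−2)`, to 1e-9. The
achromatic JND is the single-channel contrast `|Δf|/ω` on a chosen
(default LW) receptor. ΔS is in JND units: 1 is the nominal
discrimination threshold.

Named variants: `LWF1` and `LWF2` are trichromats {UV 350, SW 416, LW 531
or 543 nm} whose LW peak is the in-vitro λ_max of the corresponding opsin;
sensitivities are generated from the A1 template unless measured curves
are supplied. Defaults ν = 0.1, η = (1, 1, 2), flat photon illuminant.
These are documented assumptions, not measured values: the Weber fraction
and abundances of damselfly photoreceptors are unknown, so every parameter
is config-overridable and conclusions should be read as orderings, not
absolute JNDs. The `ERG` variant stands in for a whole-eye
electroretinogram-based system and *requires* measured curves via config;
without them it runs on a clearly flagged placeholder and warns. No
ocular-media filtering is applied.

Because von Kries adaptation cancels in the two-stimulus log-ratio, the
chromatic JND of a stimulus pair is independent of the chosen background;
backgrounds matter for detection tasks (where the background is itself one
of the stimuli) and would matter under alternative adaptation models.

## Morph frequencies and year comparisons

Frequencies are computed among mature females only (immature colour phases
do not identify the genetic morph), per site × year, with across-site
mean, sd and range per year. Sites with zero mature females are flagged
and excluded from summaries. Between-year comparisons per site use the
Pearson chi-square on the 2 × k table after dropping morphs absent in both
years, switching to a full-enumeration two-sided Fisher exact test
(multivariate hypergeometric, summing probabilities ≤ the observed
table's) whenever any expected count is ≤ 5 — with a rare third morph this
is the common case.

## Quadratic expression-frequency trends

The trend module fits, per opsin × stage, ordinary least squares of
replicate-averaged per-individual log relative expression on the site's
mature-female androchrome frequency and its square. This is deliberately
the marginal fixed-effects analogue of a full mixed model: site, year and
individual random effects are out of scope, and the replicate averaging
restores one-row-per-individual independence. The vertex −β1/(2β2) is
reported only when the curvature is supported (|t| > 2). When a family of
opsin × stage fits is screened at once, `convexity_screen` applies a Holm
correction across the family before declaring a trend convex; an
uncorrected per-fit |t| > 2 rule would false-alarm on some member of a
16-fit family in roughly a third of datasets (the per-individual residuals
share the UV-calibrator noise, so the fits are positively dependent, but
Holm's familywise control holds under arbitrary dependence).

## Synthetic-data generator

The generator produces every input the chain consumes, with all true
parameters written to manifests. All randomness flows from one top-level
seed through fixed per-generator streams, so outputs are byte-identical
given a config regardless of call order.

* **Absorbance**: A1 templates at the eight in-vitro opsin λ_max values
  {SWb1 397, SWb2 416, LWF1 531, LWE1 533, LWF4 541, LWF2 543, LWF3 545,
  LWA2 548 nm} plus i.i.d. Gaussian noise (sd 0.02 of peak height, three
  replicates, 1-nm grid 300–700 nm). Real spectrometer noise is
  heteroscedastic and serially correlated; passing recovery tests here
  demonstrates estimator correctness under the stated noise model, not
  robustness to instrument artefacts.
* **qPCR**: 87 males (8 teneral, 36 immature, 43 mature) cycled across 8
  sites whose androchrome frequencies span 0.571–0.857. Per-stage mean
  log2 expression relative to UV is shaped so LWF4 dominates teneral heads
  while LWF2 rises (to ~0.5–0.6 of compound-eye expression) and LWF1 falls
  over maturation, with LWE lowest throughout. Mature-male LWF2 carries a
  convex quadratic term β2·(x − 0.72)² in androchrome frequency x with
  β2 = 50 natural-log units (≈2–4-fold elevation at the frequency
  extremes); β2 was sized by an a-priori power calculation to give the
  curvature t-statistic an expectation near 6 at these sample sizes, i.e.
  comfortable power after Holm correction. Biological scatter 0.3
  (natural log), technical replicate noise 0.15 Ct, two stable
  housekeeping genes, per-gene efficiencies in [0.93, 1.02]. Quantities
  convert to Ct through `Ct = −ln(quantity·scale)/ln(1+E)`, landing in
  the 19–31 cycle range.
* **Reflectance**: Gaussian peaks for the blue androchrome (450 nm, peak
  reflectance 0.55) and green infuscans (550 nm, 0.28 — roughly the
  twofold overall brightness separation between the morphs), a broad green
  vegetation peak and a brown long-wavelength logistic ramp, plus a flat
  photon illuminant. Random morph-pair draws jitter peak position (sd
  5 nm), width (2 nm) and amplitude (5%). These shapes emulate the
  qualitative structure of measured morph and vegetation spectra, not any
  published curves; absolute JNDs computed from them are illustrative.
* **Morph counts**: multinomial draws of 60 mature females per site × year
  at the site frequencies above (rare infuscans-obsoleta at 0.03), with
  one site shifting to androchrome frequency 0.45 in the second year (the
  detectable between-year change) and one site losing the rare morph.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on generator output:
200 spectra for the recovery rate, 200 simulations × 200 bootstrap
replicates for CI coverage (1000 replicates for the per-pigment CIs), 100
generator replicates for the quadratic-detection rate, 100 jittered morph
pairs for the directional JND property, and 500 simulations for the
curvature-contrast recovery check. These sizes give the binomial
assertions comfortable margins at the documented thresholds.

## Known limitations

* A1 chromophore only; no A2 templates, metarhodopsin kinetics or
  photobleaching time series.
* Chromatic model limited to 2–3 receptor classes; no ommatidial-level
  opsin co-expression, retinal regionalization, polarization or temporal
  vision.
* No mixed-effects machinery: random-effect structures should be fitted in
  a dedicated stats environment on the tidy tables this package exports.
* The ERG variant is a stub until measured whole-eye sensitivities are
  supplied.
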