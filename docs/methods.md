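# Methods

This note documents the models, conventions and numerical choices behind
`ftirfg`, and what the synthetic-data tests do and do not demonstrate.

## Spectra and units

Spectra are transmission-mode absorbances A(ν̃) on a canonical descending
grid, 4000 → 400 cm⁻¹ at 4 cm⁻¹ spacing (901 points); readers resample
arbitrary monotone grids onto it by linear interpolation, never
extrapolating. Absorbance is in AU; band areas in AU·cm⁻¹. Bond abundances
are **µmol per filter** throughout: at that scale the anthracene-derived
OOP absorptivity of 0.017 (response per µmol of CH bond) maps realistic
filter loadings onto peak heights of 0.01–1 AU. Absorptivities are therefore
empirical response-per-µmol constants under this normalization — height
responses in AU µmol⁻¹, area responses in AU·cm⁻¹ µmol⁻¹ — rather than
dimensioned molar absorptivities. Masses are µg per filter; emission factors
mg MJ⁻¹. Negative absorbances arising from corrections are preserved and
summarized by a per-spectrum negative-point fraction; clipping would bias
every downstream fit. Standard deviations use the n−1 denominator
everywhere.

## Baseline model

The raw spectrum of a loaded PTFE filter rides on a smooth background from
membrane/particle scattering plus the electronic-transition absorption of
elemental carbon, which rises toward high wavenumber. It is removed with a
cubic smoothing spline fitted **only** to grid points inside anchor windows
chosen to be free of organic bands:

4000–3750, 2750–2500, 1900–1800, 980–900, 680–620 cm⁻¹ (configurable).

The 2750–2500 cm⁻¹ window is special: the very broad dimerized
carboxylic-acid OH (3400–2400 cm⁻¹) places real signal there, and a spline
anchored on it absorbs band intensity — worse, a cross-validated spline
interpolates the 2600 cm⁻¹ acid doublet to zero, erasing the very evidence
needed to detect the problem. The per-sample chain therefore baselines
**without** that anchor first, tests the corrected spectrum for (a) the
two-doublet acid signature and (b) any systematic positive mean inside the
window (threshold: max(2·10⁻⁴ AU, 3× the noise standard error)), and only
re-adds the anchor when the window is verified clean.

Penalty selection ("auto"): if the anchors are effectively noiseless
(robust noise < 10⁻⁶ AU from second differences of grid-adjacent anchor
points) the penalty is chosen by generalized cross-validation, which then
interpolates the smooth anchor signal essentially exactly. With noise, GCV
on clustered anchor windows undersmooths badly — it interpolates the noise
and lets the spline swing freely across the wide unanchored gaps — so the
penalty is instead chosen by the discrepancy principle: bisection in log λ
for the smallest λ whose anchor residual RMS reaches the noise estimate.
A fixed λ is accepted in configuration. Note that λ ≳ 10¹⁶ on this grid is
numerically unstable in the spline solver; the λ→∞ straight-line limit is
reached in practice near λ ≈ 10¹⁴.

The spline value at 4000 cm⁻¹ is recorded per sample and can be regressed
(OLS with intercept) on collocated EC and OC loadings; the EC/OC coefficient
ratio quantifies how strongly elemental carbon drives the spectral
baseline.

## Blank subtraction

Each baselined sample is paired with the library blank whose PTFE reference
peak height (max over 1180–1120 cm⁻¹) is closest, ties broken toward the
lexicographically smallest blank id. The subtraction scale s ≥ 0 minimizes
the squared residual over the PTFE-dominated window 1300–1000 cm⁻¹ — this
uses all the PTFE band structure and is robust to noise; the simple
peak-height ratio is retained as a diagnostic in the match record. The
1300–1000 cm⁻¹ window is excluded from all downstream fitting and
reporting.

## Band model and fitting

All bands are Gaussian (no line-shape information justifies Voigt here);
the fixed band table places them at standard assignments: aCOH 3500, rCH
stretch 3050, aliphatic CH₃/CH₂ 2960/2920/2850, broad acid OH ~2900
(σ 150–350), acid doublets 2600/2400, carbonyl 1700, aromatic C=C 1600,
lignin ring 1515, nitrate 1400/830, aromatic CH OOP 750 cm⁻¹. Three
sub-peaks model the aliphatic CH region; the fitted CH₃/CH₂ ratio is a
diagnostic, not a calibrated quantity.

Fit regions are 3700–2300, 1850–1350, and 900–650 cm⁻¹. The OH/CH stretch
super-region is deliberately fitted as **one** window: the broad acid OH
spans both the 3500 and the 3000–2400 neighbourhoods, and splitting it
across two windows leaves each window a truncated half-Gaussian that is
nearly collinear with that window's local baseline term (observed worst-case
area errors ≈ 190% on noiseless synthetic spectra); the merged window also
gives the 2400 cm⁻¹ doublet full support.

Each window adds a local residual-baseline term, parameterized as a centered
offset + tilt and **bounded at ±0.02 AU**. The bound matters: an unbounded
linear term is quasi-collinear with the broadest band over the window, and
the optimizer can drift into a degenerate valley (huge Gaussian minus huge
ramp) with near-identical residual but badly misattributed area. After a
competent global baseline the true window residual is ≪ 0.02 AU, so the
bound costs nothing; its fitted values are reported for QC.

Parameters are bounded (amplitude ≥ 0, center within ±tol of its
assignment, σ within per-class bounds) and optimized by trust-region
least squares with tight tolerances (xtol = ftol = gtol = 10⁻¹³; looser
settings visibly degrade noiseless recovery). Non-convergence yields a
flagged result with NaN responses, never an exception. Reported height and
area satisfy area = height·σ·√(2π) identically.

The acid signature is declared present only when **both** doublets (2600
and 2400 cm⁻¹) rise above the local envelope (a median chord across their
flanks) by more than 3× the spectral noise *and* above an absolute floor of
2·10⁻³ AU — the floor represents an instrument-scale detection limit and
prevents a pure-SNR rule from firing on arbitrarily small structure in
noiseless data. Quantification statements in the tests are restricted to
bands with height ≥ 0.01 AU (~5× that floor); below it, relative recovery
of a quasi-flat broad band is not meaningful.

## Calibration and composition

Calibrations are through-origin by default (a blank filter has zero
analyte); the R² is reported against the fitted line with the conventional
centered total sum of squares. Anthracene standards convert areal mass
loading to bond abundance via M(C₁₄H₁₀) = 178.234 g mol⁻¹ and 10 CH bonds
per molecule. Negative fitted responses invert to 0 µmol with a clip flag.

Default absorptivities ship as configurable constants: 0.017 for the OOP
height response, placeholder area absorptivities of literature lineage for
the others (aCH 0.35, aCOH 1.2, broad acid OH 2.0, carbonyl 0.5, rCH
stretch 0.10, doublets 0.2) — to be replaced by laboratory values where
available. Because the synthetic generator emits bands through the same
table, recovery tests exercise the inversion without asserting the
placeholder values themselves.

The carbonyl band counts acid and non-acid C=O together; since each COOH
carries exactly one acid OH and one C=O, COOH = min(carbonyl, acid OH) and
the remainder is naCO. This conserves carbonyl moles and never invents acid
beyond either measurement.

The attribution table (per µmol of bond): aCH — 0.5 C, 7.014 µg (CH₂
assumption); rCH — 1.4 C, 17.823 µg (anthracene-like, consistent with the
PAH conversion); aCOH — 1 C, 29.018 µg; COOH — 1 C, 45.017 µg; naCO — 1 C,
28.010 µg. Every row must carry more mass than its attributed carbon, which
makes OM ≥ OC a table-level invariant. Back-filter artifact correction is a
plain difference with negatives retained and flagged (back/front ratios
above 1 occur for semivolatile-rich emissions). Emission factors:
EF = mass·(tunnel flow·1000/sample flow)/energy, output in mg MJ⁻¹.

## PLSR and VIP

PLS1 by NIPALS on mean-centered, **unscaled** X — the absorbance scale is
physically meaningful, so a wavenumber's variance should count. Component
selection by 5-fold cross-validation (seeded fold assignment recorded in
the model) minimizing RMSE with a one-standard-error parsimony rule; a
fixed component count is also accepted. Requested components beyond the
data rank truncate with a flag. VIP uses the standard weighted-weights
formula with per-component explained y-variance SSY_a = q_a²·t_aᵀt_a; with
unit-norm weights Σ_j VIP²_j = p holds identically. Influential intervals
are contiguous runs of VIP > 1 (the conventional threshold, configurable),
annotated with any band whose ±2σ_max extent overlaps them. The spectra
matrix for study-level VIP excludes the PTFE window.

## Synthetic generator

A sample spectrum is
A(ν̃) = (b₀ + k_EC·EC + k_OC·OC)·(ν̃/4000)² + c + i·PTFE(ν̃) + Σ n_g ε_g g(ν̃) + noise,
with k_EC = 2.2·k_OC = 1.1·10⁻³ AU µg⁻¹ so the EC-baseline diagnostic is
recoverable by construction; PTFE is a fixed three-Gaussian cluster
(1210/1152/1110 cm⁻¹) of unit peak height scaled per filter; band
abundances are lognormal per fuel archetype. The archetypes encode the
qualitative emission profiles of the three FG-analysable fuels: red oak
(dominant broad aCOH, carbonyl, aromatic C=C, lignin band, nitrates),
kerosene (aromatics-rich, frequent acid signature, CH₃-rich aliphatics),
charcoal (strong aCH and C=C, little else); alcohol and LPG archetypes emit
near-blank spectra. Default study mix: red oak 0.45 / charcoal 0.35 /
kerosene 0.20. Default spectral noise is 0.002 AU (~2% of a typical strong
band height).

Pseudo-references mirror the structure of collocated measurements:
pseudo-thermal-optical OC = FG-OC·(1+δ) with δ = +0.67 by default, so
spectroscopic OC recovers ~60% of the reference, the characteristic
under-recovery of functional-group carbon budgets; a back-filter fraction
drawn from U(0.06, 0.5) exercises artifact correction; pseudo-GC-MS PAH
sum = spectroscopic PAH mass / k with k = 19.6 by default, the scale of
the spectroscopy-vs-chromatography gap (the OOP band sees aromatic CH in
*all* compounds, chromatography only the target list). All reference noise
is multiplicative, 5% relative by default. Everything is reproducible from
a single integer seed.

What the generator does **not** emulate: instrument line shape and
apodization, wavenumber calibration error, water-vapor/CO₂ features,
detector nonlinearity, band-shape deviations from Gaussian, correlated
(pink) noise, and real between-compound absorptivity variation (~30% for a
given FG). Passing recovery tests therefore demonstrate the correctness and
conditioning of the inversion chain under its own model assumptions, not
field accuracy on real filters.

## Problem sizes and performance

The test suite and the acceptance script use 50 spectra for baseline
recovery, 20 for peak-fit recovery, 12 calibration standards, and one
60-sample study for the end-to-end and VIP checks — sizes chosen so each
stage's statistics are stable while a full run stays in the minutes range
on a single CPU (the 60-sample study processes in ≈ 40 s).

## Known limitations

- Gaussian-only profiles; Voigt/Lorentzian would need a band-table schema
  extension.
- The clean-window re-anchoring test is one-sided (positive mean); a
  negative artifact under the 2750–2500 cm⁻¹ window would not trigger it.
- The carbonyl apportionment is a hard min rule; partial acid/ester overlap
  is not modeled.
- EC is an external input; the baseline-at-4000 regression is a diagnostic,
  not a calibrated EC estimator.
- Component count for study-level VIP defaults to 3; cross-validated
  selection is available but slower and is not the default in the pipeline.
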