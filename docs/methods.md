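# Methods

## Data model

A `Spectrum` is an absorbance vector on a strictly increasing
wavenumber grid (cm⁻¹).  The canonical analysis grid is 800–3500 cm⁻¹
at 1 cm⁻¹ spacing with the 1800–2800 cm⁻¹ window excluded, i.e. two
uniform blocks (1001 + 701 points).  The acquisition convention the
package emulates records at 2 cm⁻¹ resolution; the 1 cm⁻¹ synthetic
grid oversamples harmlessly and keeps reported peak positions on
integers.  All intervals in the API are closed and expressed in
physical cm⁻¹ — no index arithmetic.  Operations that need uniform
spacing (Savitzky–Golay filters, median filters) act independently on
each contiguous uniform block, so the inter-block gap and any excised
windows never leak filter artifacts across edges.

Fingerprint analyses (clustering, dynamics) use 800–1800 cm⁻¹ with
1350–1500 cm⁻¹ excised.  That window is dominated by paraffin CH₂/CH₃
deformation bands in FFPE tissue and would otherwise bias every
between-group comparison; derivatives are computed on the contiguous
fingerprint block *first* and the window excised afterwards.

## Preprocessing chain

Order: resample → average replicates → rubberband baseline → vector
normalize.  The order of the last two steps is a design choice (the
emulated protocol lists both without ordering); baseline-before-
normalize keeps the unit-norm contract on the signal actually
analyzed.

*Rubberband baseline.*  The axis is split into 64 equal-width segments;
the spectrum minimum of each segment is a candidate node; the baseline
is the piecewise-linear lower convex hull through the candidates plus
both endpoints, subtracted from the spectrum.  This reproduces the
contract of the proprietary instrument-software algorithm (a concave
baseline touching the spectrum from below at ≤ 64 points) in a single
deterministic pass.  The corrected spectrum is exactly zero at every
hull vertex.

*Vector normalization.*  Subtract the mean, scale to unit Euclidean
norm.  The divisor is recorded in `meta["norm_factor"]` so absolute
amplitudes remain reconstructible (the dynamics-signature injection
uses this).

*Derivatives.*  Savitzky–Golay: window 9 / polyorder 3 for second
derivatives (resolves components ~6 cm⁻¹ apart on the 1 cm⁻¹ grid
without ringing), window 7 / polyorder 2 for the first derivative used
by the dynamics statistic.  Output length equals input length
(polynomial edge handling).

## Amide I deconvolution

The 1600–1700 cm⁻¹ slice is detrended by the chord through its
endpoint absorbances.  Component positions are the minima of the SG
second derivative, restricted to *negative* curvature (a positive
second derivative marks a valley between bands, not a band), with
prominence ≥ 5% of the deepest minimum; minima closer than 3 cm⁻¹ are
merged keeping the deeper.  The fit is a bounded nonlinear least
squares (lmfit / trust-region reflective) of a sum of Gaussians —
centers within seed ± 3 cm⁻¹, σ ∈ [2, 20] cm⁻¹, areas ≥ 0 — **plus a
free linear term**.  The linear term exists because the endpoint
detrend subtracts a chord that a pure Gaussian sum cannot represent
(the 1691 cm⁻¹ component has a real tail at 1700 cm⁻¹); without it,
component areas near the slice edges are biased.  Composition is
reported from the Gaussian areas only; components below 0.5% of total
area are dropped without re-fitting.  Structure classes by center:
β-sheet < 1645 ≤ α-helix < 1662 ≤ β-turn < 1685 ≤ β-sheet, half-open
on the left; the boundaries are interpolated between the reference
component assignments (1630/1631, 1641 and 1691 β-sheet; 1648–1659
α-helix; 1679/1680 β-turn) and are configurable constants.
"Others" pools β-turn with any unassigned component.

## Multivariate stage

Feature vectors are per-sample second derivatives on the excised
fingerprint grid (850 points).  PCA mean-centers columns but never
variance-scales them: all columns share absorbance units, and scaling
would inflate flat spectral regions.  Clustering is UPGMA
(average linkage) on Euclidean distances, via scipy; a brute-force
cubic-time UPGMA serves as an independent oracle in the tests.
Flat cuts demand exactly *k* clusters and report a diagnostic when tied
merge heights make that impossible.  Outlier screening flags leaves
whose first merge height exceeds median + 3·IQR of all merge heights
(flagged, never silently removed).  Purity of a cut is
Σ_c max_g n(c,g) / n.

## Absorbance dynamics

The control envelope is the per-wavenumber mean and SD (ddof = 1) of
control first derivatives on the excised fingerprint grid.  The SD is
floored at 10% of its median over the grid: with n = 4 control
subjects the raw per-wavenumber SD is unstable and can degenerate
toward zero, which would make the threshold rule flag everything.
"Significantly altered" is operationalized as exceeding k·SD
(default k = 2, configurable); the discrimination probability is the
percentage of patients altered at each wavenumber, overall and per
subtype; band summaries report (min–max) of P(ν) over each marker
band, the reading under which a one-wavenumber band gives a single
number and wider bands give ranges.  The false-positive rate of the
rule is testable: under Gaussian additive noise and no signal, the
flag rate matches the two-sided normal tail for k = 2 (≈4.6%), which
the test suite checks with 64 controls and 200 patients.

In the cohort pipeline the envelope is built from **individual control
replicate spectra** (4 subjects × 3 replicates → 11 df for the SD)
while each patient enters as their **replicate-averaged** spectrum.
With only four control subjects, a subject-level SD would have 3 df
and make the k·SD threshold itself the dominant noise source; pooling
replicates is the minimal stabilization, and representing a patient by
the mean of their triplicate is the standard reduction.  The module
functions are agnostic — they analyze whatever `SpectrumSet` they are
given — so other conventions are one call away.

## Synthetic-spectrum generator

Forward model per spectrum: A(ν) = Σ bands + Σ amide-components +
baseline + ε.  Bands are Gaussians at the reference-atlas positions of
the sample's group (σ = 8 cm⁻¹ fingerprint, 12 cm⁻¹ for the broad
3283 cm⁻¹ N–H/O–H band); the amide I region carries both a dominant
envelope band (amplitude 1.0, the fingerprint maximum) and six narrow
components (σ = 2.5 cm⁻¹) whose centers follow the group's column and
whose areas realize the group's composition row — class mass split
equally within a class, "others" realized as the β-turn component
(the reference table lists exactly six components; both conventions
are recorded assumptions, not facts of the emulated study).  The
baseline is a gentle concave quadratic (coefficients 0.05/0.04/0.03
over the normalized axis) so the rubberband stage has real work.

Default σ for the amide components is 2.5 cm⁻¹ because the two
α-helix components sit only 6–11 cm⁻¹ apart: at σ ≥ 3.5 cm⁻¹ their
second-derivative minima merge and six-component seeding is
physically impossible on the synthetic truth.  The corresponding
FWHM (~6 cm⁻¹) is narrower than typical protein sub-bands; this is a
deliberate trade so that the seeding → fitting → composition loop is
exactly testable.

Noise model defaults: additive white noise SD 0.004 (≈0.4% of the
amide I peak, plausible for 32-scan ATR), per-sample amplitude jitter
5% CV, per-sample center jitter 0.2 cm⁻¹; replicates share the
sample's jittered profile but draw fresh additive noise.  The jitter
and the weak C=O shoulder amplitude (0.02 at 1737/1734 cm⁻¹) are set
so that the generator realizes the qualitative structure the analysis
is meant to exhibit — classic and anaplastic profiles most similar,
desmoplastic and control separated, and the carbonyl-band dynamics
signature detectable in every tumor — since that structure *is* the
study condition being emulated.  Larger center jitter (≥0.5 cm⁻¹)
drowns the desmoplastic separation; a stronger C=O shoulder puts a
fixed systematic on the anaplastic dynamics at 1714–1716 cm⁻¹ that
competes with the injected signature.  All defaults were frozen after
those checks and are not tuned per seed (the test suite passes across
dozens of generator seeds).

*Signature injection.*  The 1714–1716 cm⁻¹ alteration is modeled as a
smooth downward erf step (loss of carbonyl shoulder intensity) added
to every tumor spectrum.  Its amplitude is calibrated so that the SG
first derivative of the perturbation is at least `magnitude` × the
cohort's own preprocessed control-derivative SD at *every* grid point
of the band (the spec of the operation demands "somewhere"; covering
the whole band is the stronger reading), mapped back to raw absorbance
units via the recorded normalization factors.

## What the generator does and does not emulate

It reproduces: band positions and group-specific presence/absence,
composition-driven amide I shape differences, paraffin bands, smooth
baselines, replicate structure, cohort sizes, and a dynamics marker
band.  It does **not** model ATR penetration-depth effects, Mie or
other scattering, atmospheric compensation residues, water-vapor
lines, correlated (pink) detector noise, or biological heterogeneity
beyond independent per-band jitter.  Passing tests therefore
demonstrate that the *pipeline* recovers planted structure correctly,
not that real FFPE cohorts of this size would separate as cleanly.

## Numerical choices and degenerate inputs

- Read/write round trips are exact to better than 1e-12 (`%.17g`).
- Descending instrument axes are silently reversed; duplicate
  wavenumbers are an error naming the offending value.
- `resample_to_grid` never extrapolates.
- Excising everything, constant spectra in `vector_normalize` (detected
  via exact zero peak-to-peak), empty groups, grids shorter than the
  baseline-segment count or SG window: all raise typed errors.
- Peak detection thresholds prominence at max(3×MAD of the high-pass
  residual, 0.5% of the spectrum's dynamic range); the relative floor
  exists because on noise-free synthetic input the MAD collapses to
  exactly zero (a median filter reproduces locally monotone signals).
  Atlas matching is nearest-first and injective with a 4 cm⁻¹ default
  tolerance — the largest within-row spread in the atlas is 5 cm⁻¹,
  so 4 separates neighboring rows while absorbing jitter.
- UPGMA ties are resolved by scipy's deterministic merge order; the
  cut-k operation verifies the requested cluster count and raises
  with a diagnostic when duplicate heights collapse it.
- Amide fits restart once with seeds shifted +0.5 cm⁻¹ before
  reporting non-convergence.

## Problem sizes

The shipped tests and the acceptance script run the default cohort
(132 spectra × 1702 points), a 264-spectrum null-calibration study,
and 100 random UPGMA oracle instances with ≤ 12 leaves; the whole
suite completes in well under a minute on one CPU.

## Known limitations

- The amide-component width needed for exact six-component seeding is
  narrower than physically typical; on real spectra, Fourier
  self-deconvolution or wider SG windows would be needed and the
  six-minimum guarantee would not hold.
- The k·SD alteration rule is an operationalization; the original
  "absorbance dynamics" criterion is not published in formula form.
- With four control subjects the SD envelope, even pooled over
  replicates, is noisy; the 10% median floor and the replicate
  pooling are pragmatic, documented mitigations, not optimal
  statistics.
- Cohort-level amide I deconvolution of *full* spectra mixes the
  unresolved amide envelope band with the six components, so group-mean
  compositions from `run-all` are qualitative; exact composition
  recovery holds for pure amide bands (`synth.amide_band`), which is
  what the acceptance checks exercise.
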