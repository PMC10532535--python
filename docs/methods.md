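# Methods

## Problem and data model

An ATR-FTIR absorbance spectrum of a polysaccharide extract is a trace
A(ν̃) on a uniform wavenumber grid; the canonical acquisition grid is
0.482 cm⁻¹ spacing over 400–4000 cm⁻¹ (16-scan, resolution-4 mid-IR ATR
practice). Spectra are stored ascending; samples are coded by species,
month, year and replicate (triplicate measurement is the norm). No public
raw spectra exist for the target systems, so the package treats the
synthetic generator (below) as its test bed and states explicitly what that
does and does not demonstrate.

## Conditioning

Peak heights and between-spectrum comparisons are meaningless on raw ATR
absorbance: contact pressure scales the trace and scattering adds a broad
baseline. The conditioning recipe is crop → baseline → normalize:

- **Crop** is closed-interval on [lo, hi]. Named windows: full 400–4000,
  mid-IR 500–4000, carrageenan band table 800–1240, red-algal PCA 580–1350,
  brown-algal PCA 500–1600 cm⁻¹.
- **Baseline**: asymmetric least squares (Eilers), minimizing
  Σwᵢ(yᵢ−zᵢ)² + λΣ(Δ²z)² with w = p above the baseline and 1−p below,
  λ = 1e5, p = 0.01, 10 iterations. On the canonical grid this removes a
  linear drift to numerical precision and preserves an isolated band apex
  to better than 2% (verified in the test suite). λ and p are declared
  defaults: the source workflows never state their baseline treatment.
- **Normalization**: SNV (per-spectrum mean 0, sd 1 over the window) by
  default, removing the multiplicative pathlength factor; max-in-window
  normalization is available for display.
- **Smoothing/derivatives**: Savitzky–Golay, 21 points (≈10 cm⁻¹) and
  polyorder 3 — wide enough to suppress noise, narrow enough to keep
  shoulders that 12–18 cm⁻¹ FWHM bands produce.

## Peak and shoulder detection

Apexes are prominence-filtered local maxima of the smoothed trace with
3-point parabolic sub-grid refinement; on noise-free planted bands
(FWHM 6–30 cm⁻¹) the position error is below half a grid step. Shoulders —
partially resolved bands riding a stronger neighbor — are minima of the
Savitzky–Golay second derivative at least 2 grid steps away from any apex,
above 10% of the window's maximum |d²A/dν̃²|.

Two noise guards matter in practice and are part of the design: (i) the
prominence threshold is the larger of 2% of the window span and five times
the noise level propagated through the smoother (noise sd estimated
robustly from the smoothing residual via the median absolute deviation);
(ii) the second derivative is computed on a doubled smoothing window, with
an analogous five-sigma floor, and a shoulder must carry at least 15% of
the window's maximum absorbance. Without these, white noise at
signal-to-noise 30 plants spurious "bands" on the flanks of real ones and
classification degrades sharply; with them, weak-but-real features
(≥ 0.15 of the strongest band) are retained.

## Band libraries and assignment

A band library is a versioned plain-text table: code (structural-unit
notation), nominal center, search window, indicated colloid types, shoulder
expectation, specificity and an evidence weight. The carrageenan library
covers S=O (ester sulfate), DA and DA* (3,6-anhydrogalactose), G/D
(galactose backbone), DA2S and DA2S* (ι-exclusive 2-sulfate on the
anhydro ring), G4S, and the ν bands G/D2S, G/D6S and shouldered G/D6S*.
Windows are set to cover the positions observed on commercial standards
and monthly extracts (these wander several cm⁻¹ around literature centers,
e.g. S=O prints at 1218–1225 against a nominal 1240).

Assignment: each detected peak may satisfy at most one band — the
containing band with the nearest center, ties toward lower wavenumber.
Shoulder-expected bands prefer shoulder detections when both are in-window.
A matched band whose height falls below 8% of the tallest matched band is
downgraded to "present at low intensity" (the `+` cell of published band
tables); bands with no in-window peak are absent (`-`). The 8% cut is a
declared threshold — the table convention itself publishes none.

## Carrageenan typing

Scores per type, with present-low evidence at half weight:

- ι = evidence on the ι-exclusive bands DA2S (≈805) and DA2S* (≈905 cm⁻¹);
- ν = evidence on G/D2S (825–830) and G/D6S (815–820), plus the shouldered
  867–874 cm⁻¹ feature at **half** weight — that band also prints on ι and
  κ standards (any sulfate contributes there), so it is deliberately weak
  evidence;
- κ = the shared ι/κ anhydro-bridge bands (DA ≈930, DA* ≈1070 cm⁻¹),
  counted only when no ι-exclusive evidence exists. Chemically κ
  (G4S–DA) *is* the bridge without the 2-sulfate: it has no exclusive
  mid-IR band of its own, and treating bridge-without-2-sulfate as κ is
  what lets a κ standard row classify as κ rather than tie with ι.

Dominant = the strictly best score; "mixture" when ≥2 types score ≥1
(i.e. at least one full-weight specific band each); "undetermined" when no
type-specific band is seen. The 867 cm⁻¹ half-weight choice means that
feature alone can never produce a ν or mixture call — a deliberate
resolution of its acknowledged ambiguity. Family is "carrageenan" when the
ester-sulfate band and a backbone band (G/D or G4S) are both matched.
λ-carrageenan is representable in a library but no typing rule ships for
it (no λ standard row exists to anchor one).

Colloid family identification compares the hit fraction of each library's
markers, with a +1 shrinkage on the library size (hits/(n+1)) so a 3-band
marker set cannot outvote a 10-band library on one coincidental hit; ties
are undetermined.

## Similarity

percent = 100 × max(0, r), r the Pearson correlation of the two traces
after identical conditioning on a common grid. Scale- and offset-invariant
(SNV), symmetric, 100 for self-comparison, and monotonically degraded by
additive noise in expectation. This is an open analog of commercial
"match" percentages — those metrics are proprietary and no numerical
equality with them is claimed. Window, grid size and preprocessing are
recorded in the result.

## PCA and seasonal grouping

Mean-centered PCA (no per-wavenumber scaling — the spectroscopy
convention) via full SVD; component signs are canonicalized so the
largest-|loading| element is positive, making results independent of
sample order and backend. Group separation is the mean silhouette on the
first one or two score dimensions; singleton groups get silhouette 0 and
are flagged. Published seasonal claims of this kind are argued from score
plots; the silhouette makes them one testable scalar.

## Synthetic generator

Bands are pseudo-Voigt (η = 0.3 Lorentzian fraction; FWHM 12 cm⁻¹ for
sharp bands, 14 for shouldered ones, 16–40 for broad envelopes), with
three relative height tiers (1.0/0.5/0.25) so the matched-vs-`+`
distinction is meaningful. Component band sets: ι and κ at the positions
printed for commercial standards; ν with its C6-sulfate bands; fucoidan
and alginate at their marker positions; a protein amide I/II background
near 1645/1555 cm⁻¹. A spectrum is the weighted component sum plus a
random smooth quadratic drift and white Gaussian noise.

Seasonal designs ship as code: `solieria_2014` (12 months × 3 replicates;
Sep–Dec pure ι as the mature phase, Jan–Aug ι + 0.3 ν-precursor + amide as
growth/transition) and `sargassum_2015` (Feb/Apr/Jun/Oct × 3 replicates,
alginate/fucoidan balance shifting by season). Within-month dispersions —
jitter sd 0.5 cm⁻¹, height CV 5%, noise sd 0.005 AU, drift 0.02 AU — are
declared, realistic-looking defaults, not estimates from data; the
between-block composition shifts are several times those dispersions.
Seeding uses one master seed with per-spectrum `SeedSequence` spawn keys
of (year, month, replicate), so extending a design never perturbs
existing months.

What passing tests on this generator show: the detection/assignment/
classification/chemometrics chain is correct and robust at the stated
noise levels for band-shaped signals at the documented positions. What
they do not show: performance on real extracts, whose band widths,
overlapping sugar envelopes (e.g. the intense 1022–1070 cm⁻¹ region),
water/protein interferences and hybrid-carrageenan chemistry are richer
than the model; the 1022 cm⁻¹ envelope in particular is not simulated,
which is why the DA* shoulder appears as a small isolated apex in
synthetic spectra.

## Numerical choices and degenerate inputs

Closed-interval cropping; strictly ascending storage with descending files
reversed on read; linear-interpolation regridding with extrapolation
refused; round trips through CSV/JCAMP-DX preserve values to 1e-9;
constant traces are rejected for SNV and similarity (degenerate); ties in
band matching break toward lower wavenumber; classification ties return
"undetermined" rather than guessing. Problem sizes in the test suite
(e.g. 200 draws for classifier recovery, 50 draws per noise level, full
36-spectrum seasonal designs) were chosen to make the statistical
assertions stable at fixed seeds.

## Known limitations

- The similarity metric is an analog of vendor match scores; absolute
  percentages are not comparable to instrument-software output.
- κ typing is inferential (bridge without 2-sulfate), so a genuinely mixed
  ι+κ sample reads as ι — resolving that requires NMR, not mid-IR.
- No ATR penetration-depth correction, water-vapor/CO₂ compensation or
  proprietary binary formats (OMNIC/SPC); export absorbance as CSV or
  JCAMP-DX first.
- PCA explained-variance percentages on real data depend on preprocessing
  choices the source workflows leave unstated; the shipped defaults are
  documented above rather than inferred.
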