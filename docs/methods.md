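# Methods

This note records the models, conventions, numerical choices and known
limitations behind `jetcurve`, in the order the pipeline runs.

## Jet-axis detection

**Model.** The westerly jet axis at one time step is a single-valued
polyline y(x): one latitude per longitude column, restricted to the
Northern Hemisphere (0–90°N). Detection assumes one dominant westerly
maximum per column; split jets are out of scope.

**Morphological filtering.** The daily zonal-wind field is filtered by
grayscale closing (dilation then erosion) followed by grayscale opening
(erosion then dilation), in that order. Closing fills narrow low-wind gaps
inside the westerly channel; opening removes isolated high-wind patches
smaller than the structuring element. Both operators are rank filters: they
preserve edges and geometric structure rather than blurring them, which is
why they are preferred over convolution here. Longitude is treated as
periodic (wrap padding); latitude edges use edge replication. Padding is
twice the element half-span so both passes of each compound operator see
correct neighbourhoods.

The default structuring element is a 5×5-cell rectangle. There is no
uniquely correct choice; 5×5 is small enough to preserve synoptic-scale
structure and large enough to remove the few-cell spurious patches the
generator emits. Shape (`rectangle`/`disk`) and span are configurable, and
the element must not exceed the domain.

**Extraction and ties.** The axis is the latitude of maximum filtered wind
per column. Because rank filters output repeated values, the maximum is
typically an *exactly flat plateau* several cells wide. Two tie rules are
provided:

- `midpoint` (default): the centre of the contiguous tied plateau
  containing the argmax. This is the unbiased reading of "latitude of
  maximum" for a plateau. Taking instead the first tied index biases the
  axis equatorward by roughly half the plateau width (~2 cells for a 5×5
  element), an error that does not average out over time.
- `continuity`: the tied latitude nearest the previous column's choice
  (the westernmost column starts at 45°N). This keeps the axis continuous
  across plateaus but tends to stick to plateau *edges*, which we measured
  to lag the true meander systematically; it is retained as an option, not
  the default.

A column in which more than half of the latitudes tie with the maximum
(e.g. a constant column) has no distinct jet and raises an error for that
time step.

**Smoothing.** The extracted axis is smoothed with a longitude-periodic
running mean over ~1000 km before any curvature is computed, suppressing
mesoscale wiggles. Kilometres convert to grid columns at the 45°N reference
latitude (the mid-latitude of the jet belt), giving a single deterministic
window for all longitudes: w = nearest odd integer to
1000 km / (111.32 · cos 45° · Δx) — 51 columns at 0.25°, 13 at 1°. Windows
wider than 180° of longitude are rejected.

**Daily-then-average.** Seasonal products are built by detecting the axis
in each daily field and averaging the resulting daily axes (and daily
curvature), not by filtering a seasonal-mean wind field. Averaging after
detection is what suppresses the considerable cell-level noise in daily
fields: with spatially white noise at a peak-to-noise ratio of 5, a single
daily detection places ~95% of longitudes within one grid cell of the true
axis, while a 92-day season mean places essentially all of them (this is
the axis-recovery check in the test suite and acceptance script). Users
working with single snapshots should expect the former accuracy, not the
latter.

## Curvature metrics

For the smoothed axis y(x), both coordinates in degrees, the signed
curvature at each longitude is

    κ(x) = − y″ / (1 + y′²)^{3/2}        [degree⁻¹]

with y′ and y″ by central differences over one grid step, wrapping at the
longitude endpoints. The leading minus sign is the package's
*ridge-positive* convention: a northward crest (y″ < 0) has κ > 0, a
southward trough κ < 0. The raw differential-geometry sign (crest
negative) is available with `convention="raw"`; every default output uses
ridge-positive.

Coordinates are treated as planar longitude–latitude degrees with no
cos-latitude metric scaling — κ describes the polyline in the x–y plane of
a cylindrical-equidistant map, not a great-circle curvature. This keeps the
metric simple, zonally equivariant, and comparable across latitudes; it
understates physical (great-circle) bending at high latitudes.

Curvature is computed on the smoothed axis only; κ itself is never
re-smoothed. Derived metrics:

- |κ|: bending magnitude regardless of direction. Seasonal means of κ and
  of |κ| are kept distinct because they answer different questions: a
  sector whose mean κ trend is positive while its |κ| stays flat has
  *reversed direction* (trough → ridge) without bending harder.
- overall curvature √(Σκᵢ²/N) over all longitudes: a hemispheric waviness
  scalar, reported with anomalies relative to a configurable base period
  (default: the full record).
- sector means over a scheme of half-open [west, east) intervals on the
  [0, 360) circle. The default eight sectors are WE 35°W–16.5°E,
  EE 16.5°E–47°E, CA 47°E–80.25°E, EA 80.25°E–120.5°E, PA 120.5°E–141.75°W,
  WN 141.75°W–106.75°W, CN 106.75°W–71.75°W, EN 71.75°W–35°W; schemes must
  tile the circle without overlap.

Seasonal (JJA) means average the 92 daily values of June–August per year;
years with under 80% coverage are flagged missing.

**Numerical behaviour.** Against the closed-form curvature of a harmonic
axis (amplitude 5°, wavelength 60°), the central-difference κ agrees to
0.006% of the peak at 0.25° spacing, and the error decreases monotonically
with grid refinement. A zonal axis gives κ = 0 to machine precision. Units
are degree⁻¹ throughout (the RMS of a degree⁻¹ quantity is degree⁻¹).

## Statistical layer

Trends are ordinary least squares against time with a two-sided t test and
95% confidence interval. By default no autocorrelation correction is
applied; a flag replaces n with the AR(1) effective sample size
n(1−r₁)/(1+r₁), inflating the standard error and reducing the degrees of
freedom. A constant series returns slope 0 with an undefined p, flagged
degenerate. Under Gaussian nulls the test rejects at 5.0% and the CI covers
a known slope at 95.0% (both verified to ±1% at 10⁴ replicates).

Correlation and regression maps compute per-cell Pearson r (or the OLS
coefficient on the — by default z-scored — index) with per-cell t
significance at 95%. Cells with missing values use pairwise-complete
observations; detrending (both the index and each cell, on the cell's own
mask) removes co-trending as a spurious source of correlation and costs
one degree of freedom. No multiple-testing adjustment is applied by
default, matching per-cell masking practice for such maps;
Benjamini–Hochberg FDR is available by flag.

Land-use stratification classes a cell as *managed* when its
cropland+urban fraction exceeds its primary+secondary-forest fraction
(simple majority — fraction data give no principled threshold, so the
simplest rule is the default), *natural* in the opposite case, and compares
per-class mean |r| with a Welch t test.

Binned response curves use equal-width bins over the driver range and fit
the continuous hinge model a + b₁x + b₂·max(x−c, 0) by least squares, with
the breakpoint c searched over interior bin edges (boundary edges would
make a segment degenerate). The breakpoint counts as identified only when
the hinge improves on a single line by a partial F test at 95%; otherwise
both slopes collapse to the single-line slope and the breakpoint is NaN.

## Forcing attribution

The contribution of forcing F to a change C in an index is
ΔC_F = (C_ALL − C_XF)/C_ALL × 100%, where X⟨F⟩ denotes the ensemble with
forcing F fixed at its baseline level. C defaults to the ensemble-mean OLS
slope over the analysis period multiplied by the period's span in years;
an epoch-difference mode (late minus early epoch means) is provided for
sensitivity, and the two agree exactly for a linear series when the epochs
are the endpoint years. Attribution is undefined (error) when |C_ALL| ≤
10⁻¹² in index units.

Percentages are reported signed and unclamped: contributions below 0% or
above 100% are meaningful (offsetting forcings, nonlinear interactions)
and must not be hidden by clipping.

Confidence intervals bootstrap the *members* — the only sampling unit that
carries uncertainty — with replacement within each scenario (default 2000
resamples, seeded), taking percentiles 2.5/97.5 of the recomputed
contributions. CIs are reproducible under a fixed seed and widen
monotonically with internal variability.

## Synthetic generators

The generators define the conditions under which the pipeline is verified;
their defaults are fixed once and shared by the tests and the acceptance
script.

**Wind.** u(x, φ, t) = P·exp(−(φ−y₀(x,t))²/2σ²) + ε + patches, with peak
P = 40 m s⁻¹ and Gaussian width σ = 5° latitude (a broad summer-jet
profile), the axis y₀ a sum of integer-wavenumber harmonics (guaranteeing
zonal periodicity) kept inside 5–85°N, ε i.i.d. Gaussian per cell (white
noise — the simplest null that still stresses detection; verification runs
use sd 8 m s⁻¹, i.e. peak-to-noise 5), and spurious square patches of 2–3
cells a side at Poisson-random off-axis locations (≥3σ from the axis) with
speeds above the jet peak — shaped to be removable by a 5×5 opening. The
true axis is always emitted alongside the data.

**Productivity.** A chosen fraction of grid cells responds linearly to a
curvature index (optionally flattened above a plateau threshold); the rest
are pure noise. Default coefficient 1 and noise sd 1 in index/productivity
units give per-cell correlations near 0.7 for a unit-variance index — high
power at a 37-year record length without being trivial. The coupled-cell
mask is returned for recovery tests.

**Ensembles.** Each member is a prescribed forced trajectory plus
independent N(0, internal_sd) noise per member and year; the all-forcing
response is by construction the sum of the three single-forcing responses,
and each fixed-forcing scenario omits exactly one response. Member counts
default to 40/20/20/15 (ALL/XGHG/XAER/XBMB). Additivity is the generator's
defining assumption — it makes the differencing estimator exact in the
ensemble-mean limit, so recovery tests measure only sampling noise, not
model error.

**What the generators do not emulate.** Real dynamics (no geostrophy, no
spatially correlated turbulence spectra), split or merged jets, missing
data inside the detection band, non-Gaussian productivity noise, or
nonlinear forcing interactions. Passing tests therefore demonstrate
correctness of the *operators* under controlled conditions, not skill on
any particular reanalysis product.

## Verification problem sizes

The test suite and `scripts/acceptance.py` use: 1° grids with 92-day
seasons and 10–20 seeds for axis recovery; 10⁴ replicates of 45-year
series for calibration and coverage; 100–200 Monte-Carlo worlds of
80-year ensembles (2000 bootstrap resamples each) for attribution;
60×80-cell fields over 37 years for coupling maps; 6000 paired samples in
18 bins for breakpoint recovery. These sizes make every Monte-Carlo
tolerance comfortably larger than its sampling error while keeping a full
run to a few minutes on one CPU.

## Known limitations

- Single-valued axis: double-jet situations collapse to whichever branch
  is stronger after filtering.
- Planar curvature understates great-circle bending at high latitudes.
- The AR(1) correction is a first-order account of serial dependence only.
- Map significance is per-cell; field significance under spatial
  autocorrelation is out of scope (FDR flag available).
- The 1000 km → columns conversion uses 45°N for all longitudes; at the
  extremes of the jet's latitude range the physical window differs.
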