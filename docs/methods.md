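# Methods

## Design space and coding

Five geometric factors define a stent: strut width w [µm], strut
thickness t [µm], number of struts NS [count], link amplitude LA [mm] and
strut amplitude SA [mm].  The first design space spans w, t ∈ [100, 250] µm,
NS ∈ [16, 32], LA ∈ [0, 0.8] mm, SA ∈ [0.5, 2.0] mm; the refined
three-factor space spans w, t ∈ [50, 150] µm and SA ∈ [0.3, 0.7] mm with
NS = 16 and LA = 0.4 mm frozen.  Every factor grid is symmetric about its
mid value, so coding `c = (x − mid)/(upper − mid)` is a bijection onto
[−1, 1]^k; asymmetric spaces are rejected rather than silently
generalized, because nothing in the package is exercised against them.
Internal units are fixed as printed above; conversions (e.g. µm → mm for
geometry radii) happen only at I/O boundaries so that fitted coefficients
remain directly comparable.

NS is treated as continuous during model fitting and optimization — the
response surfaces are polynomials and the optima sit on grid levels — and
validated as a positive even integer only when geometry is generated,
where sine peaks must pair around the circumference.

## Parametric geometry

The stent is drawn on a flat sheet of width π·D (D = 8 mm) as seven
sine-wave rings, z(u) = SA·sin(2π·(NS/2)·u/(πD) + φ), joined by six sets
of sine-wave links, then wrapped to a cylinder.  Conventions the source
drawing leaves open, fixed here and isolated in single functions:

* SA is the standard sine amplitude (peak-to-peak extent 2·SA).
* Adjacent rings alternate phase by π; the axial gap between facing peak
  tips equals the link length LL = π/2 mm, making the ring pitch
  2·SA + LL independent of LA and the closed-form stent length
  (R−1)·(2·SA + LL) + 2·SA strictly increasing in SA.
* Links connect every other facing peak pair (NS/4 links per junction for
  NS divisible by 4), with the selection phase alternating between
  junctions so no stiff axial spine forms.  A link is a half-wave sine
  excursion of amplitude LA in u over the axial span LL; LA = 0 gives a
  straight axial strut.
* Wrapping uses the angle θ = u/(D/2), which closes the seam exactly, and
  places the centerline at the mid-wall radius D/2 − t/2.  Consequently
  circumferential arc components scale by (D − t)/D (≈ 2 % at
  t = 175 µm); the tests assert this exact factor rather than pretending
  lengths are preserved.  The cross-section w × t is carried as metadata
  only — downstream metrics need centerlines, not solids.

Metal coverage is computed as (total centerline arc length × w)/(π·D·L),
a first-order footprint ratio that is linear in w by construction.

## DOE generation and the packaged tables

`generate_ccd` produces the face-centered central composite design (α = 1):
full 2^k factorial core in binary order, 2k face-centered axial points in
factor order, one center point — 43 runs at k = 5 and 15 at k = 3,
matching the studies.  Simulation outputs are deterministic, so no
replicate center points are generated.  Coded factor columns of this
layout are exactly orthogonal, which the Pearson-correlation check
(`factor_orthogonality`) asserts; constant columns yield NaN with a
warning instead of a silent zero.

The two response matrices are shipped as plain CSV and validated on load:
factor values must sit on the declared levels, and each response row must
be physically possible (stress ≥ 0, percentages in [0, 100],
pinching ≥ 1).  The 43-run table contains two near-duplicate rows at
center-like settings differing only in LA (runs 17 and 29); both are kept
as printed.

## Response-surface fitting and screening

Fits are ordinary least squares (statsmodels OLS) on explicitly built
term columns.  The full quadratic model has 1 + 2k + k(k−1)/2 terms
(21 at k = 5, 10 at k = 3).  Two unit systems are exposed: natural-unit
fits give coefficients in printed units; coded-unit fits are numerically
well conditioned.  Their predictions agree to rounding error.

Screening is a single pass over the full-model t-values at the two-tailed
α = 0.05 threshold, followed by one refit — no stepwise search.  Two
choices matter and are deliberate:

* **Screening runs on the coded-unit fit.**  In a face-centered CCD the
  natural-unit full model is nearly collinear (x and x² over a narrow
  positive range), which corrupts linear-term t-values; coded columns are
  orthogonal between linear and interaction groups, so coded t-values
  isolate effects the way DOE practice expects.  The reduced model is
  then refitted in natural units.
* **t_crit is computed from the residual df** (t(0.975, 22) ≈ 2.074 for
  the 43-run full model); a fixed published constant such as 2.04 can be
  passed instead for compatibility.  Weak heredity is enforced: a
  factor's linear term is retained whenever a retained higher-order term
  contains it.

Two screening modes are available.  Per-response screening
(`reduce_model`) keeps each response's own significant terms.  Union
screening (`screen_union`) pools the significant terms across all four
responses into one shared reduced model; applied to the packaged 43-run
table this reproduces exactly the ten-term set
{w, t, NS, SA, w², SA², w·NS, w·SA, t·SA, NS·SA} — the reduced equation
the five-factor study reports, with every LA term dropped.  That preset
is available as `eq5_terms()` and is the default for first-DOE analyses;
the three-factor table has no published term set, so per-response
screening is used there.

Residual diagnostics (Shapiro–Wilk normality; Levene homogeneity with
residuals grouped by each factor's levels, the smallest-p factor
headlined) are reported but never auto-reject a fit.

## Desirability optimization

Predicted responses map to desirabilities by piecewise-linear ramps:
larger-the-better for apposition, smaller-the-better for mean stress,
high-stress area and pinching.  The ramp anchors default to the min/max
of each model's predictions over the optimization grid — self-contained
and scale-free; observed-table ranges or explicit targets are
alternatives.  The composite is the plain product (all weights equal, as
in the study; unequal weights switch to a weighted geometric mean).

Maximization runs on a dense coded grid (default 21 points per axis, ~4.1M
cells at k = 5, vectorized) followed by a bounded Powell polish from the
best cell.  Ties resolve to the first grid index; axes along which D is
constant (to 1e−12) are detected and listed in the result trace, because
a coordinate on a flat axis is arbitrary — for the first-DOE models this
applies to LA, whose terms do not appear in the reduced model, so the
study's reported LA = 0.8 mm cannot be recovered (or contradicted) from
the response surfaces.  NS is rounded to the nearest even integer in the
reported design and D re-evaluated there.  The second DOE's published
optimum additionally honored an FEA-derived crimpability (no-buckling)
constraint that cannot be evaluated desk-side; it can only be imitated by
a user-supplied box restriction.

Sensitivity contributions follow the midpoint convention: analytic
∂y/∂x_i at the all-mid design, multiplied by the factor range,
absolute-valued, and normalized to 100 % per response.  A
finite-difference oracle guards the analytic gradient in the tests.

## Fatigue screening

A strain cloud is the per-element set of (mean strain, strain amplitude)
pairs in percent.  The summary reports the fraction inside the
conservative envelope (mean < 2 % AND amplitude < 0.4 %) and the
fractions above 1 % and 2 % amplitude; all comparisons are strict, so a
point exactly at 0.4 % does not meet "under 0.4 %".  Thresholds are
configurable (e.g. a generation-III envelope at 2 %).  The printed
fatigue fractions of the original study derive from FEA strain fields
that are not reproducible here; this module is exercised on constructed
and synthetic clouds only.

## The FEA surrogate

`simulate_responses` evaluates configurable ground-truth polynomials per
response and adds Gaussian noise, then clamps to the physical range
(high-stress area and apposition to [0, 100], pinching to ≥ 1,
stress to ≥ 0), tagging clamped rows in the output — a clamped value no
longer lies on the truth polynomial, which matters for recovery checks.
The default truth is the reduced-model refit of the packaged 43-run
table, so the surrogate emulates the study's own surfaces; its noise SDs
(0.8 kPa, 0.25 %, 1.5 %, 0.02) were fixed once so that refitting a 43-run
CCD lands in the R² band the study reports (0.95–0.999).  All entry
points are seeded; there is no unseeded randomness anywhere in the
package.

`simulate_strain_cloud` emulates the qualitative shape of post-flexion
fatigue exports: a bulk with lognormal mean strain (median 0.5 %,
σ_log = 0.5) and amplitudes strictly below 0.4 % (0.4 × Beta(2, 4)), plus
a Bernoulli tail (default fraction 0.003) with amplitudes 1 + Exp(0.4) %.
It reproduces exceedance *rates* by construction, not FEA strain physics.

## What the synthetic data does and does not show

Passing tests on surrogate data demonstrate that the statistical pipeline
is correct: exact recovery of noiseless quadratics, calibrated ±3·SE
coverage under noise, corner-seeking desirability optima on monotone
truths.  They do not validate the FEA itself, the realism of the response
surfaces outside the sampled box, or any clinical claim.  The packaged
tables anchor the pipeline to the real study outputs; the second DOE's
apposition response is only weakly explained by a quadratic in
(w, t, SA) (reduced R² ≈ 0.54), so its predictions carry wider
uncertainty than the first DOE's.

## Problem sizes and numerical choices

Default problem sizes: 43- and 15-run packaged tables, 21-point
optimization grids (41 used in a resolution cross-check), 200 replicates
for coverage calibration, 10⁵–2×10⁵ elements per synthetic strain cloud.
Tolerances: coding round-trip 1e−12, OLS-vs-normal-equations 1e−8,
noiseless recovery 1e−6, seam closure and radius constancy 1e−9,
desirability product identity 1e−12.  Degenerate inputs fail loudly:
empty clouds, rank-deficient design matrices (named collinear terms),
zero residual variance at screening, all-zero sensitivity derivatives,
everywhere-zero composite desirability (with the collapsing response
named).

## Known limitations

* Geometry is centerline-only; no solid model, mesh or contact surface,
  and the every-other-peak link phasing is one consistent reading of the
  source drawing.
* The screening procedure is single-pass; aggressive dfs (15-run table,
  10-term full model, df = 5) make it conservative, and reduced-model
  predictions at the refined optimum differ from the published values by
  up to ~0.7 kPa in mean stress — consistent with the published
  predictions having been evaluated at an unrounded optimizer point.
* Crimpability/buckling, plaque, angioplasty and all FEA physics are out
  of scope by design.
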