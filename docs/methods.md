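# Methods

This note documents the models implemented in `arcoptics`, their assumptions,
the defaults and units, and the numerical and design choices made where the
procedure left room for judgement. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Absorption coefficients

**Filterpad absorption.** Particulate absorption is derived from filterpad
optical density by the quantitative filter technique:

    a_p(λ) [m⁻¹] = −ln T(λ) · A · β / V,   T(λ) = exp(−OD(λ))

with A the filter clearance area (m²), V the filtered volume (m³) and
β = 1/4.5 the reciprocal path-length amplification factor appropriate for
filters measured inside an integrating sphere. The multiplicative placement
of A·β/V follows from dimensional analysis (OD is dimensionless; a_p carries
m⁻¹ = m²/m³), and β acts as a pure multiplier — halving β halves a_p.
Bleached filters yield non-algal particle absorption a_NAP; phytoplankton
absorption is the pointwise difference a_ph = a_p − a_NAP on the common
wavelength grid. Negative a_ph values, which arise from over-bleaching, are
retained and flagged (warning below −0.001 m⁻¹), never clipped, so the
artifact remains auditable downstream.

**OD convention.** The transmittance relation is implemented as natural-log
OD, T = exp(−OD), exactly as defined. Because bench spectrophotometers
usually report decadic OD, `transmittance_from_od(..., decadic=True)`
computes T = 10^(−OD) instead; the choice is the caller's, the default is the
as-defined form.

**CDOM.** Decadic absorbance A(λ) over 260–600 nm converts to the Napierian
absorption coefficient with a 600 nm baseline, under the assumption that CDOM
absorption is negligible at 600 nm:

    a_CDOM(λ) [m⁻¹] = 2.303 · (A(λ) − A(600)) / L

with L the cuvette path length in metres. a_CDOM(600) is exactly zero and the
correction is idempotent. Reference bands are exposed as constants: 443 nm
(the visible band used in all station-level analyses; occasional "440 nm"
naming in the field is resolved to 443 nm, the band actually used) and 350 nm
(the UV band used for DOC/lignin comparisons). No spectral-slope fitting is
performed — the analysis only consumes band values and full spectra.

**Budget.** a_tw = a_ph + a_NAP + a_CDOM on the intersection grid; fractional
contributions at any band sum to one and are undefined (an error) when
a_tw = 0. Grid intersection interpolates the coarser spectrum linearly onto
the finer grid inside the overlap; disjoint grids are an error, and no
spectrum is ever extrapolated beyond its measured range.

**Power-law couplings.** Bio-optical parameters are treated as log-normally
distributed, so pairwise relations are fitted as y = a·x^b by OLS in
log₁₀–log₁₀ space; r² is reported from the log-log fit. The regional pigment
law used by the synthetic generator is a_ph(443) = 0.0513·Chl^0.6675 (total
particulate: a_p(443) = 0.0595·Chl^0.5603).

## Radiometry

Raw records are quality-controlled on sensor inclination (records at or above
14° in either axis are excluded — the threshold is strict) and averaged into
depth bins of 5 m over 0–30 m and 10 m below. The reported bin centre is the
mean depth of the surviving records in the bin, which makes binning exact for
profiles sampled at discrete stops and keeps noise-free exponential profiles
regression-identical before and after binning.

Attenuation coefficients come from OLS of ln E_d (and ln L_u) on depth over a
fixed window, by default z′ = 10–30 m, which avoids the wave-affected upper
metres: K_d = −slope, with at least 3 usable bins per wavelength (fewer marks
that wavelength missing; all wavelengths missing is an error). Non-positive
binned values are set missing before the log regression and counted.
Subsurface values E_d⁻(λ, 0) and L_u⁻(λ, 0) are the regression value at
z = 0, i.e. exp(intercept) — this uses every point of the window and is
consistent with the regression-based K_d rather than propagating a single bin
upward. K_u is computed identically on L_u; the two are treated symmetrically
throughout.

Remote-sensing reflectance uses the flat water–air transfer coefficient:

    R_rs(λ) [sr⁻¹] = 0.519 · L_u⁻(λ, 0) / E_d⁻(λ, 0)

applied exactly as defined, with no separate internal-reflection term.
Wavelengths with non-positive E_d⁻(0) are dropped (a per-wavelength failure);
negative R_rs values are flagged, not removed. Inputs are assumed to be
calibrated radiometric quantities (integration-time normalization and
immersion/dark corrections applied upstream by the instrument chain).

## Ocean-color algorithms

**Empirical.** Chl-a = 10^P(R), where R is log₁₀ of the maximum blue/green
band ratio and P a polynomial:

| name      | scheme                    | coefficients (constant first)          |
|-----------|---------------------------|----------------------------------------|
| OC3M      | max(443, 488)/551         | 0.2830, −2.753, 1.457, 0.659, −1.403  |
| OC4V6     | max(443, 490, 510)/555    | 0.366, −3.067, 1.930, 0.649, −1.532   |
| OC4L      | max(443, 490, 510)/555    | 0.592, −3.607 (linear)                |
| OC3M-mod  | max(443, 488)/551         | −0.32, −2.33, 4.02, −31.64, 48.54     |
| OC4V6-mod | max(443, 490, 510)/555    | −0.35, −1.52, −2.44, −12.80, 30.48    |

Band values are extracted from hyperspectral R_rs by linear interpolation
(including the 488/551 pair) — at ~3 nm instrument resolution interpolation
is accurate and nearest-neighbour snapping would be coarser. Non-positive
numerator bands are excluded from the maximum; a non-positive denominator is
an error. Retrievals are capped at 1000 mg m⁻³ with a warning (overflow
guard: the retuned quartics grow explosively outside the ratio range they
were fitted on; the global quartics are monotone decreasing over
R ∈ [−0.4, 1], the retuned ones are not). The turbidity screen flags
R_rs(676) > 0.00042 sr⁻¹, strictly.

**Semi-analytical (GIOP-class).** The forward operator composes

    a(λ)   = a_w(λ) + a_ph(443)·φ(λ) + a_dg(443)·exp(−S_dg (λ − 443))
    b_b(λ) = b_bw(λ) + b_bp(555)·(555/λ)^η
    u      = b_b / (a + b_b)
    r_rs   = g₁·u + g₂·u²          (subsurface)
    R_rs   = 0.52·r_rs / (1 − 1.7·r_rs)   (above surface)

with defaults S_dg = 0.018 nm⁻¹, η = 1, g₁ = 0.0949, g₂ = 0.0794 — the
standard settings of this model family; all are configuration, since regional
deployments retune them. φ(λ) is a Bricaud-class normalized phytoplankton
absorption shape with φ(443) = 1 (blue maximum, green minimum, secondary red
peak near 675 nm), stored as an interpolation table. Pure-water absorption is
a standard laboratory table at 10 nm resolution (interpolated) and pure-water
backscatter uses b_bw = 0.0038·(400/λ)^4.32. The inversion is bounded
(non-negative) nonlinear least squares (trust-region reflective) on the
operational bands, initial guess (0.01, 0.1, 0.001), parameter/function
tolerance 1e−8, at most 500 function evaluations, needing ≥ 4 valid bands;
non-convergence is reported in the `converged` flag rather than raised.
Chl-a = a_ph(443)/0.055.

Note the asymmetry, kept deliberately: measured-data R_rs is derived with the
flat 0.519 transfer (above), while the forward model lifts r_rs with the
0.52/(1 − 1.7·r_rs) transform; the inversion consumes whichever R_rs it is
given. At Arctic reflectance levels the difference is sub-percent.

**NAP/CDOM partition.** a_NAP(443) = min(k_NAP·b_bp(555), a_dg(443)),
a_CDOM(443) the remainder, so the partition conserves a_dg exactly. The
regional coefficient k_NAP is required configuration with default 0 (pure
pass-through, all of a_dg attributed to CDOM): the western-Arctic value is
cited in the literature but not printed in the sources this package works
from, and a silently invented default would be worse than an explicit one.

## Evaluation statistics

For retrieved Y versus measured X (pairs with missing or non-positive values
excluded and counted; n is the post-exclusion count):

    RMSE = sqrt( mean( (log₁₀Y − log₁₀X)² ) )
    MAE  = mean( |Y − X| )
    BIAS = mean( Y − X )

r², slope and intercept come from OLS of log₁₀Y on log₁₀X. MAE and BIAS are
linear-space as defined; a documented `log_space=True` option computes them on
log₁₀ values instead, because published evaluation tables in this field
sometimes tabulate log-space values (the near-equality of MAE and BIAS in
such tables is the tell) — the ambiguity is surfaced as an option, not
silently resolved.

## Province clustering

The environmental matrix (temperature, salinity, a_CDOM(443), a_NAP(443),
a_ph(443); stations with gaps dropped and counted) is z-normalized per column
— sample SD, n−1 denominator, with a `population_sd` flag — and clustered by
UPGMA: unweighted average linkage on Euclidean distances, the standard
meaning of "average linkage" in this context. Dendrogram fidelity is the
cophenetic correlation. The cut count k is always an explicit analyst
parameter (the study-region analysis used k = 7, consolidated by the analyst
into five named provinces; that mapping ships as the constant
`PROVINCE_CONSOLIDATION = {1: LSS, 2: TPD, 3: BG, 4: EB, 5: TPD, 6: LS,
7: EB}`, never recomputed). Cutting uses the smallest height producing
exactly k groups; an unreachable k is an error. Between-cluster comparisons
of single variables are exposed as a thin Kruskal–Wallis wrapper.

**Derivative spectroscopy.** Each R_rs spectrum is normalized by R_rs(555),
interpolated to a 1 nm grid over 435–510 nm, smoothed with a centred boxcar
of 27 nm, and differenced with a central second-difference stencil whose band
separation equals the smoothing window (27 nm), isolating curvature at the
scale of the blue-green absorption features. At the grid edges the boxcar
window shrinks symmetrically (half-width min(13, distance to edge)) rather
than truncating one-sidedly: a symmetric window passes constant and affine
signals through exactly, so the derivative of a constant or linear spectrum
is identically zero everywhere, at the cost of less smoothing near the edges.
The derivative is reported only where the full ±27 nm stencil fits, i.e. over
462–483 nm for the 435–510 nm window. For a pure quadratic the stencil
returns exactly twice the curvature wherever both smoothing and stencil are
fully interior (verified on a wide grid in the tests).

## Synthetic cruise generator

The generator emulates the statistical structure the analysis assumes, not
radiative-transfer physics:

- **Stations.** Seven clusters with fixed means, SDs and counts for the five
  environmental variables (62 stations in total; the defaults are the
  study-region values and are the generator's study conditions, scaled
  globally by `sd_scale`). Temperature and salinity are Gaussian; absorption
  anchors are truncated Gaussian (reject-and-resample below zero, since some
  prescribed SDs are large relative to their means).
- **Pigment.** Chl-a is derived from a_ph(443) by inverting the regional
  power law, chl = (a_ph(443)/0.0513)^(1/0.6675), rather than sampled
  independently. This reproduces the key structural fact of these waters:
  Chl-a covaries with phytoplankton absorption and not with CDOM (across
  default cruises the log-log r² between Chl and a_CDOM(443) is typically
  ~0.03, assessed in the tests as a median over cruises because single-cruise
  values fluctuate).
- **Spectra.** a_CDOM and a_NAP decay exponentially from their 443 nm anchors
  with slopes 0.018 and 0.011 nm⁻¹ (standard literature values, configurable;
  the source data contain no fitted slopes), a_ph follows the normalized
  basis shape, and b_bp(555) = 0.5·a_NAP(443) + 5×10⁻⁴ ties backscatter
  linearly to NAP so the NAP/CDOM partition has recoverable structure.
- **Reflectance.** R_rs comes from the same forward operator the inversion
  assumes, entered through the eigenvalues (a_ph(443), a_dg(443) =
  a_CDOM(443) + a_NAP(443), b_bp(555)) — generator and inverter share one
  operator, so the noise-free inversion round trip is exact by construction
  and tests isolate optimizer behaviour from model mismatch. The
  per-constituent spectra feed the absorption-budget side of the pipeline.
- **Profiles.** K_d(λ) = (a_total(λ) + b_b(λ))/μ with mean cosine μ = 0.75;
  E_d(λ, z) = E_d0·exp(−K_d z) with flat E_d0 = 1.2 W m⁻² nm⁻¹;
  L_u(λ, z) = R_rs(λ)·E_d(λ, z)/0.519 with K_u = K_d, so the radiometric
  processing chain reproduces the generating R_rs exactly in the noise-free
  case. Records are emitted at discrete depth stops (one stop per bin, three
  records per stop by default) so that depth-binning is exact for noise-free
  exponentials. Multiplicative lognormal noise and inclination jitter are
  injectable; all randomness flows from a single cruise-level seed.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: multiple scattering, Raman scattering and bidirectional
effects; sea-ice and melt-pond optics; wave focusing in the upper metres;
instrument self-shading; spectral shape diversity of real phytoplankton
assemblages (one fixed basis shape); departures of real CDOM/NAP spectra from
single exponentials; and measurement error structure beyond multiplicative
lognormal noise. Closure results on synthetic data bound implementation
error, not retrieval error in the field.

## Problem sizes and numerical choices

The test suite and acceptance checks run at desk scale by design: the
semi-analytical round trip uses a 5×5×5 grid over the observed parameter
ranges (a_ph(443) ∈ [0.005, 0.06], a_dg(443) ∈ [0.02, 1.14],
b_bp(555) ∈ [0.0005, 0.01] m⁻¹); statistical properties use 100 fixed seeds;
cruises are the full 62 stations; radiometric profiles use a 5 nm wavelength
step. Floating-point tolerances in tests reflect the arithmetic: exact
identities are asserted at 1e−10…1e−12, optimizer round trips at 0.1 %, and
stochastic properties at bounds derived from the regression standard errors
involved (e.g. the log-intercept SE of the surface extrapolation,
σ·sqrt(1/n + z̄²/S_xx) ≈ 0.067 at 5 % record noise with five bins, sets what
accuracy surface extrapolation can honestly promise).

## Known limitations

- Cluster recovery from synthetic cruises is limited by genuine overlap of
  the prescribed cluster distributions at their full SDs (two pairs of
  clusters overlap substantially); recovery is assessed both at half spread
  (where it is near-perfect) and at full spread (where agreement is
  substantial but not perfect — the generating labels are not fully
  identifiable, consistent with the provinces having been defined by
  clustering in the first place).
- The AOP top-split separation of high- from low-CDOM stations is fragile in
  the presence of extreme low-CDOM outliers (a_CDOM(443) ≲ 0.04 m⁻¹): the
  curvature response of normalized reflectance saturates at high CDOM and is
  steepest near zero, so a near-zero-CDOM station can peel off as a singleton
  under average linkage before the CDOM regimes separate.
- The retuned empirical quartics (OC3M-mod, OC4V6-mod) are non-monotone and
  explode outside the band-ratio range they were fitted on; the 1000 mg m⁻³
  cap is a guard, not a scientific statement.
- k_NAP for the NAP/CDOM partition must be supplied by the user for
  quantitatively meaningful partitions.
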