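# Methods

This note documents the models implemented in `drusensf`, the synthetic
data they are validated on, and the numerical and design choices made
where the problem left room.

## OCT quantification

All OCT computations run on untransformed (linear) intensities, indexed
`(b_scan, depth_row, a_scan)` with row 0 on the vitreous side.

**RPE initialization.** For each A-scan the profile above the BM row is
normalized by its maximum; the initial RPE estimate is the local maximum
with normalized value strictly above 0.4 that lies nearest to (and
above) the BM. A peak is a strict local maximum; a plateau contributes
its BM-nearest sample; array boundaries count when they exceed their
single neighbor. All-zero profiles, and profiles where no peak clears
the threshold, are flagged for interpolation.

**Refinement.** The cited segmentation algorithm the initialization was
designed to feed is not available, so refinement is a documented
slope-bounded smoothing: within each B-scan, columns flagged invalid or
deviating from a 5-column running median by more than `max_jump` rows
(default 10) are discarded and re-interpolated linearly from valid
neighbors; the path is capped at the BM. Smooth, valid input passes
through unchanged, which is what makes the noise-free round trip exact.

**Maps.** RPE-E = (BM − RPE) rows × axial scale (default 3.87 µm/px);
the raw row difference is recoverable by dividing the scale back out.
PRR uses cumulative sums to the image bottom (literally the last row,
including sub-BM signal) started 6 and 20 pixels above the RPE; "k
pixels above" means `rpe_row − k`, 0-based, both endpoints included.
The orientation PRR = S₂₀/S₆ (≥ 1 identically) is chosen because it is
the only one under which a dimmer photoreceptor band both drives the
ratio toward 1 and decreases it. A start row above the image top is
clamped to 0 with a warning; S₆ = 0 marks the location invalid.

## Macular pigment compensation

MPOD is the green/blue channel ratio (blue is the absorbed channel, so
absorption gives values above 1); pixels with a zero channel are
masked. The correction C_dB = 10·log₁₀(0.66·(MPOD−1)+1) is exactly 0 at
MPOD = 1, and the exposed `compute_cdb` clamps it to 0 below 1. For
compensation, disc means are taken on the *signed* map and only the
means are clamped — pixel noise around a ratio of 1 then averages out
instead of biasing the correction upward. The factor 0.66 is the
relative pigment absorption of the 505 nm stimulus versus the 488 nm
excitation. Whether the ratio map should be pre-smoothed before
averaging is left as an option (`smoothing_px`, default off).

## Co-localization

Microperimeter-to-SLO registration is a least-squares affine or
projective fit to landmark pairs (≥3 / ≥4, non-collinear); the landmark
residual RMS is reported on the transform. Tested locations travel as
grid-frame degrees → microperimeter pixels → (transform) → SLO pixels →
degrees, using 768 px / 30° for the SLO unless stated otherwise.
Structural values are unweighted means over pixels whose centers fall
within the 0.43° stimulus disc (≈5.5 px radius at SLO calibration);
area weighting at the disc boundary was considered and rejected as
unnecessary complexity at these radii. A sub-pixel disc falls back to
the containing pixel. Eccentricity is Euclidean distance from the grid
center — the preferred retinal locus, not the anatomic fovea, since the
grid follows fixation. Locations mapped outside the structural frame,
or without valid pixels, are dropped with a warning.

## Normative models and sensitivity loss

Model forms are fixed; coefficients are always estimated from healthy
data:

* mesopic, scotopic red: `sensitivity ~ eccentricity + age`,
* scotopic cyan: `sensitivity ~ ln(ecc) + ln(ecc)²`, no age term,

each with a per-eye random intercept, fitted by maximum likelihood (not
REML) so that downstream likelihood-ratio tests and AIC comparisons are
valid without refitting. Natural log is used for the cyan eccentricity;
no covariate centering is applied. Cyan inputs must already be
MP-compensated, which is why compensation sits upstream in the
pipeline. Predictions use fixed effects only; SL = observed − predicted.

## Structure–function models

Predictors are log₁₀-transformed with guards against zeros (1 µm for
RPE-E, 10⁻³ for PRR and AF; clamp events are counted and logged).
The fixed-effect R² is 1 − SS_res(fixed)/SS_tot, computed per test —
the only reading of a residual-over-variance ratio that is 1 for a
perfect fit and 0 at the mean. LRTs compare the full 8-term
interaction model against a reduced model dropping one predictor's main
effect and all its interactions (4 df, χ²). Backward AIC elimination
respects marginality (no main dropped while one of its interactions
remains) and stops at a local minimum; AIC = 2k − 2·logLik with k
counting fixed effects plus the two variance components. Coefficient
p-values use the Wald z approximation — mixed-model denominator degrees
of freedom are not well defined and the record counts here are large.
The abnormality threshold is the healthy-cohort 95th percentile of
per-location RPE-E (linear-interpolation convention, pooled across all
healthy locations), with strict `>` membership.

All mixed fits run through one helper that standardizes design columns
internally and maps estimates and covariance back exactly; this is a
pure reparametrization that stabilizes the optimizer on raw-scale
predictors such as log₁₀ AF (≈3 with small spread, nearly collinear
with the intercept). Records from a single eye cannot identify the
random intercept, and the fit degenerates to ordinary least squares
with zero intercept variance.

## Synthetic cohort generator

Defaults are the study conditions: 56 healthy and 43 drusen eyes, ages
uniform on 55–85 y, a 44-location polar grid (rings {1°:4, 3°:8, 5°:8,
7°:12, 9°:12}; the device's actual meridian layout is unpublished, so
this layout is a configurable stand-in totalling 44 within the ~10°
field; the central and optic-nerve locations are never generated),
Goldmann III discs, 36 dB mesopic and 20 dB scotopic dynamic ranges
with 2 dB and 1 dB final staircase steps, 768 px / 30° lateral and
3.87 µm axial scales.

**Structure.** Drusen eyes receive 3–10 Gaussian elevation bumps
(heights 25–120 µm, σ 0.25–0.7°) on a 2 µm RPE floor. PRR starts at
1.6 and loses 0.4 per unit normalized drusen load; green AF starts at
1000 a.u. and loses 30% at full load; the pigment ratio is a radial
Gaussian peaking at 2.0 with σ = 3°, ≈1 beyond 7°. Rendered volumes
place a BM row, an RPE row at `bm − round(elev/axial)`, and a uniform
photoreceptor band in the 14 rows between 20 and 7 px above the RPE
whose total encodes (PRR−1)·S₆ — invertible exactly on noise-free
renders. Rendered FAF pairs set green = AF + noise and blue =
AF/MPOD + noise. Misalignments are small random rotations (±2°), scales
(±2%), translations (±8 px) and, for projective frames, perspective
terms of order 10⁻⁵.

**Sensitivities.** True sensitivity = normative fixed effects (mesopic
32 − 0.45·ecc − 0.08·age; red 18 − 0.12·ecc − 0.05·age; cyan
8 + 3·ln(ecc) − 0.5·ln(ecc)², chosen to land in the devices' observed
healthy ranges) + a per-eye N(0, 1.5²) intercept + the
structure–function contribution + N(0, 1.2²) noise, then staircase
quantization and range clamping. For the cyan test the disc-mean C_dB
is subtracted before emission, so skipping the compensation step leaves
a detectable negative foveal bias — the ordering is falsifiable.

**Record-level generator.** The statistical validation studies
(coefficient recovery, LRT calibration, stepwise selection) run on
`simulate_location_records`, which draws per-location records directly
from this generating model without rendering images. Its structural
predictors are drawn with zero cross-correlation by default
(configurable couplings exist), consistent with the near-independent
predictors the analysis assumes and necessary for univariable slope
recovery to be well-posed. In the default scenario the
structure–function effect acts on the *reported* structural values, so
the fitted model matches the generating one exactly; healthy eyes
contribute no structural loss by definition (they define the normative
reference). In the drusen-localized scenario (`sf_localized=True`) the
elevation effect instead acts on the *true* elevation through a hinge
at 20 µm — healthy-range elevation carries no functional cost — which
deliberately misspecifies a single linear fit over all locations and
reproduces the abnormal-subset enrichment; a linear generating law
cannot produce that enrichment, because the between-group signal always
dominates the all-locations fit.

**What the generator does not emulate.** Speckle statistics, curved
retinal geometry, reticular pseudodrusen, trial-by-trial staircase
psychophysics (quantize-and-clamp of a noisy threshold reproduces the
floor/ceiling and lattice artifacts that matter downstream), fixation
instability, and media opacity. Passing tests therefore demonstrate
correctness of the measurement and modeling chain under the stated
generative assumptions, not performance on clinical images.

## Validation scale and known limitations

Recovery and calibration studies use 50 replicates at full cohort scale
(56/43 eyes × 44 locations), 200 smaller (20-eye) replicates for LRT
type-I calibration, and 10 replicates for the subset contrast; imaging
round trips run on coarsened maps (8 px/°) where the geometry, not the
resolution, is under test. Under the no-effect null both subset R²
values are near zero, so their ratio is ill-conditioned; the stable
contrast reported is the R² difference.

Backward AIC selection has an intrinsic per-term overfitting
probability — a spurious term survives when its χ²₁ deviance exceeds
the 2-point penalty, ~16% of the time — so even on perfectly specified
data the probability of recovering *exactly* the generating term set
from a full three-way start is capped near
0.84³ ≈ 0.6, and measured at 0.48–0.56 here (staircase quantization
contributes mild lack-of-fit). Exact single-run selection of the
generating model should therefore be treated as roughly a coin flip,
not a guarantee.

The univariable R² values on synthetic cohorts are larger than is
typical of clinical drusen data: the generator omits sources of
functional variability that are unrelated to the modeled structure, so
a larger share of the loss variance is explainable. Directional and
calibration properties, not R² magnitudes, are the validated claims.
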