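"""Synthetic cohort generator with known ground truth.

Emulates the study conditions of a drusen structure-function dataset:
per-eye en-face ground-truth maps (RPE elevation, photoreceptor
reflectivity ratio, green autofluorescence, macular pigment ratio), raw
linear-intensity OCT volumes rendered from those maps, dual-wavelength
autofluorescence image pairs, misaligned microperimeter frames with
landmark pairs, and staircase-quantized microperimetric sensitivities
driven by normative (eccentricity/age) and structure-function truth
coefficient sets.

Two generation paths are provided:

* :func:`simulate_cohort` renders every imaging modality so the image
  processing chain (OCT quantification, FAF ratio, registration) can be
  tested end to end against the retained ground truth.
* :func:`simulate_location_records` draws per-location records directly
  from the generating statistical model at full cohort scale, for
  parameter-recovery and calibration studies of the normative and
  structure-function modules where rendering volumes adds nothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .datatypes import (
    DYNAMIC_RANGE_DB,
    GOLDMANN_III_DIAMETER_DEG,
    SLO_PX_PER_DEG,
    TEST_TYPES,
    EnFaceMap,
    MicroperimetryTest,
    OCTVolume,
    PlanarTransform,
    SegmentationSet,
)

#: Default 44-location grid: points per ring at each eccentricity (degrees).
DEFAULT_GRID_SPEC = {1.0: 4, 3.0: 8, 5.0: 8, 7.0: 12, 9.0: 12}


@dataclass(frozen=True)
class NormativeTruth:
    """Generating fixed-effect coefficients of the three normative models.

    Mesopic and scotopic-red sensitivities fall linearly with eccentricity
    and age; the scotopic-cyan profile follows the rod-density dip toward
    the fovea and is quadratic in ln(eccentricity) with no age term.
    Units: dB, dB/deg, dB/year; cyan: dB, dB/ln(deg), dB/ln(deg)^2.
    """

    mesopic: tuple[float, float, float] = (32.0, -0.45, -0.08)
    scotopic_red: tuple[float, float, float] = (18.0, -0.12, -0.05)
    scotopic_cyan: tuple[float, float, float] = (8.0, 3.0, -0.5)
    random_intercept_sd: float = 1.5  # dB, between-eye

    def fixed_effects(self, test_type: str, eccentricity, age):
        """Fixed-effects-only sensitivity prediction, dB."""
        ecc = np.asarray(eccentricity, dtype=float)
        if np.any(ecc <= 0):
            raise ValueError("eccentricity must be positive")
        if test_type == "mesopic":
            b0, be, ba = self.mesopic
            return b0 + be * ecc + ba * np.asarray(age, dtype=float)
        if test_type == "scotopic_red":
            b0, be, ba = self.scotopic_red
            return b0 + be * ecc + ba * np.asarray(age, dtype=float)
        if test_type == "scotopic_cyan":
            b0, b1, b2 = self.scotopic_cyan
            le = np.log(ecc)
            return b0 + b1 * le + b2 * le**2
        raise ValueError(f"unknown test type {test_type!r}")


@dataclass(frozen=True)
class SFTruth:
    """Generating structure-function coefficients on log10 predictors.

    Each slope multiplies the log10 predictor centered at its healthy
    baseline, so the structural contribution vanishes for an unaffected
    location. Signs follow the expected physiology: elevation hurts,
    preserved photoreceptor reflectivity and autofluorescence help.
    """

    rpe_e: float = -2.5  # dB per log10(um)
    prr: float = 8.0  # dB per log10(ratio)
    gaf: float = 4.0  # dB per log10(a.u.)
    rpe_prr_interaction: float = 0.0  # dB per log10(um)*log10(ratio)

    def contribution(self, z_rpe, z_prr, z_gaf):
        return (
            self.rpe_e * z_rpe
            + self.prr * z_prr
            + self.gaf * z_gaf
            + self.rpe_prr_interaction * z_rpe * z_prr
        )


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_healthy: int = 56
    n_drusen: int = 43
    age_range: tuple[float, float] = (55.0, 85.0)
    grid_spec: dict[float, int] = field(
        default_factory=lambda: dict(DEFAULT_GRID_SPEC)
    )
    # drusen morphology
    drusen_count_range: tuple[int, int] = (3, 10)
    drusen_height_range_um: tuple[float, float] = (25.0, 120.0)
    drusen_sigma_range_deg: tuple[float, float] = (0.25, 0.7)
    rpe_floor_um: float = 2.0
    # structural baselines and couplings
    prr_baseline: float = 1.6
    prr_attenuation: float = 0.4  # per unit normalized drusen load
    gaf_baseline: float = 1000.0
    gaf_attenuation: float = 0.3  # fractional GAF loss at full drusen load
    mpod_peak: float = 2.0
    mpod_sigma_deg: float = 3.0
    # measurement/structural noise
    rpe_noise_um: float = 0.3
    prr_noise: float = 0.04
    gaf_noise: float = 25.0
    noise_sd: float = 1.2  # dB, within-eye sensitivity noise
    # truth coefficient sets
    normative_truth: NormativeTruth = field(default_factory=NormativeTruth)
    sf_truth: SFTruth = field(default_factory=SFTruth)
    # record-level generator: fraction of drusen-eye locations affected and
    # coupling of photoreceptor/FAF damage to the local drusen load; zero by
    # default so predictors carry independent information, matching the
    # near-zero inter-predictor correlations the analysis assumes
    p_affected: float = 0.35
    prr_drusen_coupling: float = 0.0
    gaf_drusen_coupling: float = 0.0
    # drusen-localized scenario for the abnormal-RPE-E subset study: the
    # elevation term of the loss acts only above a hinge (healthy-range
    # elevation carries no functional cost), so a single linear fit over
    # all locations is diluted while the abnormal subset is not
    sf_localized: bool = False
    rpe_hinge_um: float = 20.0
    # imaging geometry
    map_field_deg: float = 20.0
    px_per_deg: float = SLO_PX_PER_DEG
    axial_um_per_px: float = 3.87
    render_noise: float = 0.02  # OCT background noise, fraction of RPE peak
    faf_noise: float = 10.0  # a.u. on rendered FAF images
    landmark_noise_px: float = 0.0
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_healthy < 0 or self.n_drusen < 0:
            raise ValueError("cohort sizes must be non-negative")
        if not self.grid_spec:
            raise ValueError("grid_spec must not be empty")
        for lo, hi in (
            self.age_range,
            self.drusen_height_range_um,
            self.drusen_sigma_range_deg,
        ):
            if not lo < hi:
                raise ValueError("ranges must be non-degenerate (lo < hi)")
        if self.prr_baseline <= 1:
            raise ValueError("prr_baseline must exceed 1")
        if self.mpod_peak < 1:
            raise ValueError("mpod_peak must be >= 1")
        if self.px_per_deg <= 0 or self.axial_um_per_px <= 0:
            raise ValueError("scales must be positive")


@dataclass
class GroundTruthEye:
    """All generating quantities for one synthetic eye."""

    eye_id: str
    age_years: float
    cohort: str  # "healthy" | "drusen"
    rpe_elevation_true: EnFaceMap  # um
    prr_true: EnFaceMap
    gaf_true: EnFaceMap
    mpod_ratio_true: EnFaceMap
    random_intercept_db: float
    true_transforms: dict[str, PlanarTransform] = field(default_factory=dict)


@dataclass
class EyeDataset:
    """Rendered modalities for one eye, plus retained ground truth."""

    truth: GroundTruthEye
    volume: OCTVolume | None
    true_segmentation: SegmentationSet | None
    blue_image: np.ndarray | None
    green_image: np.ndarray | None
    tests: dict[str, MicroperimetryTest]
    landmarks: dict[str, tuple[np.ndarray, np.ndarray]]  # (maia_px, slo_px)


def generate_grid(grid_spec: dict[float, int] | None = None) -> np.ndarray:
    """Polar-ring testing grid in degrees relative to the grid center.

    Each ring at eccentricity ``e`` receives ``n`` points at equally spaced
    meridians starting from the positive x axis. The central (0 deg)
    location and the optic-nerve location are never generated: both are
    excluded from analysis by design.

    Returns an (n_points, 2) array of (x, y) in degrees.
    """
    if grid_spec is None:
        grid_spec = DEFAULT_GRID_SPEC
    if not grid_spec:
        raise ValueError("grid_spec must not be empty")
    pts = []
    for ecc in sorted(grid_spec):
        n = grid_spec[ecc]
        if ecc <= 0:
            raise ValueError("ring eccentricities must be positive")
        if n <= 0:
            raise ValueError("ring point counts must be positive")
        ang = 2.0 * np.pi * np.arange(n) / n
        pts.append(np.column_stack([ecc * np.cos(ang), ecc * np.sin(ang)]))
    return np.vstack(pts)


def _deg_grids(n: int, px_per_deg: float) -> tuple[np.ndarray, np.ndarray]:
    c = (n - 1) / 2.0
    ax = (np.arange(n) - c) / px_per_deg
    return np.meshgrid(ax, ax)  # x over columns, y over rows


def _smooth_noise(rng, shape, sd: float, sigma_px: float = 4.0) -> np.ndarray:
    """Spatially smooth Gaussian field with pointwise standard deviation sd."""
    if sd <= 0:
        return np.zeros(shape)
    w = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(w, sigma_px)
    s = f.std()
    return f * (sd / s) if s > 0 else f


def _random_transform(rng, config: SimConfig, kind: str = "projective"
                      ) -> PlanarTransform:
    """Small random misalignment between the MAIA and SLO frames."""
    th = rng.uniform(-2.0, 2.0) * np.pi / 180.0
    s = rng.uniform(0.98, 1.02)
    tx, ty = rng.uniform(-8.0, 8.0, size=2)
    m = np.array(
        [
            [s * math.cos(th), -s * math.sin(th), tx],
            [s * math.sin(th), s * math.cos(th), ty],
            [0.0, 0.0, 1.0],
        ]
    )
    if kind == "projective":
        m[2, :2] = rng.uniform(-1e-5, 1e-5, size=2)
    return PlanarTransform(kind=kind, matrix=m)


def simulate_structure(
    config: SimConfig,
    rng: np.random.Generator,
    cohort: str = "drusen",
    eye_id: str = "eye000",
    age: float | None = None,
) -> GroundTruthEye:
    """Draw the ground-truth structural maps for one eye.

    Drusen eyes receive a random number of Gaussian elevation bumps on a
    small positive RPE floor; the photoreceptor reflectivity ratio is
    attenuated and the autofluorescence reduced in proportion to the
    normalized local drusen load. The macular pigment ratio is a foveally
    peaked radial profile that decays to 1 beyond ~7 degrees. Healthy eyes
    carry zero bumps.
    """
    n = int(round(config.map_field_deg * config.px_per_deg))
    x, y = _deg_grids(n, config.px_per_deg)
    ppd = config.px_per_deg

    elev = np.full((n, n), config.rpe_floor_um)
    if cohort == "drusen":
        k = int(rng.integers(config.drusen_count_range[0],
                             config.drusen_count_range[1] + 1))
        half = config.map_field_deg / 2.0 - 1.0
        for _ in range(k):
            cx, cy = rng.uniform(-half, half, size=2)
            h = rng.uniform(*config.drusen_height_range_um)
            sig = rng.uniform(*config.drusen_sigma_range_deg)
            elev += h * np.exp(-(((x - cx) ** 2 + (y - cy) ** 2)
                                 / (2.0 * sig**2)))
    elif cohort != "healthy":
        raise ValueError(f"unknown cohort {cohort!r}")

    # normalized drusen load in [0, ~1]
    load = (elev - config.rpe_floor_um) / config.drusen_height_range_um[1]

    prr = (config.prr_baseline
           - config.prr_attenuation * load
           + _smooth_noise(rng, (n, n), config.prr_noise, sigma_px=ppd / 4))
    prr = np.maximum(prr, 1.0)

    gaf = (config.gaf_baseline * (1.0 - config.gaf_attenuation * load)
           + _smooth_noise(rng, (n, n), config.gaf_noise, sigma_px=ppd / 4))
    gaf = np.maximum(gaf, 1.0)

    r2 = x**2 + y**2
    mpod = 1.0 + (config.mpod_peak - 1.0) * np.exp(-r2 / config.mpod_sigma_deg**2)

    if age is None:
        age = float(rng.uniform(*config.age_range))
    ri = float(rng.normal(0.0, config.normative_truth.random_intercept_sd))
    transforms = {t: _random_transform(rng, config) for t in TEST_TYPES}

    def emap(v, units):
        return EnFaceMap(values=v, px_per_deg=ppd, units=units)

    return GroundTruthEye(
        eye_id=eye_id,
        age_years=age,
        cohort=cohort,
        rpe_elevation_true=emap(elev, "um"),
        prr_true=emap(prr, ""),
        gaf_true=emap(gaf, "a.u."),
        mpod_ratio_true=emap(mpod, ""),
        random_intercept_db=ri,
        true_transforms=transforms,
    )


# Rendered band intensities (linear, arbitrary units).
_RPE_PEAK = 1.0
_BM_PEAK = 0.6
_BAND_ROWS = 14  # rows rpe-20 .. rpe-7 inclusive


def render_oct_volume(
    eye: GroundTruthEye,
    axial_um_per_px: float | None = None,
    px_per_deg: float | None = None,
    depth: int | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[OCTVolume, SegmentationSet]:
    """Render a raw linear-intensity volume from the true structural maps.

    Each A-scan holds a flat Bruch's membrane row, a bright RPE row at
    ``bm_row - round(elevation / axial_scale)``, and a uniform
    photoreceptor band in the 14 rows between 20 and 7 pixels above the
    RPE whose total intensity encodes the true reflectivity ratio:
    ``band_sum = (prr_true - 1) * (RPE + BM peak)``, which the downstream
    cumulative-signal ratio inverts exactly on noise-free renders.
    """
    axial = 3.87 if axial_um_per_px is None else axial_um_per_px
    ppd = px_per_deg or eye.rpe_elevation_true.px_per_deg
    elev = eye.rpe_elevation_true.values
    prr = eye.prr_true.values
    n_b, n_a = elev.shape

    elev_rows = np.rint(elev / axial).astype(int)
    min_depth = int(elev_rows.max()) + 21 + 1 + 8  # band fits + below-BM pad
    if depth is None:
        depth = min_depth + 4
    bm_row = depth - 8
    rpe_rows = bm_row - elev_rows
    if np.any(rpe_rows - 20 < 0):
        raise ValueError("RPE elevation exceeds the image height")

    if rng is None:
        rng = np.random.default_rng(0)
    if noise_sd > 0:
        vol = np.abs(rng.normal(0.0, noise_sd, size=(n_b, depth, n_a)))
    else:
        vol = np.zeros((n_b, depth, n_a))
    vol = vol.astype(np.float32)

    b_idx, a_idx = np.meshgrid(np.arange(n_b), np.arange(n_a), indexing="ij")
    vol[b_idx, np.full_like(rpe_rows, bm_row), a_idx] += _BM_PEAK
    vol[b_idx, rpe_rows, a_idx] += _RPE_PEAK
    band_val = ((prr - 1.0) * (_RPE_PEAK + _BM_PEAK) / _BAND_ROWS).astype(
        np.float32
    )
    for off in range(7, 21):
        vol[b_idx, rpe_rows - off, a_idx] += band_val

    seg = SegmentationSet(
        ilm_row=np.maximum(rpe_rows - 25, 0),
        rpe_row=rpe_rows,
        bm_row=np.full_like(rpe_rows, bm_row),
    )
    return OCTVolume(intensities=vol, axial_um_per_px=axial,
                     px_per_deg=ppd), seg


def render_faf_pair(
    eye: GroundTruthEye,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render the (blue, green) autofluorescence pair.

    Green carries the fluorescence signal unabsorbed; blue is the same
    signal divided by the macular pigment ratio (pigment absorbs the blue
    excitation, negligibly the green). Independent Gaussian noise is added
    to each channel and intensities are clipped at zero.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    g = eye.gaf_true.values.copy()
    b = g / eye.mpod_ratio_true.values
    if noise_sd > 0:
        g = g + rng.normal(0.0, noise_sd, g.shape)
        b = b + rng.normal(0.0, noise_sd, b.shape)
    return np.maximum(b, 0.0), np.maximum(g, 0.0)


def quantize_sensitivity(value, test_type: str):
    """Quantize to the staircase lattice and clamp to the dynamic range.

    The final staircase step (2 dB mesopic for the 4-2 strategy, 1 dB
    scotopic for the 2-1 procedure) sets the lattice; measured values are
    clamped to [0, 36] dB mesopic and [0, 20] dB scotopic.
    """
    lo, hi, step = DYNAMIC_RANGE_DB[test_type]
    q = np.rint(np.asarray(value, dtype=float) / step) * step
    return np.clip(q, lo, hi)


def _cdb_from_mpod(mpod_mean):
    """Signed correction formula; clamped to 0 where MPOD <= 1."""
    m = np.asarray(mpod_mean, dtype=float)
    raw = 10.0 * np.log10(0.66 * (m - 1.0) + 1.0)
    return np.where(m <= 1.0, 0.0, raw)


def _sf_z(config: SimConfig, rpe_e, prr, gaf):
    """Log10 structural predictors centered at their healthy baselines."""
    z_rpe = np.log10(np.maximum(rpe_e, 1e-6) / config.rpe_floor_um)
    z_prr = np.log10(np.maximum(prr, 1.0) / config.prr_baseline)
    z_gaf = np.log10(np.maximum(gaf, 1e-6) / config.gaf_baseline)
    return z_rpe, z_prr, z_gaf


def simulate_sensitivities(
    eye: GroundTruthEye,
    test_type: str,
    config: SimConfig,
    rng: np.random.Generator,
) -> MicroperimetryTest:
    """Draw one quantized microperimetric test from the generating model.

    True sensitivity = normative fixed effects (eccentricity, age) +
    per-eye random intercept + structure-function contribution evaluated
    on disc-mean structural truth + Gaussian noise. For the cyan stimulus
    the macular-pigment attenuation C_dB (disc mean of the pigment map,
    clamped at 0) is subtracted before emission, so the downstream
    compensation step must add it back.
    """
    if test_type not in TEST_TYPES:
        raise ValueError(f"unknown test type {test_type!r}")
    from .colocalize import sample_disc_mean  # local import to avoid cycle

    pts = generate_grid(config.grid_spec)
    ecc = np.hypot(pts[:, 0], pts[:, 1])
    nt = config.normative_truth
    true = nt.fixed_effects(test_type, ecc, eye.age_years)

    rpe_m = np.array([sample_disc_mean(eye.rpe_elevation_true, p) for p in pts])
    prr_m = np.array([sample_disc_mean(eye.prr_true, p) for p in pts])
    gaf_m = np.array([sample_disc_mean(eye.gaf_true, p) for p in pts])
    z = _sf_z(config, rpe_m, prr_m, gaf_m)
    true = true + config.sf_truth.contribution(*z) + eye.random_intercept_db

    if test_type == "scotopic_cyan":
        mpod_m = np.array(
            [sample_disc_mean(eye.mpod_ratio_true, p) for p in pts]
        )
        true = true - _cdb_from_mpod(mpod_m)

    measured = true + rng.normal(0.0, config.noise_sd, size=len(ecc))
    emitted = quantize_sensitivity(measured, test_type)
    return MicroperimetryTest(
        test_type=test_type,
        points_deg=pts,
        sensitivities_db=emitted,
        eye_id=eye.eye_id,
        age_years=eye.age_years,
    )


def simulate_eye(
    config: SimConfig,
    rng: np.random.Generator,
    cohort: str,
    eye_id: str,
    with_volume: bool = True,
) -> EyeDataset:
    """Generate one eye with every modality and its ground truth."""
    truth = simulate_structure(config, rng, cohort=cohort, eye_id=eye_id)
    volume = seg = None
    if with_volume:
        volume, seg = render_oct_volume(
            truth,
            axial_um_per_px=config.axial_um_per_px,
            noise_sd=config.render_noise,
            rng=rng,
        )
    blue, green = render_faf_pair(truth, noise_sd=config.faf_noise, rng=rng)
    tests = {
        t: simulate_sensitivities(truth, t, config, rng) for t in TEST_TYPES
    }
    # landmark pairs: fixed points in the MAIA frame mapped by the true
    # transform into the SLO frame (optionally jittered)
    n_map = truth.rpe_elevation_true.shape[0]
    m = n_map * 0.35
    c = (n_map - 1) / 2.0
    base = np.array(
        [[c - m, c - m], [c + m, c - m], [c - m, c + m], [c + m, c + m],
         [c, c - m], [c, c + m], [c - m, c], [c + m, c]]
    )
    landmarks = {}
    for t in TEST_TYPES:
        dst = truth.true_transforms[t].apply(base)
        if config.landmark_noise_px > 0:
            dst = dst + rng.normal(0, config.landmark_noise_px, dst.shape)
        landmarks[t] = (base.copy(), dst)
    return EyeDataset(
        truth=truth,
        volume=volume,
        true_segmentation=seg,
        blue_image=blue,
        green_image=green,
        tests=tests,
        landmarks=landmarks,
    )


def simulate_cohort(
    config: SimConfig, with_volumes: bool = True
) -> list[EyeDataset]:
    """Generate the full healthy + drusen cohort, deterministic in the seed."""
    rng = np.random.default_rng(config.random_seed)
    eyes = []
    for i in range(config.n_healthy):
        eyes.append(
            simulate_eye(config, rng, "healthy", f"H{i:03d}", with_volumes)
        )
    for i in range(config.n_drusen):
        eyes.append(
            simulate_eye(config, rng, "drusen", f"D{i:03d}", with_volumes)
        )
    return eyes


def simulate_location_records(
    config: SimConfig,
    seed: int | None = None,
    cohorts: tuple[str, ...] = ("healthy", "drusen"),
    test_types: tuple[str, ...] = TEST_TYPES,
) -> pd.DataFrame:
    """Draw the per-location record table straight from the generating model.

    Produces the same statistical structure as the full imaging pipeline
    (normative truth + random intercepts + structure-function contribution
    + staircase quantization + cyan pigment attenuation) without rendering
    images. Structural predictors are drawn with near-zero cross-correlation
    across locations, matching the weak inter-predictor correlations the
    analysis assumes. Cyan rows carry the emitted (attenuated) sensitivity
    in ``sensitivity_db`` and the true disc-mean correction in
    ``cdb_mean_db``; compensation is left to the pipeline.
    """
    rng = np.random.default_rng(
        config.random_seed if seed is None else seed
    )
    pts = generate_grid(config.grid_spec)
    ecc = np.hypot(pts[:, 0], pts[:, 1])
    n_loc = len(pts)
    nt = config.normative_truth
    rows = []
    counts = {"healthy": config.n_healthy, "drusen": config.n_drusen}
    for cohort in cohorts:
        for i in range(counts[cohort]):
            eye_id = f"{'H' if cohort == 'healthy' else 'D'}{i:03d}"
            age = rng.uniform(*config.age_range)
            ri = rng.normal(0.0, nt.random_intercept_sd)
            if cohort == "drusen":
                aff = rng.random(n_loc) < config.p_affected
                d = np.where(aff, rng.uniform(0.2, 1.0, n_loc), 0.0)
                u_ind = np.where(
                    rng.random(n_loc) < config.p_affected,
                    rng.uniform(0.2, 1.0, n_loc),
                    0.0,
                )
                u = ((1 - config.prr_drusen_coupling) * u_ind
                     + config.prr_drusen_coupling * d)
                g_ind = np.where(
                    rng.random(n_loc) < config.p_affected,
                    rng.uniform(0.2, 1.0, n_loc),
                    0.0,
                )
                g = ((1 - config.gaf_drusen_coupling) * g_ind
                     + config.gaf_drusen_coupling * d)
            else:
                d = u = g = np.zeros(n_loc)
            # true structural state drives the functional effect; the
            # reported disc means add measurement noise on top of it
            rpe_true = (config.rpe_floor_um
                        + d * rng.uniform(*config.drusen_height_range_um,
                                          size=n_loc))
            prr_true = np.maximum(
                config.prr_baseline - config.prr_attenuation * u, 1.0
            )
            gaf_true = np.maximum(
                config.gaf_baseline * (1.0 - config.gaf_attenuation * g), 1.0
            )
            rpe = rpe_true + np.abs(rng.normal(0, config.rpe_noise_um, n_loc))
            prr = np.maximum(
                prr_true + rng.normal(0, config.prr_noise, n_loc), 1.0
            )
            gaf = np.maximum(
                gaf_true + rng.normal(0, config.gaf_noise, n_loc), 1.0
            )
            if config.sf_localized:
                # loss driven by the true structural state through an
                # elevation hinge; the reported means keep their
                # measurement spread, so the all-locations linear fit is
                # deliberately misspecified below the hinge
                z = _sf_z(config, rpe_true, prr_true, gaf_true)
                z_hinge = np.log10(config.rpe_hinge_um / config.rpe_floor_um)
                z = (np.maximum(z[0] - z_hinge, 0.0), z[1], z[2])
            else:
                # effect evaluated on the reported structural values: the
                # fitted model matches the generating one exactly
                z = _sf_z(config, rpe, prr, gaf)
            sf = config.sf_truth.contribution(*z)
            if cohort == "healthy":
                # healthy structure sits at baseline and defines the
                # normative reference; it contributes no loss
                sf = np.zeros(n_loc)
            mpod = 1.0 + (config.mpod_peak - 1.0) * np.exp(
                -(ecc**2) / config.mpod_sigma_deg**2
            )
            cdb = _cdb_from_mpod(mpod)
            for t in test_types:
                true = nt.fixed_effects(t, ecc, age) + ri + sf
                if t == "scotopic_cyan":
                    true = true - cdb
                meas = true + rng.normal(0, config.noise_sd, n_loc)
                emitted = quantize_sensitivity(meas, t)
                rows.append(
                    pd.DataFrame(
                        {
                            "eye_id": eye_id,
                            "cohort": cohort,
                            "test_type": t,
                            "loc_index": np.arange(n_loc),
                            "x_deg": pts[:, 0],
                            "y_deg": pts[:, 1],
                            "eccentricity_deg": ecc,
                            "sensitivity_db": emitted,
                            "rpe_e_mean_um": rpe,
                            "prr_mean": prr,
                            "gaf_mean": gaf,
                            "cdb_mean_db": cdb if t == "scotopic_cyan"
                            else 0.0,
                            "age_years": age,
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)
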