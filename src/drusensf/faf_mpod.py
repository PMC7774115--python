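"""Macular pigment maps from dual-wavelength autofluorescence.

Macular pigment absorbs the blue (488 nm) excitation but barely the
green (518 nm) one, so the per-pixel ratio of the two channels acts as
an optical pigment-density surrogate. Because the cyan (505 nm)
microperimetric stimulus is itself absorbed by the pigment, the ratio is
converted into a dB correction added back to the measured cyan
sensitivity. At 505 nm the absorption is about 66% of that at 488 nm,
hence the factor 0.66 in the correction formula.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy import ndimage

from .datatypes import EnFaceMap, MicroperimetryTest

MP_ABSORPTION_FACTOR = 0.66


@dataclass
class FAFPair:
    """Co-registered blue (488 nm) and green (518 nm) AF images."""

    blue_image: np.ndarray
    green_image: np.ndarray
    px_per_deg: float

    def __post_init__(self) -> None:
        self.blue_image = np.asarray(self.blue_image, dtype=float)
        self.green_image = np.asarray(self.green_image, dtype=float)
        if self.blue_image.shape != self.green_image.shape:
            raise ValueError("blue and green images must share one shape")
        if np.any(self.blue_image < 0) or np.any(self.green_image < 0):
            raise ValueError("AF intensities must be non-negative")


@dataclass
class CorrectionMap:
    """MPOD ratio map with its dB correction.

    ``c_db`` is the clamped map (0 wherever the ratio is <= 1);
    ``c_db_signed`` keeps the raw formula value, which may be negative
    where the ratio dips below 1. Per-location disc means are taken on
    the signed map and only the means are clamped, so pixel noise around
    a ratio of 1 averages out instead of biasing the correction upward.
    """

    mpod_ratio: EnFaceMap
    c_db: EnFaceMap
    c_db_signed: EnFaceMap


def compute_mpod_ratio(pair: FAFPair, smoothing_px: float = 0.0) -> EnFaceMap:
    """MPOD ratio map, oriented so pigment absorption gives values > 1.

    Computed as green / blue: the blue channel is the attenuated one, so
    absorption raises the ratio above 1. Pixels where either channel is
    zero are masked invalid. Optional Gaussian pre-smoothing (sigma in
    pixels) is applied to both channels before the division.
    """
    blue, green = pair.blue_image, pair.green_image
    if smoothing_px > 0:
        blue = ndimage.gaussian_filter(blue, smoothing_px)
        green = ndimage.gaussian_filter(green, smoothing_px)
    valid = (blue > 0) & (green > 0)
    if not valid.any():
        raise ValueError("no valid pixels: a channel is zero everywhere")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(valid, green / np.where(valid, blue, 1.0), np.nan)
    return EnFaceMap(
        values=ratio, px_per_deg=pair.px_per_deg, units="", mask=valid
    )


def compute_cdb(
    mpod_ratio,
    k: float = MP_ABSORPTION_FACTOR,
    clamp: bool = True,
):
    """Cyan-sensitivity correction C_dB = 10*log10(k*(MPOD - 1) + 1).

    The correction is 0 at an MPOD ratio of exactly 1 (no absorption) and,
    with ``clamp`` (the default), 0 for every ratio below 1. With
    ``clamp=False`` the signed formula value is returned (used internally
    before disc averaging). Accepts scalars or arrays.
    """
    m = np.asarray(mpod_ratio, dtype=float)
    if np.any(m <= 0):
        raise ValueError("MPOD ratio must be positive")
    arg = k * (m - 1.0) + 1.0
    out = 10.0 * np.log10(arg)
    if clamp:
        out = np.where(m < 1.0, 0.0, out)
        out = np.maximum(out, 0.0)
    if np.isscalar(mpod_ratio):
        return float(out)
    return out


def build_correction_map(
    pair: FAFPair, smoothing_px: float = 0.0, k: float = MP_ABSORPTION_FACTOR
) -> CorrectionMap:
    """MPOD ratio plus clamped and signed C_dB maps from one FAF pair."""
    ratio = compute_mpod_ratio(pair, smoothing_px=smoothing_px)
    valid = ratio.valid_mask()
    m = np.where(valid, ratio.values, 1.0)
    signed = compute_cdb(m, k=k, clamp=False)
    clamped = compute_cdb(m, k=k, clamp=True)
    signed = np.where(valid, signed, np.nan)
    clamped = np.where(valid, clamped, np.nan)
    mk = dict(px_per_deg=pair.px_per_deg, units="dB", mask=valid)
    return CorrectionMap(
        mpod_ratio=ratio,
        c_db=EnFaceMap(values=clamped, **mk),
        c_db_signed=EnFaceMap(values=signed, **mk),
    )


def clamp_cdb_means(cdb_means) -> np.ndarray:
    """Clamp per-location disc-mean corrections at zero (ratio-below-1
    averages contribute no negative correction)."""
    return np.maximum(np.asarray(cdb_means, dtype=float), 0.0)


def compensate_cyan(
    test: MicroperimetryTest, cdb_means
) -> MicroperimetryTest:
    """Add the per-location mean correction to a cyan test's sensitivities.

    Non-cyan tests pass through unchanged (pigment absorption is only
    relevant for the cyan stimulus).
    """
    if test.test_type != "scotopic_cyan":
        return test
    cdb = clamp_cdb_means(cdb_means)
    if len(cdb) != test.n_locations:
        raise ValueError(
            f"{len(cdb)} corrections for {test.n_locations} locations"
        )
    return MicroperimetryTest(
        test_type=test.test_type,
        points_deg=test.points_deg.copy(),
        sensitivities_db=test.sensitivities_db + cdb,
        eye_id=test.eye_id,
        age_years=test.age_years,
    )


def compensate_records(records):
    """Apply MP compensation on a location-record table.

    Returns a copy where cyan rows' ``sensitivity_db`` has the clamped
    ``cdb_mean_db`` added; the raw value is preserved in
    ``sensitivity_raw_db``. Other test types keep their raw value in both
    columns.
    """
    out = records.copy()
    out["sensitivity_raw_db"] = out["sensitivity_db"]
    cyan = out["test_type"] == "scotopic_cyan"
    out.loc[cyan, "sensitivity_db"] = out.loc[cyan, "sensitivity_db"] + (
        clamp_cdb_means(out.loc[cyan, "cdb_mean_db"].to_numpy())
    )
    return out
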