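"""Registration of microperimeter frames and per-location structural means.

The microperimeter tracks the fundus in its own camera frame; structural
maps live in the SLO/OCT frame. A planar (affine or projective)
transform estimated from landmark pairs carries each tested location
into the structural frame, where the Goldmann III stimulus footprint
(0.43 degrees diameter) is averaged over each map to give one
co-localized measurement per location.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from skimage import transform as sktransform

from .datatypes import (
    GOLDMANN_III_DIAMETER_DEG,
    SLO_PX_PER_DEG,
    EnFaceMap,
    MicroperimetryTest,
    PlanarTransform,
)
from .faf_mpod import CorrectionMap, clamp_cdb_means


def estimate_transform(
    src_points: np.ndarray,
    dst_points: np.ndarray,
    kind: str = "projective",
) -> PlanarTransform:
    """Least-squares planar transform from landmark pairs.

    Needs at least 3 non-collinear pairs for an affine fit, 4 for a
    projective one. The fitted transform carries its landmark residual
    RMS (pixels) in ``residual_rms_px``.
    """
    src = np.asarray(src_points, dtype=float)
    dst = np.asarray(dst_points, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("point sets must be matching (n, 2) arrays")
    n_min = {"affine": 3, "projective": 4}.get(kind)
    if n_min is None:
        raise ValueError("kind must be 'affine' or 'projective'")
    if len(src) < n_min:
        raise ValueError(f"{kind} fit needs >= {n_min} point pairs")
    tf = sktransform.estimate_transform(kind, src, dst)
    if not tf:  # degenerate estimation (e.g. collinear landmarks)
        raise ValueError(f"degenerate landmark configuration: {tf}")
    matrix = np.asarray(tf.params, dtype=float)
    if not np.all(np.isfinite(matrix)) or abs(np.linalg.det(matrix)) < 1e-12:
        raise ValueError("degenerate landmark configuration")
    out = PlanarTransform(kind=kind, matrix=matrix)
    res = out.apply(src) - dst
    out.residual_rms_px = float(np.sqrt(np.mean(np.sum(res**2, axis=1))))
    return out


def map_locations(
    transform: PlanarTransform,
    points_src_px: np.ndarray,
    image_shape: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Map (x, y) pixel points into the target frame.

    Returns ``(points_px, inside)``; with ``image_shape`` given
    (rows, cols), points landing outside the target image are flagged
    ``inside=False`` with a warning, for the caller to mask.
    """
    pts = transform.apply(points_src_px)
    inside = np.ones(len(pts), dtype=bool)
    if image_shape is not None:
        h, w = image_shape
        inside = (
            (pts[:, 0] >= 0) & (pts[:, 0] <= w - 1)
            & (pts[:, 1] >= 0) & (pts[:, 1] <= h - 1)
        )
        if not inside.all():
            warnings.warn(
                f"{int((~inside).sum())} locations mapped outside the image",
                stacklevel=2,
            )
    return pts, inside


def px_to_deg(points_px, image_shape, px_per_deg: float = SLO_PX_PER_DEG):
    """Pixel coordinates to degrees about the image center."""
    pts = np.atleast_2d(np.asarray(points_px, dtype=float))
    h, w = image_shape
    c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    return (pts - c) / px_per_deg


def deg_to_px(points_deg, image_shape, px_per_deg: float = SLO_PX_PER_DEG):
    """Degrees about the image center to pixel coordinates."""
    pts = np.atleast_2d(np.asarray(points_deg, dtype=float))
    h, w = image_shape
    c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    return pts * px_per_deg + c


def sample_disc_mean(
    emap: EnFaceMap,
    center_deg,
    diameter_deg: float = GOLDMANN_III_DIAMETER_DEG,
) -> float:
    """Unweighted mean over pixels whose centers fall inside the stimulus disc.

    The disc is centered at ``center_deg`` (x, y degrees about the map
    center). At the SLO calibration the Goldmann III radius is
    (0.43 / 2) * 25.6 = 5.5 px. A disc smaller than the pixel pitch falls
    back to the single containing pixel. Returns NaN when no valid pixel
    lies inside the disc.
    """
    cx_deg, cy_deg = float(center_deg[0]), float(center_deg[1])
    col_c, row_c = emap.deg_to_px(cx_deg, cy_deg)
    r_px = (diameter_deg / 2.0) * emap.px_per_deg
    h, w = emap.shape
    valid = emap.valid_mask()

    r_ceil = max(int(np.ceil(r_px)), 0)
    r0 = max(int(np.floor(row_c)) - r_ceil - 1, 0)
    r1 = min(int(np.ceil(row_c)) + r_ceil + 2, h)
    c0 = max(int(np.floor(col_c)) - r_ceil - 1, 0)
    c1 = min(int(np.ceil(col_c)) + r_ceil + 2, w)
    if r0 >= r1 or c0 >= c1:
        return float("nan")
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    inside = (rr - row_c) ** 2 + (cc - col_c) ** 2 <= r_px**2
    sel = inside & valid[r0:r1, c0:c1]
    if not sel.any():
        # sub-pixel disc: take the containing pixel if it is valid
        ri, ci = int(round(row_c)), int(round(col_c))
        if 0 <= ri < h and 0 <= ci < w and valid[ri, ci]:
            return float(emap.values[ri, ci])
        return float("nan")
    return float(emap.values[r0:r1, c0:c1][sel].mean())


def build_location_table(
    tests: list[MicroperimetryTest],
    transforms: dict[str, PlanarTransform],
    rpe_e_map: EnFaceMap,
    prr_map: EnFaceMap,
    gaf_map: EnFaceMap,
    correction: CorrectionMap | None = None,
    cohort: str = "",
    maia_px_per_deg: float | None = None,
    maia_image_shape: tuple[int, int] | None = None,
    compensate: bool = True,
) -> pd.DataFrame:
    """Project every tested location onto the structural maps.

    Grid coordinates (degrees about the PRL) are converted to
    microperimeter pixels, carried through that test's transform into the
    SLO frame, and the disc mean of each structural map is extracted
    there. The green-AF map supplies the autofluorescence means. Cyan
    rows receive the disc mean of the signed C_dB map (clamped at zero)
    and, with ``compensate`` (default), the compensated sensitivity.
    Eccentricity stays defined in the grid frame: distance from the grid
    center. Locations mapped outside the structural frame are dropped.
    """
    if maia_px_per_deg is None:
        # synthetic microperimeter frames share the structural calibration;
        # pass the device scale explicitly for real exports
        maia_px_per_deg = rpe_e_map.px_per_deg
    if maia_image_shape is None:
        maia_image_shape = rpe_e_map.shape
    frames = []
    for test in tests:
        tf = transforms[test.test_type]
        src_px = deg_to_px(test.points_deg, maia_image_shape, maia_px_per_deg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dst_px, inside = map_locations(tf, src_px, rpe_e_map.shape)
        dst_deg = px_to_deg(dst_px, rpe_e_map.shape, rpe_e_map.px_per_deg)
        ecc = test.eccentricities()

        rpe_m = np.array([sample_disc_mean(rpe_e_map, p) for p in dst_deg])
        prr_m = np.array([sample_disc_mean(prr_map, p) for p in dst_deg])
        gaf_m = np.array([sample_disc_mean(gaf_map, p) for p in dst_deg])
        sens = test.sensitivities_db.astype(float).copy()
        cdb_m = np.zeros(len(ecc))
        if test.test_type == "scotopic_cyan" and correction is not None:
            cdb_raw = np.array(
                [sample_disc_mean(correction.c_db_signed, p) for p in dst_deg]
            )
            cdb_m = clamp_cdb_means(np.nan_to_num(cdb_raw, nan=0.0))
            if compensate:
                sens = sens + cdb_m

        keep = inside & np.isfinite(rpe_m) & np.isfinite(prr_m) \
            & np.isfinite(gaf_m)
        frames.append(
            pd.DataFrame(
                {
                    "eye_id": test.eye_id,
                    "cohort": cohort,
                    "test_type": test.test_type,
                    "loc_index": np.arange(len(ecc)),
                    "x_deg": test.points_deg[:, 0],
                    "y_deg": test.points_deg[:, 1],
                    "eccentricity_deg": ecc,
                    "sensitivity_db": sens,
                    "rpe_e_mean_um": rpe_m,
                    "prr_mean": prr_m,
                    "gaf_mean": gaf_m,
                    "cdb_mean_db": cdb_m,
                    "age_years": test.age_years,
                }
            )[keep]
        )
    return pd.concat(frames, ignore_index=True)
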