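"""Core containers shared across the pipeline.

Coordinate conventions
----------------------
* En-face arrays are indexed ``[row, col]`` with row 0 at the top; the
  angular origin (0, 0) degrees sits at the array center, x increasing
  with column and y with row.
* OCT volumes are indexed ``(b_scan, depth_row, a_scan)``; depth row 0 is
  the vitreous side and the last row is the bottom of the image.
* All angular scales are expressed in pixels per degree. The SLO default
  is 768 px / 30 deg = 25.6 px/deg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: SLO angular calibration: 768 px over a 30 degree field.
SLO_PX_PER_DEG = 768.0 / 30.0

#: Goldmann III stimulus diameter in degrees.
GOLDMANN_III_DIAMETER_DEG = 0.43

#: Per-test (floor dB, ceiling dB, final staircase step dB).
TEST_TYPES = ("mesopic", "scotopic_red", "scotopic_cyan")
DYNAMIC_RANGE_DB = {
    "mesopic": (0.0, 36.0, 2.0),
    "scotopic_red": (0.0, 20.0, 1.0),
    "scotopic_cyan": (0.0, 20.0, 1.0),
}


@dataclass
class EnFaceMap:
    """Scalar map over the en-face plane (RPE-E, PRR, GAF, MPOD, C_dB)."""

    values: np.ndarray
    px_per_deg: float
    units: str = ""
    mask: np.ndarray | None = None  # True where valid; None = all valid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("EnFaceMap values must be 2-D")
        if self.px_per_deg <= 0:
            raise ValueError("px_per_deg must be positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def center_px(self) -> tuple[float, float]:
        """(col, row) of the angular origin."""
        h, w = self.values.shape
        return ((w - 1) / 2.0, (h - 1) / 2.0)

    def valid_mask(self) -> np.ndarray:
        if self.mask is None:
            return np.ones(self.values.shape, dtype=bool)
        return self.mask

    def deg_to_px(self, x_deg, y_deg) -> tuple[np.ndarray, np.ndarray]:
        cx, cy = self.center_px
        return (np.asarray(x_deg) * self.px_per_deg + cx,
                np.asarray(y_deg) * self.px_per_deg + cy)

    def px_to_deg(self, col, row) -> tuple[np.ndarray, np.ndarray]:
        cx, cy = self.center_px
        return ((np.asarray(col) - cx) / self.px_per_deg,
                (np.asarray(row) - cy) / self.px_per_deg)


@dataclass
class OCTVolume:
    """Raw linear-intensity OCT volume.

    Intensities are non-negative, untransformed (linear) values as exported
    by the device, indexed ``(b_scan, depth_row, a_scan)``.
    """

    intensities: np.ndarray
    axial_um_per_px: float
    px_per_deg: float = SLO_PX_PER_DEG

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float32)
        if self.intensities.ndim != 3:
            raise ValueError("OCT volume must be 3-D (b_scan, depth, a_scan)")
        if self.axial_um_per_px <= 0 or self.px_per_deg <= 0:
            raise ValueError("scales must be positive")
        if np.any(self.intensities < 0):
            raise ValueError("OCT intensities must be non-negative")

    @property
    def n_bscans(self) -> int:
        return self.intensities.shape[0]

    @property
    def depth(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_ascans(self) -> int:
        return self.intensities.shape[2]


@dataclass
class SegmentationSet:
    """Per-A-scan depth-row indices for ILM, RPE and Bruch's membrane.

    Row indices increase with depth, so the anatomical ordering
    ILM above RPE above BM reads ``ilm_row <= rpe_row <= bm_row``.
    """

    ilm_row: np.ndarray
    rpe_row: np.ndarray
    bm_row: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ilm_row = np.asarray(self.ilm_row, dtype=int)
        self.rpe_row = np.asarray(self.rpe_row, dtype=int)
        self.bm_row = np.asarray(self.bm_row, dtype=int)
        if not (self.ilm_row.shape == self.rpe_row.shape == self.bm_row.shape):
            raise ValueError("segmentation arrays must share one shape")
        if self.valid is None:
            self.valid = np.ones(self.rpe_row.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        v = self.valid
        if np.any(self.ilm_row[v] > self.rpe_row[v]) or np.any(
            self.rpe_row[v] > self.bm_row[v]
        ):
            bad = np.argwhere(
                (self.ilm_row > self.rpe_row) | (self.rpe_row > self.bm_row)
            )
            raise ValueError(
                "segmentation ordering ILM <= RPE <= BM violated at "
                f"(b_scan, a_scan) = {tuple(bad[0])}"
            )


@dataclass
class MicroperimetryTest:
    """One microperimetric examination of one eye.

    ``points_deg`` holds (x, y) grid coordinates in degrees relative to the
    grid center (the preferred retinal locus), one row per tested location.
    """

    test_type: str
    points_deg: np.ndarray
    sensitivities_db: np.ndarray
    eye_id: str
    age_years: float

    def __post_init__(self) -> None:
        if self.test_type not in TEST_TYPES:
            raise ValueError(f"unknown test type {self.test_type!r}")
        self.points_deg = np.asarray(self.points_deg, dtype=float)
        self.sensitivities_db = np.asarray(self.sensitivities_db, dtype=float)
        if self.points_deg.shape != (len(self.sensitivities_db), 2):
            raise ValueError("points_deg must be (n, 2) matching sensitivities")

    @property
    def n_locations(self) -> int:
        return len(self.sensitivities_db)

    def eccentricities(self) -> np.ndarray:
        """Distance of each location from the grid center, degrees."""
        return np.hypot(self.points_deg[:, 0], self.points_deg[:, 1])


@dataclass
class PlanarTransform:
    """Affine or projective map between two fundus pixel frames."""

    kind: str
    matrix: np.ndarray
    source: str = "maia"
    target: str = "slo"
    residual_rms_px: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("affine", "projective"):
            raise ValueError("kind must be 'affine' or 'projective'")
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ValueError("matrix must be 3x3 homogeneous")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("transform matrix is singular")
        if self.kind == "affine" and not np.allclose(
            self.matrix[2], [0.0, 0.0, 1.0], atol=1e-9
        ):
            raise ValueError("affine transform must have last row (0, 0, 1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 2) points with perspective division."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        h = np.hstack([pts, np.ones((len(pts), 1))])
        out = h @ self.matrix.T
        return out[:, :2] / out[:, 2:3]

    def inverse(self) -> "PlanarTransform":
        return PlanarTransform(
            kind=self.kind,
            matrix=np.linalg.inv(self.matrix),
            source=self.target,
            target=self.source,
        )


#: Column contract of the per-location record table consumed by the
#: statistical modules (one row per analyzed grid location per test).
LOCATION_RECORD_COLUMNS = [
    "eye_id",
    "cohort",
    "test_type",
    "loc_index",
    "x_deg",
    "y_deg",
    "eccentricity_deg",
    "sensitivity_db",
    "rpe_e_mean_um",
    "prr_mean",
    "gaf_mean",
    "cdb_mean_db",
    "age_years",
]
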