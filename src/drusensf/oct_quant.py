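"""OCT structural maps: RPE elevation and photoreceptor reflectivity ratio.

All computations run on untransformed (linear) intensities. The RPE is
located per A-scan as the first normalized intensity peak above a 0.4
threshold closest to Bruch's membrane, then smoothed across the B-scan;
RPE elevation is the row difference to the BM segmentation times the
axial scale. The photoreceptor reflectivity ratio (PRR) divides the
cumulative linear signal integrated from 20 pixels above the RPE to the
image bottom by the same sum started 6 pixels above the RPE: a dim
photoreceptor band drives the ratio toward 1.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datatypes import EnFaceMap, OCTVolume, SegmentationSet

DEFAULT_PEAK_THRESHOLD = 0.4
DEFAULT_PRR_OFFSETS = (6, 20)


def _local_maxima(profile: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; a plateau yields its last sample.

    Array boundaries count as maxima when they exceed their single
    neighbor. "Last sample" of a plateau is the one with the largest row
    index, i.e. the sample nearest Bruch's membrane for a profile ordered
    vitreous-to-BM.
    """
    n = len(profile)
    if n == 0:
        return np.array([], dtype=int)
    if n == 1:
        return np.array([0], dtype=int)
    peaks = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and profile[j + 1] == profile[i]:
            j += 1
        left_ok = i == 0 or profile[i - 1] < profile[i]
        right_ok = j == n - 1 or profile[j + 1] < profile[i]
        if left_ok and right_ok:
            peaks.append(j)
        i = j + 1
    return np.array(peaks, dtype=int)


def rpe_initial_guess(
    ascan_intensities: np.ndarray,
    bm_row: int,
    threshold: float = DEFAULT_PEAK_THRESHOLD,
) -> tuple[int, bool]:
    """Initial RPE row for one A-scan.

    The profile above the BM (rows ``0 .. bm_row - 1``) is normalized by
    its maximum; the returned row is the local maximum with normalized
    value strictly above ``threshold`` that lies nearest to (and above)
    the BM.

    Returns ``(row, valid)``; ``valid`` is False when the profile is all
    zero or no peak clears the threshold, in which case the caller should
    interpolate from neighboring A-scans.
    """
    if bm_row < 1:
        raise ValueError("bm_row must be >= 1 (need samples above the BM)")
    profile = np.asarray(ascan_intensities[:bm_row], dtype=float)
    peak = profile.max() if profile.size else 0.0
    if peak <= 0:
        return 0, False
    norm = profile / peak
    maxima = _local_maxima(norm)
    good = maxima[norm[maxima] > threshold]
    if good.size == 0:
        return 0, False
    return int(good.max()), True  # largest row index = closest to the BM


def initial_rpe_rows(
    volume: OCTVolume,
    bm_row: np.ndarray,
    threshold: float = DEFAULT_PEAK_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-A-scan initial RPE guesses over a whole volume."""
    bm = np.asarray(bm_row, dtype=int)
    n_b, _, n_a = volume.intensities.shape
    rows = np.zeros((n_b, n_a), dtype=int)
    valid = np.zeros((n_b, n_a), dtype=bool)
    for b in range(n_b):
        sl = volume.intensities[b]
        for a in range(n_a):
            rows[b, a], valid[b, a] = rpe_initial_guess(
                sl[:, a], int(bm[b, a]), threshold
            )
    return rows, valid


def refine_rpe(
    initial_rows: np.ndarray,
    valid: np.ndarray,
    bm_row: np.ndarray | None = None,
    max_jump: int = 10,
    median_width: int = 5,
) -> np.ndarray:
    """Smooth the initial RPE guesses into a continuous per-B-scan path.

    Within each B-scan, columns flagged invalid or deviating from the
    running median by more than ``max_jump`` rows (the per-column slope
    bound) are discarded and re-interpolated linearly from their valid
    neighbors; edge gaps take the nearest valid value. Columns that are
    already smooth and valid pass through unchanged. The result is capped
    at the BM row (the RPE can never lie below Bruch's membrane).
    """
    from scipy.ndimage import median_filter

    rows = np.atleast_2d(np.asarray(initial_rows, dtype=float))
    valid = np.atleast_2d(np.asarray(valid, dtype=bool))
    out = np.empty_like(rows)
    for b in range(rows.shape[0]):
        r = rows[b].copy()
        v = valid[b].copy()
        if not v.any():
            raise ValueError(f"entire B-scan {b} invalid")
        idx = np.arange(len(r))
        # fill invalid columns before outlier screening
        r_filled = np.interp(idx, idx[v], r[v])
        med = median_filter(r_filled, size=median_width, mode="nearest")
        v &= np.abs(r - med) <= max_jump
        if not v.any():
            raise ValueError(f"entire B-scan {b} invalid after slope bound")
        out[b] = np.interp(idx, idx[v], r[v])
    out = np.rint(out).astype(int)
    if bm_row is not None:
        out = np.minimum(out, np.atleast_2d(np.asarray(bm_row, dtype=int)))
    if np.asarray(initial_rows).ndim == 1:
        return out[0]
    return out


def segment_volume(
    volume: OCTVolume,
    bm_row: np.ndarray,
    ilm_row: np.ndarray | None = None,
    threshold: float = DEFAULT_PEAK_THRESHOLD,
    max_jump: int = 10,
) -> SegmentationSet:
    """Peak-initialize and refine the RPE against a given BM segmentation."""
    rows, valid = initial_rpe_rows(volume, bm_row, threshold)
    rpe = refine_rpe(rows, valid, bm_row=bm_row, max_jump=max_jump)
    if ilm_row is None:
        ilm_row = np.zeros_like(rpe)
    return SegmentationSet(ilm_row=ilm_row, rpe_row=rpe, bm_row=bm_row)


def compute_rpe_elevation(
    seg: SegmentationSet,
    axial_um_per_px: float,
    px_per_deg: float,
) -> EnFaceMap:
    """RPE elevation map: (BM row - RPE row) * axial scale, micrometers."""
    diff = seg.bm_row - seg.rpe_row
    if np.any(diff < 0):
        bad = np.argwhere(diff < 0)[0]
        raise ValueError(
            "RPE below BM at (b_scan, a_scan) = "
            f"({int(bad[0])}, {int(bad[1])})"
        )
    return EnFaceMap(
        values=diff * float(axial_um_per_px),
        px_per_deg=px_per_deg,
        units="um",
        mask=seg.valid.copy() if seg.valid is not None else None,
    )


def cumulative_signal(
    ascan_intensities: np.ndarray, start_row: int
) -> tuple[float, bool]:
    """Linear sum from ``start_row`` to the bottom of the A-scan, inclusive.

    A ``start_row`` above the image top (negative) is clamped to 0 and
    flagged (RPE too close to the image top); a row past the bottom is an
    error. Returns ``(sum, clamped)``.
    """
    a = np.asarray(ascan_intensities, dtype=float)
    if start_row >= len(a):
        raise ValueError("start_row beyond the bottom of the image")
    clamped = start_row < 0
    if clamped:
        warnings.warn("start_row above image top; clamped to 0", stacklevel=2)
        start_row = 0
    return float(a[start_row:].sum()), clamped


def compute_prr(
    volume: OCTVolume,
    seg: SegmentationSet,
    offsets: tuple[int, int] = DEFAULT_PRR_OFFSETS,
) -> EnFaceMap:
    """Photoreceptor reflectivity ratio map (vectorized).

    Per A-scan: ``S_near`` sums the linear signal from ``rpe_row -
    offsets[0]`` to the image bottom, ``S_far`` from ``rpe_row -
    offsets[1]``; PRR = S_far / S_near >= 1 since the far sum contains
    every term of the near sum plus the photoreceptor band between the
    two start rows. A-scans with ``S_near = 0`` are masked invalid.
    """
    near, far = offsets
    if not 0 <= near < far:
        raise ValueError("offsets must satisfy 0 <= near < far")
    vol = volume.intensities.astype(np.float64)
    # tail[:, r, :] = sum of rows r..bottom
    tail = np.flip(np.cumsum(np.flip(vol, axis=1), axis=1), axis=1)
    depth = vol.shape[1]

    def take(start_rows):
        s = np.clip(start_rows, 0, depth - 1)
        b, a = np.meshgrid(
            np.arange(vol.shape[0]), np.arange(vol.shape[2]), indexing="ij"
        )
        return tail[b, s, a]

    s_near = take(seg.rpe_row - near)
    s_far = take(seg.rpe_row - far)
    valid = s_near > 0
    if seg.valid is not None:
        valid &= seg.valid
    with np.errstate(divide="ignore", invalid="ignore"):
        prr = np.where(valid, s_far / np.where(valid, s_near, 1.0), np.nan)
    return EnFaceMap(
        values=prr, px_per_deg=volume.px_per_deg, units="", mask=valid
    )


def compute_prr_reference(
    volume: OCTVolume,
    seg: SegmentationSet,
    offsets: tuple[int, int] = DEFAULT_PRR_OFFSETS,
) -> EnFaceMap:
    """Plain per-A-scan loop over :func:`cumulative_signal`.

    Independent reference path kept for cross-checking the vectorized map;
    exact agreement is asserted by the test suite.
    """
    near, far = offsets
    n_b, _, n_a = volume.intensities.shape
    prr = np.full((n_b, n_a), np.nan)
    valid = np.zeros((n_b, n_a), dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for b in range(n_b):
            for a in range(n_a):
                asc = volume.intensities[b, :, a]
                r = int(seg.rpe_row[b, a])
                s_near, _ = cumulative_signal(asc, r - near)
                s_far, _ = cumulative_signal(asc, r - far)
                if s_near > 0:
                    prr[b, a] = s_far / s_near
                    valid[b, a] = True
    if seg.valid is not None:
        valid &= seg.valid
        prr[~valid] = np.nan
    return EnFaceMap(
        values=prr, px_per_deg=volume.px_per_deg, units="", mask=valid
    )
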