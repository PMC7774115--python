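"""On-disk formats for synthetic datasets and analysis products.

One directory per eye:

* ``volume.npy`` + ``volume.json`` — raw float32 volume with a text
  header (dims, axial/lateral scales)
* ``blue.png`` / ``green.png`` — 16-bit grayscale FAF pair (a scale
  factor in ``faf.json`` restores physical units)
* ``test_<type>.csv`` — grid coordinates and sensitivities
* ``landmarks_<type>.csv`` — landmark pairs (x_src, y_src, x_dst, y_dst)
* ``truth.json`` / ``truth_<map>.csv`` — retained ground truth

Analysis outputs are CSV (maps, record tables) and JSON (transforms,
normative models).
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .datatypes import EnFaceMap, MicroperimetryTest, OCTVolume, PlanarTransform

_PNG_MAX = 65535


def write_volume(path: Path, volume: OCTVolume) -> None:
    path = Path(path)
    np.save(path.with_suffix(".npy"), volume.intensities)
    header = {
        "shape": list(volume.intensities.shape),
        "dtype": "float32",
        "axial_um_per_px": volume.axial_um_per_px,
        "px_per_deg": volume.px_per_deg,
        "depth_convention": "row0=vitreous",
    }
    path.with_suffix(".json").write_text(json.dumps(header, indent=2))


def read_volume(path: Path) -> OCTVolume:
    path = Path(path)
    header = json.loads(path.with_suffix(".json").read_text())
    data = np.load(path.with_suffix(".npy"))
    return OCTVolume(
        intensities=data,
        axial_um_per_px=header["axial_um_per_px"],
        px_per_deg=header["px_per_deg"],
    )


def write_image_u16(path: Path, image: np.ndarray) -> float:
    """Write a non-negative float image as 16-bit PNG; returns the scale
    factor (physical units per count)."""
    image = np.asarray(image, dtype=float)
    peak = image.max()
    scale = peak / _PNG_MAX if peak > 0 else 1.0
    counts = np.rint(image / scale).astype(np.uint16)
    iio.imwrite(Path(path), counts)
    return scale


def read_image_u16(path: Path, scale: float = 1.0) -> np.ndarray:
    return np.asarray(iio.imread(Path(path)), dtype=float) * scale


def write_map_csv(path: Path, emap: EnFaceMap) -> None:
    np.savetxt(Path(path), emap.values, delimiter=",",
               header=f"px_per_deg={emap.px_per_deg} units={emap.units}")


def read_map_csv(path: Path) -> EnFaceMap:
    path = Path(path)
    header = path.read_text().splitlines()[0].lstrip("# ")
    meta = dict(kv.split("=") for kv in header.split())
    values = np.loadtxt(path, delimiter=",", skiprows=1)
    return EnFaceMap(values=values, px_per_deg=float(meta["px_per_deg"]),
                     units=meta.get("units", ""))


def write_test_csv(path: Path, test: MicroperimetryTest) -> None:
    pd.DataFrame(
        {
            "x_deg": test.points_deg[:, 0],
            "y_deg": test.points_deg[:, 1],
            "sensitivity_db": test.sensitivities_db,
        }
    ).to_csv(Path(path), index=False)
    meta = {
        "test_type": test.test_type,
        "eye_id": test.eye_id,
        "age_years": test.age_years,
    }
    Path(path).with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_test_csv(path: Path) -> MicroperimetryTest:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return MicroperimetryTest(
        test_type=meta["test_type"],
        points_deg=df[["x_deg", "y_deg"]].to_numpy(),
        sensitivities_db=df["sensitivity_db"].to_numpy(),
        eye_id=meta["eye_id"],
        age_years=meta["age_years"],
    )


def write_landmarks_csv(path: Path, src: np.ndarray, dst: np.ndarray) -> None:
    pd.DataFrame(
        {
            "x_src": src[:, 0],
            "y_src": src[:, 1],
            "x_dst": dst[:, 0],
            "y_dst": dst[:, 1],
        }
    ).to_csv(Path(path), index=False)


def read_landmarks_csv(path: Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(Path(path))
    return (
        df[["x_src", "y_src"]].to_numpy(dtype=float),
        df[["x_dst", "y_dst"]].to_numpy(dtype=float),
    )


def write_transform_json(path: Path, transform: PlanarTransform) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "kind": transform.kind,
                "matrix": transform.matrix.tolist(),
                "source": transform.source,
                "target": transform.target,
                "residual_rms_px": transform.residual_rms_px,
            },
            indent=2,
        )
    )


def read_transform_json(path: Path) -> PlanarTransform:
    d = json.loads(Path(path).read_text())
    return PlanarTransform(
        kind=d["kind"],
        matrix=np.asarray(d["matrix"]),
        source=d.get("source", "maia"),
        target=d.get("target", "slo"),
        residual_rms_px=d.get("residual_rms_px", 0.0),
    )


def write_eye_dataset(out_dir: Path, eye) -> None:
    """Write one synthetic eye (``synthetic_data.EyeDataset``) to disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = eye.truth
    if eye.volume is not None:
        write_volume(out / "volume", eye.volume)
        pd.DataFrame(
            {
                "b_scan": np.repeat(
                    np.arange(eye.true_segmentation.rpe_row.shape[0]),
                    eye.true_segmentation.rpe_row.shape[1],
                ),
                "a_scan": np.tile(
                    np.arange(eye.true_segmentation.rpe_row.shape[1]),
                    eye.true_segmentation.rpe_row.shape[0],
                ),
                "ilm_row": eye.true_segmentation.ilm_row.ravel(),
                "rpe_row": eye.true_segmentation.rpe_row.ravel(),
                "bm_row": eye.true_segmentation.bm_row.ravel(),
            }
        ).to_csv(out / "segmentation_true.csv", index=False)
    scales = {}
    scales["blue"] = write_image_u16(out / "blue.png", eye.blue_image)
    scales["green"] = write_image_u16(out / "green.png", eye.green_image)
    (out / "faf.json").write_text(
        json.dumps(
            {"scales": scales,
             "px_per_deg": truth.gaf_true.px_per_deg},
            indent=2,
        )
    )
    for t, test in eye.tests.items():
        write_test_csv(out / f"test_{t}.csv", test)
        src, dst = eye.landmarks[t]
        write_landmarks_csv(out / f"landmarks_{t}.csv", src, dst)
        write_transform_json(
            out / f"transform_true_{t}.json", truth.true_transforms[t]
        )
    for name, emap in (
        ("rpe_elevation", truth.rpe_elevation_true),
        ("prr", truth.prr_true),
        ("gaf", truth.gaf_true),
        ("mpod_ratio", truth.mpod_ratio_true),
    ):
        write_map_csv(out / f"truth_{name}.csv", emap)
    (out / "truth.json").write_text(
        json.dumps(
            {
                "eye_id": truth.eye_id,
                "age_years": truth.age_years,
                "cohort": truth.cohort,
                "random_intercept_db": truth.random_intercept_db,
            },
            indent=2,
        )
    )
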