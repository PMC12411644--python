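"""File formats: TIFF frames with a JSON manifest, fiducial CSV, mask PNG.

Intensity and DOP images travel as 32-bit float TIFFs.  A measurement set is
a directory of single-page TIFFs plus ``manifest.json`` mapping each file to
its (incident, analyzed) state pair.  Fiducial correspondences are a CSV with
columns ``frame,point_id,row,col`` where ``frame`` is ``fluorescence`` or
``polarimetry``.  Masks and outlines are 0/255 PNGs with a JSON provenance
sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .polarimetry import DOPImage, PolarimetricMeasurementSet
from .segmentation import OutlineImage, RegionMask

__all__ = [
    "write_measurement_set",
    "read_measurement_set",
    "write_image",
    "read_image",
    "write_dop_image",
    "read_dop_image",
    "write_fiducials",
    "read_fiducials",
    "write_mask",
    "read_mask",
    "write_json",
    "read_json",
]

MANIFEST_NAME = "manifest.json"


def write_image(path, image: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))


def read_image(path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)), dtype=float)


def write_measurement_set(directory, mset: PolarimetricMeasurementSet, prefix: str = "frame") -> Path:
    """Write one TIFF per frame plus a manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for (inc, ana), img in sorted(mset.frames.items()):
        name = f"{prefix}_{inc}_{ana}.tif"
        write_image(directory / name, img)
        entries.append({"file": name, "incident": inc, "analyzed": ana})
    manifest = {
        "frames": entries,
        "image_shape": list(mset.image_shape),
        "metadata": mset.metadata,
    }
    path = directory / MANIFEST_NAME
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def read_measurement_set(manifest_path) -> PolarimetricMeasurementSet:
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / MANIFEST_NAME
    if not manifest_path.exists():
        raise FileNotFoundError(f"frames manifest not found: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    frames = {}
    cache: dict[str, np.ndarray] = {}
    for entry in manifest["frames"]:
        name = entry["file"]
        if name not in cache:
            cache[name] = read_image(manifest_path.parent / name)
        img = cache[name]
        if "page" in entry:  # multi-page TIFF with declared page order
            img = img[int(entry["page"])]
        frames[(entry["incident"], entry["analyzed"])] = img
    return PolarimetricMeasurementSet(frames=frames, metadata=manifest.get("metadata", {}))


def write_dop_image(path, dop: DOPImage) -> None:
    """Float TIFF plus a ``.json`` sidecar with metric and valid-pixel count."""
    path = Path(path)
    write_image(path, dop.values)
    sidecar = {
        "metric": dop.metric,
        "valid_pixels": int(dop.valid_mask.sum()),
        "flagged_pixels": int(dop.flagged.sum()),
        "convention": "negative = helicity-flipped (circular) / co-linear dominant (linear)",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    write_image(path.with_name(path.stem + "_valid.tif"), dop.valid_mask.astype(np.float32))


def read_dop_image(path) -> DOPImage:
    path = Path(path)
    values = read_image(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    valid_path = path.with_name(path.stem + "_valid.tif")
    valid = read_image(valid_path) > 0.5 if valid_path.exists() else np.ones(values.shape, bool)
    return DOPImage(values=values, metric=sidecar["metric"], valid_mask=valid)


def write_fiducials(path, fiducials_fluor: np.ndarray, fiducials_pol: np.ndarray) -> None:
    rows = []
    for i, (r, c) in enumerate(np.asarray(fiducials_fluor, dtype=float)):
        rows.append({"frame": "fluorescence", "point_id": i, "row": r, "col": c})
    for i, (r, c) in enumerate(np.asarray(fiducials_pol, dtype=float)):
        rows.append({"frame": "polarimetry", "point_id": i, "row": r, "col": c})
    pd.DataFrame(rows, columns=["frame", "point_id", "row", "col"]).to_csv(path, index=False)


def read_fiducials(path) -> tuple[np.ndarray, np.ndarray]:
    """Return matched (fluorescence, polarimetry) point arrays sorted by id."""
    df = pd.read_csv(path)
    required = {"frame", "point_id", "row", "col"}
    if not required.issubset(df.columns):
        raise ValueError(f"fiducial CSV must have columns {sorted(required)}")
    out = []
    for frame in ("fluorescence", "polarimetry"):
        sub = df[df["frame"] == frame].sort_values("point_id")
        out.append(sub[["row", "col"]].to_numpy(dtype=float))
    fluor, pol = out
    if len(fluor) != len(pol) or len(fluor) == 0:
        raise ValueError("fiducial CSV must contain matched fluorescence/polarimetry points")
    return fluor, pol


def write_mask(path, obj) -> None:
    path = Path(path)
    if isinstance(obj, RegionMask):
        data, meta = obj.mask, {"kind": "mask", "frame": obj.frame, "threshold_fraction": obj.threshold_fraction}
    elif isinstance(obj, OutlineImage):
        data, meta = obj.outline, {"kind": "outline", "frame": obj.frame, "thickness": obj.thickness}
    else:
        raise TypeError(f"expected RegionMask or OutlineImage, got {type(obj).__name__}")
    iio.imwrite(path, (data.astype(np.uint8) * 255))
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_mask(path):
    path = Path(path)
    data = np.asarray(iio.imread(path)) > 127
    meta = json.loads(path.with_suffix(".json").read_text())
    if meta.get("kind") == "outline":
        return OutlineImage(outline=data, thickness=int(meta["thickness"]), frame=meta.get("frame", "polarimetry"))
    return RegionMask(mask=data, frame=meta.get("frame", "polarimetry"), threshold_fraction=meta.get("threshold_fraction"))


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
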