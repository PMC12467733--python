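"""Reading and writing of pipeline artifacts.

Radiographs travel as 16-bit PNG images with a JSON sidecar carrying the
physical metadata (pixel spacing, acquisition geometry, provenance);
detections, ROIs, calibrations and measurements use small tidy CSVs so every
pipeline stage can be run standalone on the previous stage's output.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .calibration import DistanceMeasurement, PlaneCalibration
from .detection import DetectedBead, RegionOfInterest
from .projection import AcquisitionGeometry, Radiograph

__all__ = [
    "save_radiograph", "load_radiograph",
    "save_ct_volume", "load_ct_volume",
    "save_detections", "load_detections",
    "save_rois", "load_rois",
    "save_measurements", "save_calibrations",
]

_INT16_MAX = 65535


def save_radiograph(rad: Radiograph, path) -> Path:
    """Write a 16-bit PNG plus a ``.json`` sidecar next to it."""
    path = Path(path)
    lo, hi = float(rad.image.min()), float(rad.image.max())
    scale = (hi - lo) or 1.0
    quantized = np.round((rad.image - lo) / scale * _INT16_MAX).astype(np.uint16)
    Image.fromarray(quantized).save(path)
    sidecar = {
        "pixel_spacing": rad.pixel_spacing,
        "geometry": dataclasses.asdict(rad.geometry),
        "provenance": rad.provenance,
        "meta": rad.meta,
        "intensity_window": [lo, hi],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def load_radiograph(path) -> Radiograph:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    lo, hi = sidecar["intensity_window"]
    raw = np.asarray(Image.open(path), dtype=np.float32)
    image = raw / _INT16_MAX * (hi - lo) + lo
    geo = sidecar["geometry"]
    geo["detector_size"] = tuple(geo["detector_size"])
    return Radiograph(
        image=image,
        pixel_spacing=sidecar["pixel_spacing"],
        geometry=AcquisitionGeometry(**geo),
        provenance=sidecar.get("provenance", {}),
        meta=sidecar.get("meta", {}),
    )


def save_ct_volume(volume, path) -> Path:
    """Write a CtVolume as NIfTI; spacing goes into the affine diagonal and
    the origin into the translation column."""
    import nibabel as nib

    path = Path(path)
    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32),
                             affine), path)
    return path


def load_ct_volume(path):
    import nibabel as nib

    from .phantom import CtVolume

    img = nib.load(str(path))
    affine = img.affine
    return CtVolume(
        data=np.asarray(img.dataobj, dtype=np.float32),
        spacing=tuple(float(affine[i, i]) for i in range(3)),
        origin=tuple(float(affine[i, 3]) for i in range(3)),
    )


def save_rois(rois, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [(r.label, r.row, r.col, r.height, r.width) for r in rois],
        columns=["label", "row", "col", "height", "width"],
    ).to_csv(path, index=False)
    return path


def load_rois(path) -> list[RegionOfInterest]:
    df = pd.read_csv(path)
    return [RegionOfInterest(r.label, int(r.row), int(r.col),
                             int(r.height), int(r.width))
            for r in df.itertuples()]


def save_detections(beads, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [(b.label, b.center[0], b.center[1], b.diameter_px, b.metric)
         for b in beads],
        columns=["label", "center_row", "center_col", "diameter_px", "metric"],
    ).to_csv(path, index=False)
    return path


def load_detections(path) -> list[DetectedBead]:
    df = pd.read_csv(path)
    return [DetectedBead(r.label, (float(r.center_row), float(r.center_col)),
                         float(r.diameter_px), float(r.metric))
            for r in df.itertuples()]


def save_measurements(measurements: list[DistanceMeasurement], path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [(m.pair.name, m.plane_id, m.l_pixel, m.epsilon, m.l_mm)
         for m in measurements],
        columns=["pair", "plane", "l_pixel", "epsilon", "l_mm"],
    ).to_csv(path, index=False)
    return path


def save_calibrations(calibrations: dict[int, PlaneCalibration], path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [(c.plane_id, c.mean_diameter_mm, c.epsilon)
         for c in calibrations.values()],
        columns=["plane", "mean_diameter_mm", "epsilon"],
    ).to_csv(path, index=False)
    return path
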