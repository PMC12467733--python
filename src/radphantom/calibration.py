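"""Plane-wise magnification calibration with fiducial beads.

The imaged diameter of a steel bead of true diameter R* (caliper, 8.00 mm)
is R_image = R_pixel x spacing.  Because the seven beads sit on two coronal
planes at different depths, each plane gets its own calibration coefficient

    epsilon_i = mean(R_image over the plane's beads) / R*,

and a pixel distance l_pixel measured between two markers of plane i is
converted to millimetres as

    l = l_pixel x spacing / epsilon_i.

Dividing by epsilon removes the depth-dependent projective magnification;
the construction is exactly invariant under a uniform rescaling of the
acquisition (scaling all pixel coordinates and diameters by c leaves every
corrected distance unchanged).  Cross-plane distances are deliberately out
of contract: no epsilon is defined for them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detection import DetectedBead
from .phantom import MarkerPair, PLANE_OF_LABEL, canonical_pairs

__all__ = [
    "PlaneCalibration",
    "DistanceMeasurement",
    "CalibrationError",
    "bead_diameter_mm",
    "plane_epsilon",
    "corrected_distance",
    "measure_pairs",
]


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class PlaneCalibration:
    """Calibration coefficient epsilon for one bead plane."""

    plane_id: int
    mean_diameter_mm: float
    epsilon: float
    labels: tuple[str, ...] = ()

    def __post_init__(self):
        if self.epsilon <= 0:
            raise CalibrationError("epsilon must be positive")


@dataclass(frozen=True)
class DistanceMeasurement:
    """One corrected inter-marker distance."""

    pair: MarkerPair
    l_pixel: float
    l_mm: float
    plane_id: int
    epsilon: float


def bead_diameter_mm(r_pixel: float, spacing: float) -> float:
    """Imaged bead diameter in mm: R_image = R_pixel x spacing."""
    if r_pixel <= 0 or spacing <= 0:
        raise CalibrationError("r_pixel and spacing must be positive")
    return r_pixel * spacing


def plane_epsilon(diameters_mm, r_star: float = 8.0,
                  plane_id: int = 0, labels=()) -> PlaneCalibration:
    """epsilon = mean imaged diameter of the plane's beads / true diameter."""
    diameters = [float(d) for d in diameters_mm]
    if not diameters:
        raise CalibrationError("need at least one bead diameter")
    if r_star <= 0:
        raise CalibrationError("r_star must be positive")
    mean_d = float(np.mean(diameters))
    return PlaneCalibration(
        plane_id=plane_id,
        mean_diameter_mm=mean_d,
        epsilon=mean_d / r_star,
        labels=tuple(labels),
    )


def corrected_distance(l_pixel: float, spacing: float, epsilon: float) -> float:
    """l = l_pixel x spacing / epsilon."""
    if l_pixel <= 0 or spacing <= 0:
        raise CalibrationError("l_pixel and spacing must be positive")
    if epsilon <= 0:
        raise CalibrationError("epsilon must be positive")
    return l_pixel * spacing / epsilon


def measure_pairs(
    detections,
    spacing: float,
    r_star: float = 8.0,
    plane_of_label: dict[str, int] | None = None,
) -> tuple[list[DistanceMeasurement], dict[int, PlaneCalibration]]:
    """Calibrate both planes from detected bead diameters and measure all
    nine within-plane marker distances.

    ``detections`` is an iterable of :class:`DetectedBead` covering all
    seven markers.  Returns the corrected measurements together with the two
    :class:`PlaneCalibration` objects actually used.
    """
    planes = plane_of_label or PLANE_OF_LABEL
    beads: dict[str, DetectedBead] = {}
    for det in detections:
        beads[det.label] = det
    missing = [lab for lab in planes if lab not in beads]
    if missing:
        raise CalibrationError(f"missing detections for markers {missing}")

    calibrations: dict[int, PlaneCalibration] = {}
    for plane in sorted(set(planes.values())):
        labs = [lab for lab, p in planes.items() if p == plane]
        dias = [bead_diameter_mm(beads[lab].diameter_px, spacing) for lab in labs]
        calibrations[plane] = plane_epsilon(dias, r_star=r_star,
                                            plane_id=plane, labels=labs)

    measurements = []
    for pair in canonical_pairs():
        if planes[pair.a] != planes[pair.b]:
            raise CalibrationError(
                f"pair {pair} spans planes; cross-plane distances are out "
                "of contract"
            )
        ca = np.asarray(beads[pair.a].center)
        cb = np.asarray(beads[pair.b].center)
        l_pixel = float(np.linalg.norm(ca - cb))
        eps = calibrations[planes[pair.a]].epsilon
        measurements.append(DistanceMeasurement(
            pair=pair,
            l_pixel=l_pixel,
            l_mm=corrected_distance(l_pixel, spacing, eps),
            plane_id=planes[pair.a],
            epsilon=eps,
        ))
    return measurements, calibrations
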