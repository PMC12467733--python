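"""Fiducial-bead detection on radiographs.

Each steel bead is localized inside a user-supplied region of interest by
Canny edge detection followed by a circular Hough transform; the highest-vote
accumulator peak gives the circle, refined to sub-pixel precision by a
3-point parabolic fit per axis.  Alongside center and pixel diameter, every
detection carries a circularity metric — the fraction of accumulator votes
supporting the detected circle — which degrades under geometric distortion
and therefore serves as a local image-quality indicator.

Vote normalization: the accumulator value at a cell counts the edge points
consistent with that (center, radius); "total votes" is taken as the
per-radius vote mass divided by the circle perimeter length (an effective
edge-point count), either at the detected radius alone or averaged over the
searched radius range (``total_votes='single_radius'`` /
``'radius_marginal'``).  Both reduce to 1.0 for a clean, fully supported
circle; absolute values on real vendor images depend on this choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.draw import circle_perimeter
from skimage.feature import canny
from skimage.filters import sobel, threshold_otsu
from skimage.transform import hough_circle

__all__ = [
    "RegionOfInterest",
    "DetectedBead",
    "DetectionError",
    "NoBeadFoundError",
    "detect_bead",
    "circularity_metric",
    "summarize_metrics",
]


class DetectionError(ValueError):
    pass


class NoBeadFoundError(DetectionError):
    """No accumulator peak above threshold inside the ROI."""

    def __init__(self, label):
        self.label = label
        super().__init__(f"no bead found in ROI {label!r}")


@dataclass(frozen=True)
class RegionOfInterest:
    """Axis-aligned search box for one expected bead."""

    label: str
    row: int
    col: int
    height: int
    width: int

    def validate(self, image_shape):
        h, w = image_shape
        if self.height <= 0 or self.width <= 0:
            raise DetectionError(f"ROI {self.label}: empty box")
        if (self.row < 0 or self.col < 0
                or self.row + self.height > h or self.col + self.width > w):
            raise DetectionError(f"ROI {self.label} exceeds image bounds")

    @classmethod
    def around(cls, label, center_rc, half_size, image_shape):
        """Square ROI centered on ``center_rc``, clipped to the image."""
        h, w = image_shape
        r0 = int(np.clip(round(center_rc[0] - half_size), 0, h - 1))
        c0 = int(np.clip(round(center_rc[1] - half_size), 0, w - 1))
        r1 = int(np.clip(round(center_rc[0] + half_size), 1, h))
        c1 = int(np.clip(round(center_rc[1] + half_size), 1, w))
        return cls(label, r0, c0, r1 - r0, c1 - c0)


@dataclass(frozen=True)
class DetectedBead:
    label: str
    center: tuple[float, float]   # (row, col), sub-pixel, full-image coords
    diameter_px: float
    metric: float

    def __post_init__(self):
        if self.diameter_px <= 0:
            raise DetectionError("diameter_px must be positive")
        if not (0.0 <= self.metric <= 1.0):
            raise DetectionError("circularity metric must lie in [0, 1]")


def circularity_metric(votes_for_circle: float, total_votes: float) -> float:
    """Votes for the detected circle over the total accumulator votes."""
    if total_votes <= 0:
        raise DetectionError("total_votes must be positive")
    if votes_for_circle < 0 or votes_for_circle > total_votes:
        raise DetectionError("need 0 <= votes_for_circle <= total_votes")
    return float(votes_for_circle) / float(total_votes)


def _parabolic_offset(y0, y1, y2):
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:
        return 0.0
    return float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))


def _perimeter_length(radius: int) -> int:
    rr, _ = circle_perimeter(0, 0, int(radius))
    return len(rr)


def _refine_circle(crop, row, col, radius, n_angles=96, n_iter=2):
    """Sub-pixel circle refinement from radial intensity profiles.

    The Hough peak seeds the fit; for each of ``n_angles`` directions the
    half-contrast crossing of the bilinearly interpolated radial profile
    gives a sub-pixel edge point, and an algebraic circle fit to those
    points updates center and radius.  On a rendered disk the anti-aliased
    boundary crosses half intensity exactly at the true radius, so the
    refined estimate is limited only by interpolation error.
    """
    h, w = crop.shape
    theta = np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)
    for _ in range(n_iter):
        rho = np.arange(max(radius * 0.4, 1.0), radius * 1.6, 0.25)
        rr = row + np.outer(np.cos(theta), rho)
        cc = col + np.outer(np.sin(theta), rho)
        inside = ((rr >= 0) & (rr <= h - 1) & (cc >= 0) & (cc <= w - 1))
        prof = map_coordinates(crop, [rr.ravel(), cc.ravel()], order=1,
                               mode="nearest").reshape(rr.shape)
        level = 0.5 * (prof.max() + prof.min())
        pts = []
        for j in range(n_angles):
            if not inside[j].all():
                continue
            p = prof[j]
            above = p >= level
            if not (above[0] and not above[-1]):
                continue
            k = int(np.argmax(~above))  # first sample below the level
            frac = (p[k - 1] - level) / (p[k - 1] - p[k])
            r_edge = rho[k - 1] + frac * (rho[k] - rho[k - 1])
            pts.append((row + r_edge * np.cos(theta[j]),
                        col + r_edge * np.sin(theta[j])))
        if len(pts) < n_angles // 2:
            return row, col, radius  # too occluded to refine; keep Hough
        pts = np.asarray(pts)
        # algebraic circle fit: |p|^2 = 2 c.p + (r^2 - |c|^2)
        a = np.hstack([2.0 * pts, np.ones((len(pts), 1))])
        b = (pts**2).sum(axis=1)
        sol, *_ = np.linalg.lstsq(a, b, rcond=None)
        row, col = float(sol[0]), float(sol[1])
        r2 = sol[2] + sol[0] ** 2 + sol[1] ** 2
        if r2 <= 0:
            return row, col, radius
        radius = float(np.sqrt(r2))
    return row, col, radius


def detect_bead(
    image: np.ndarray,
    roi: RegionOfInterest,
    radius_range: tuple[float, float],
    canny_sigma: float = 1.5,
    low_high_ratio: float = 0.4,
    vote_threshold_fraction: float = 0.2,
    total_votes: str = "single_radius",
    refine: bool = True,
) -> DetectedBead:
    """Detect the bead inside ``roi`` and score its circularity.

    ``radius_range`` is the (min, max) Hough radius in pixels — typically
    +/-30% around the projected radius implied by the acquisition geometry.
    Canny thresholds default to an Otsu-derived high threshold on the
    gradient magnitude with low = 0.4 x high.  The highest-vote circle wins;
    near-equal peaks break deterministically toward the smaller radius, then
    scan order.  The accumulator peak is interpolated to sub-pixel precision
    by a 3-point parabola per axis and, with ``refine`` (default), polished
    by a radial-profile circle fit (:func:`_refine_circle`), which removes
    the Hough radius quantization bias.  A peak supported by fewer than
    ``vote_threshold_fraction`` of its perimeter raises
    :class:`NoBeadFoundError`.
    """
    roi.validate(image.shape)
    rmin, rmax = (int(np.floor(radius_range[0])), int(np.ceil(radius_range[1])))
    if rmin <= 0 or rmin >= rmax:
        raise DetectionError("radius_range must be positive with min < max")
    if roi.height < 2 * rmax or roi.width < 2 * rmax:
        raise DetectionError(
            f"ROI {roi.label} ({roi.height}x{roi.width}) is smaller than "
            f"twice the maximum search radius {rmax}"
        )
    if total_votes not in ("single_radius", "radius_marginal"):
        raise DetectionError(f"unknown total_votes mode {total_votes!r}")

    crop = np.asarray(image, dtype=float)[
        roi.row:roi.row + roi.height, roi.col:roi.col + roi.width
    ]
    gmag = sobel(crop)
    if gmag.max() <= 0:
        raise NoBeadFoundError(roi.label)
    high = threshold_otsu(gmag)
    edges = canny(crop, sigma=canny_sigma,
                  low_threshold=low_high_ratio * high, high_threshold=high)
    if not edges.any():
        raise NoBeadFoundError(roi.label)

    radii = np.arange(rmin, rmax + 1)
    acc = hough_circle(edges, radii, normalize=False).astype(float)
    flat_idx = int(np.argmax(acc))  # C order: smaller radius, then scan order
    ri, pr, pc = np.unravel_index(flat_idx, acc.shape)
    peak = acc[ri, pr, pc]
    perim = _perimeter_length(radii[ri])
    if peak < vote_threshold_fraction * perim:
        raise NoBeadFoundError(roi.label)

    # sub-pixel refinement, 3-point parabola per axis (center and radius)
    row = float(pr)
    if 0 < pr < acc.shape[1] - 1:
        row += _parabolic_offset(acc[ri, pr - 1, pc], peak, acc[ri, pr + 1, pc])
    col = float(pc)
    if 0 < pc < acc.shape[2] - 1:
        col += _parabolic_offset(acc[ri, pr, pc - 1], peak, acc[ri, pr, pc + 1])
    radius = float(radii[ri])
    if 0 < ri < acc.shape[0] - 1:
        radius += _parabolic_offset(acc[ri - 1, pr, pc], peak, acc[ri + 1, pr, pc])
    if refine:
        row, col, radius = _refine_circle(crop, row, col, radius)

    # vote normalization: effective edge-point counts (see module docstring)
    per_radius_mass = np.array(
        [acc[i].sum() / _perimeter_length(r) for i, r in enumerate(radii)]
    )
    if total_votes == "single_radius":
        total = per_radius_mass[ri]
    else:
        total = per_radius_mass.mean()
    metric = min(circularity_metric(min(peak, total), total), 1.0)

    return DetectedBead(
        label=roi.label,
        center=(roi.row + row, roi.col + col),
        diameter_px=2.0 * radius,
        metric=metric,
    )


def summarize_metrics(beads) -> tuple[float, float]:
    """Mean and population standard deviation (divide by n) of the
    circularity metrics — the summary convention used for per-system
    circularity tables."""
    values = [b.metric if isinstance(b, DetectedBead) else float(b)
              for b in beads]
    if len(values) < 2:
        raise DetectionError("need at least 2 beads to summarize")
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=0))
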