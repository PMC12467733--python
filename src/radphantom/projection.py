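"""Forward models of the three full-length acquisition geometries.

World coordinates are (x, y, z) in mm: x transverse, y depth along the beam
measured from the X-ray focal spot, z longitudinal (cranio-caudal).  The
detector is the plane y = sid; pixel (row, col) = (0, 0) is the top-left
corner, the principal point sits at the detector center, rows run
longitudinal and columns transverse.

Three modalities are modelled:

``one_shot``
    A single cone-beam exposure: perspective projection from the focal spot,
    every coordinate magnified by sid / depth.

``slot``
    A narrow collimated beam translating synchronously with the detector.
    On the raw analytic path (:func:`project_slot`) the scan direction is a
    quasi-parallel projection — longitudinal coordinates are preserved at
    unit magnification while transverse coordinates are magnified by
    sid / depth.  Rendered slot radiographs model the image *after* the
    scanner's scan-speed/scale rectification (every measured image in this
    workflow has passed the manufacturer's geometric protocol), which brings
    the longitudinal scale to the same per-depth magnification as the
    transverse axis, leaving a locally isotropic image.

``rotational``
    Multi-exposure stitching: the central ray rotates toward each segment's
    longitudinal midpoint while the detector translates.  Each sub-exposure
    is tilt-rectified about its own central ray, so content keeps the local
    cone-beam scale sid / depth *within* a segment, but the assembly pastes
    the segments at their mechanically calibrated spacing — which is length
    -true at the nominal object plane (scale sid / sod) — and the
    translation-only overlap registration recovers only part of the
    resulting parallax (``registration_gain``), optionally with seeded
    jitter.  For a phantom nearer the source than the object plane the
    stitched longitudinal scale therefore falls between sid / sod and the
    cone-beam sid / depth: inter-segment distances are systematically
    *under*-estimated relative to a single cone-beam exposure, while the
    bead diameters (hence the calibration coefficient) carry the full local
    magnification — the stitching bias mechanism.

Beads are rendered as anti-aliased filled disks of diameter
R* x magnification; the slight ellipticity of an off-axis sphere shadow is
ignored (sub-pixel at these geometries).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .phantom import PhantomLayout

__all__ = [
    "AcquisitionGeometry",
    "NoiseModel",
    "Radiograph",
    "ProjectionError",
    "project_one_shot",
    "project_slot",
    "rotational_segment_map",
    "simulate_rotational",
    "render",
    "world_positions",
]

MODALITIES = ("slot", "one_shot", "rotational")


class ProjectionError(ValueError):
    """Geometry or projection-domain error."""


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Source/detector geometry of one acquisition.

    sid and sod are the source-to-image and source-to-object distances in mm
    and must satisfy sid > sod > 0.  detector_size is (rows, cols) in pixels;
    rows are longitudinal.  ``segments`` and ``overlap_fraction`` apply to
    the rotational modality only, ``slot_width`` to slot scanning.
    """

    modality: str
    sid: float
    sod: float
    pixel_spacing: float
    detector_size: tuple[int, int]
    segments: int | None = None
    overlap_fraction: float | None = None
    slot_width: float | None = None
    #: depth offset (mm) of the phantom midplane in front of the nominal
    #: object plane; per-system values are inferred from the published bead
    #: magnifications (epsilon as large as 1.25 against sid/sod ~ 1.09 means
    #: the beads sat well source-ward of sod)
    object_offset: float = 0.0

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ProjectionError(f"unknown modality {self.modality!r}")
        if not (self.sid > self.sod > 0):
            raise ProjectionError(
                f"need sid > sod > 0, got sid={self.sid}, sod={self.sod}"
            )
        if self.pixel_spacing <= 0:
            raise ProjectionError("pixel_spacing must be positive")
        if any(int(s) <= 0 for s in self.detector_size):
            raise ProjectionError("detector_size must be positive")
        if self.modality == "rotational":
            if self.segments is None or self.segments < 2:
                raise ProjectionError("rotational needs segments >= 2")
            ov = 0.0 if self.overlap_fraction is None else self.overlap_fraction
            if not (0.0 <= ov < 1.0):
                raise ProjectionError("overlap_fraction must be in [0, 1)")

    @property
    def principal_point(self) -> tuple[float, float]:
        h, w = self.detector_size
        return ((h - 1) / 2.0, (w - 1) / 2.0)

    @classmethod
    def from_preset(cls, name: str, downsample: float = 1.0) -> "AcquisitionGeometry":
        """Load a named system preset, optionally coarsening the detector
        grid by ``downsample`` (spacing multiplied, pixel counts divided)."""
        from .datasets import load_geometry_presets

        presets = load_geometry_presets()
        if name not in presets:
            raise ProjectionError(
                f"unknown geometry preset {name!r}; available: {sorted(presets)}"
            )
        p = dict(presets[name])
        rows, cols = p.pop("detector_size")
        return cls(
            detector_size=(int(round(rows / downsample)), int(round(cols / downsample))),
            pixel_spacing=p.pop("pixel_spacing") * downsample,
            **p,
        )


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian intensity noise and Gaussian blur, seeded."""

    gaussian_sigma: float = 0.0
    blur_sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.gaussian_sigma < 0 or self.blur_sigma < 0:
            raise ProjectionError("noise sigmas must be >= 0")
        if self.gaussian_sigma > 0 and self.seed is None:
            raise ProjectionError("a seed is required when gaussian_sigma > 0")

    def apply(self, image: np.ndarray) -> np.ndarray:
        out = image
        if self.blur_sigma > 0:
            out = ndimage.gaussian_filter(out, self.blur_sigma)
        if self.gaussian_sigma > 0:
            rng = np.random.default_rng(self.seed)
            out = out + rng.normal(0.0, self.gaussian_sigma, size=out.shape)
        return out.astype(np.float32)


@dataclass
class Radiograph:
    """Rendered 2-D image plus acquisition metadata and ground truth.

    ``provenance`` maps each marker label to its true post-render center
    (pixels, row/col), projected diameter (pixels) and magnification; it is
    retained so detection and calibration can be validated against the
    simulation's own ground truth.
    """

    image: np.ndarray
    pixel_spacing: float
    geometry: AcquisitionGeometry
    provenance: dict[str, dict] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# analytic projections
# ---------------------------------------------------------------------------

def _check_point(point, geometry) -> np.ndarray:
    p = np.asarray(point, dtype=float)
    if p.shape != (3,):
        raise ProjectionError("point must be a 3-vector (x, y, z) in mm")
    if p[1] <= 0:
        raise ProjectionError(f"point {tuple(p)} is at or behind the source")
    if p[1] > geometry.sid:
        raise ProjectionError(f"point {tuple(p)} lies behind the detector plane")
    return p


def _to_pixels(u_mm: float, v_mm: float, geometry) -> tuple[float, float]:
    r0, c0 = geometry.principal_point
    row = r0 + v_mm / geometry.pixel_spacing
    col = c0 + u_mm / geometry.pixel_spacing
    h, w = geometry.detector_size
    if not (0 <= row <= h - 1 and 0 <= col <= w - 1):
        raise ProjectionError(
            f"projection ({row:.1f}, {col:.1f}) px falls off the "
            f"{h}x{w} detector"
        )
    return (row, col)


def project_one_shot(point, geometry: AcquisitionGeometry):
    """Perspective (cone-beam) projection of a world point.

    Returns ``((row, col), magnification)`` with magnification = sid / depth;
    image-plane offsets are object-plane offsets times the magnification.
    """
    p = _check_point(point, geometry)
    mag = geometry.sid / p[1]
    center = _to_pixels(p[0] * mag, p[2] * mag, geometry)
    return center, mag


def project_slot(point, geometry: AcquisitionGeometry):
    """Raw slot-scan projection: the longitudinal (scan) coordinate is
    preserved at unit magnification, the transverse coordinate is magnified
    by sid / depth.  Returns ``((row, col), transverse_magnification)``."""
    p = _check_point(point, geometry)
    mag_t = geometry.sid / p[1]
    center = _to_pixels(p[0] * mag_t, p[2], geometry)
    return center, mag_t


def rotational_segment_map(point, geometry: AcquisitionGeometry, m_k: float):
    """Map a world point through one rotational sub-exposure.

    ``m_k`` is the segment's longitudinal midpoint at the object plane
    (depth = sod), through which the tilted central ray passes.  The
    tilt-rectified sub-exposure keeps the local cone-beam scale about its
    central ray, and the segment is pasted at its mechanically calibrated
    panorama position m_k * sid / sod, so the longitudinal image-plane
    coordinate of (x, y, z) is

        v = m_k * sid / sod + (z - m_k) * sid / y.

    The transverse coordinate and the rendered bead diameter keep the plain
    cone-beam magnification sid / y.  Returns ``((row, col), magnification)``.
    """
    p = _check_point(point, geometry)
    sod, sid = geometry.sod, geometry.sid
    mag = sid / p[1]
    v_mm = m_k * sid / sod + (p[2] - m_k) * mag
    center = _to_pixels(p[0] * mag, v_mm, geometry)
    return center, mag


def world_positions(layout: PhantomLayout, geometry: AcquisitionGeometry) -> dict[str, np.ndarray]:
    """Pose the phantom in front of the detector: the midpoint of the two
    bead planes is placed ``geometry.object_offset`` mm source-ward of the
    nominal object depth sod, plane 1 nearer the source; the layout's
    transverse/longitudinal coordinates are used as-is (they are centered
    by construction)."""
    mid = (layout.plane_depth(1) + layout.plane_depth(2)) / 2.0
    depth0 = geometry.sod - geometry.object_offset
    if depth0 - abs(layout.plane_separation) / 2.0 <= 0:
        raise ProjectionError("phantom placed at or behind the source")
    out = {}
    for lab, lm in layout.landmarks.items():
        x, d, z = lm.position
        out[lab] = np.array([x, depth0 + (d - mid), z])
    return out


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _draw_disk(image, row, col, radius_px, background, contrast,
               row_range=None):
    """Composite an anti-aliased disk; the half-intensity contour sits at
    ``radius_px`` from the center.  ``row_range`` clips the drawing to a
    sub-exposure strip."""
    h, w = image.shape
    r0 = max(int(np.floor(row - radius_px - 2)), 0)
    r1 = min(int(np.ceil(row + radius_px + 2)) + 1, h)
    c0 = max(int(np.floor(col - radius_px - 2)), 0)
    c1 = min(int(np.ceil(col + radius_px + 2)) + 1, w)
    if row_range is not None:
        r0 = max(r0, row_range[0])
        r1 = min(r1, row_range[1])
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1)[:, None] - row
    cc = np.arange(c0, c1)[None, :] - col
    dist = np.hypot(rr, cc)
    coverage = np.clip(radius_px + 0.5 - dist, 0.0, 1.0)
    patch = background + contrast * coverage
    np.maximum(image[r0:r1, c0:c1], patch, out=image[r0:r1, c0:c1])


def _check_disk_on_detector(label, row, col, radius_px, geometry):
    h, w = geometry.detector_size
    if (row - radius_px < 0 or row + radius_px > h - 1
            or col - radius_px < 0 or col + radius_px > w - 1):
        raise ProjectionError(
            f"bead {label} (center ({row:.1f}, {col:.1f}), radius "
            f"{radius_px:.1f} px) extends off the detector"
        )


def render(
    layout: PhantomLayout,
    geometry: AcquisitionGeometry,
    noise: NoiseModel | None = None,
    background: float = 0.1,
    contrast: float = 0.8,
    registration_error_sigma: float = 0.0,
    seed: int | None = None,
) -> Radiograph:
    """Render a full-length radiograph of the bead layout.

    slot and one_shot images map each bead isotropically at its own depth
    magnification sid / y (for slot this is the post-rectification image,
    see the module docstring); rotational delegates to
    :func:`simulate_rotational`.  Beads are drawn as anti-aliased disks of
    diameter R* x magnification / pixel_spacing on a uniform background.
    """
    if geometry.modality == "rotational":
        return simulate_rotational(
            layout, geometry,
            registration_error_sigma=registration_error_sigma,
            seed=seed, noise=noise,
            background=background, contrast=contrast,
        )

    pos = world_positions(layout, geometry)
    h, w = geometry.detector_size
    image = np.full((h, w), background, dtype=np.float32)
    provenance = {}
    for lab, p in pos.items():
        if geometry.modality == "one_shot":
            (row, col), mag = project_one_shot(p, geometry)
        else:  # slot: rectified longitudinal scale matches transverse
            (_, col), mag = project_slot(p, geometry)
            row = geometry.principal_point[0] + p[2] * mag / geometry.pixel_spacing
        diameter_px = layout.bead_diameter_true * mag / geometry.pixel_spacing
        _check_disk_on_detector(lab, row, col, diameter_px / 2, geometry)
        _draw_disk(image, row, col, diameter_px / 2, background, contrast)
        provenance[lab] = {
            "center_px": (float(row), float(col)),
            "diameter_px": float(diameter_px),
            "magnification": float(mag),
        }
    if noise is not None:
        image = noise.apply(image)
    return Radiograph(image=image, pixel_spacing=geometry.pixel_spacing,
                      geometry=geometry, provenance=provenance)


# ---------------------------------------------------------------------------
# rotational stitching simulation
# ---------------------------------------------------------------------------

def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a.ravel() @ b.ravel() / denom) if denom > 0 else 0.0


def simulate_rotational(
    layout: PhantomLayout,
    geometry: AcquisitionGeometry,
    registration_error_sigma: float = 0.0,
    seed: int | None = None,
    noise: NoiseModel | None = None,
    background: float = 0.1,
    contrast: float = 0.8,
    max_shift_px: int = 12,
    registration_gain: float = 0.5,
) -> Radiograph:
    """Render a stitched rotational acquisition.

    Each of the ``geometry.segments`` sub-exposures is a cone-beam strip
    tilt-rectified about its central ray and pasted at its mechanically
    calibrated panorama position (see :func:`rotational_segment_map`).
    Successive segments are then refined by the 1-D longitudinal
    translation that maximizes normalized cross-correlation over the
    overlap strip; a featureless overlap (the bead-only render has no soft
    tissue for the correlator to lock onto) falls back to the analytic
    parallax of the phantom mid-depth plane — what the real registration
    would measure from the anatomy — and is flagged in
    ``meta['unregistered_segments']``.

    ``registration_gain`` in [0, 1] is the fraction of the measured
    parallax the assembly actually applies: real stitchers regularize the
    content-based shift toward the mechanical prior, which is what leaves
    the panorama's longitudinal scale between the object-plane scale
    sid/sod and the content's cone scale sid/depth.
    ``registration_error_sigma`` adds seeded Gaussian jitter (pixels) to
    every applied shift.

    Provenance records the post-stitch bead centers, so the stitching bias
    (longitudinal compression relative to a single cone-beam exposure when
    the phantom sits nearer the source than the object plane) is directly
    measurable.
    """
    if geometry.modality != "rotational":
        raise ProjectionError("simulate_rotational needs a rotational geometry")
    if registration_error_sigma < 0:
        raise ProjectionError("registration_error_sigma must be >= 0")
    if registration_error_sigma > 0 and seed is None:
        raise ProjectionError("a seed is required when registration_error_sigma > 0")
    rng = np.random.default_rng(seed)

    pos = world_positions(layout, geometry)
    h, w = geometry.detector_size
    n_seg = int(geometry.segments)
    ov_frac = geometry.overlap_fraction or 0.0
    h_core = h / n_seg
    n_ov = int(round(ov_frac * h_core))

    # segment row ranges on the common grid and object-plane midpoints
    ranges, mids = [], []
    r_pp = geometry.principal_point[0]
    for k in range(n_seg):
        r0 = int(round(k * h_core)) - (n_ov if k > 0 else 0)
        r1 = int(round((k + 1) * h_core))
        ranges.append((max(r0, 0), min(r1, h)))
        core_center = (k + 0.5) * h_core
        mids.append((core_center - r_pp) * geometry.pixel_spacing
                    * geometry.sod / geometry.sid)

    # per-segment mapped bead positions
    seg_beads: list[dict[str, tuple[float, float, float]]] = []
    for m_k in mids:
        mapped = {}
        for lab, p in pos.items():
            (row, col), mag = rotational_segment_map(p, geometry, m_k)
            mapped[lab] = (row, col, layout.bead_diameter_true * mag
                           / geometry.pixel_spacing)
        seg_beads.append(mapped)

    # render each sub-exposure on the common grid, clipped to its strip
    seg_images = []
    for k, (r0, r1) in enumerate(ranges):
        img = np.full((h, w), background, dtype=np.float32)
        for lab, (row, col, dia) in seg_beads[k].items():
            _draw_disk(img, row, col, dia / 2, background, contrast,
                       row_range=(r0, r1))
        seg_images.append(img)

    if not 0.0 <= registration_gain <= 1.0:
        raise ProjectionError("registration_gain must be in [0, 1]")

    # analytic registration fallback: the parallax between two adjacent
    # segments' renderings of content at the phantom mid-depth plane
    # (uniform over the overlap under the piecewise-linear panorama map)
    y_ref = float(np.mean([p[1] for p in pos.values()]))
    sp = geometry.pixel_spacing
    sid, sod = geometry.sid, geometry.sod

    def _plane_parallax(k):
        return (mids[k - 1] - mids[k]) * (sid / sod - sid / y_ref) / sp

    # stitch: register each segment to the composite over the overlap strip
    composite = seg_images[0].copy()
    shifts = [0.0]
    unregistered = []
    for k in range(1, n_seg):
        r0, _ = ranges[k]
        strip = slice(r0, min(r0 + max(n_ov, 1), h))
        ref = composite[strip]
        expected = shifts[k - 1] + _plane_parallax(k)
        if ref.std() < 1e-6 or seg_images[k][strip].std() < 1e-6:
            unregistered.append(k)
            raw = expected
        else:
            window = max(max_shift_px, int(np.ceil(abs(expected))) + 8)
            scores = []
            cands = range(-window, window + 1)
            for s in cands:
                lo, hi = strip.start - s, strip.stop - s
                if lo < 0 or hi > h:
                    scores.append(-np.inf)
                else:
                    scores.append(_ncc(ref, seg_images[k][lo:hi]))
            scores = np.asarray(scores)
            best = int(np.argmax(scores))
            raw = float(list(cands)[best])
            if 0 < best < len(scores) - 1 and np.isfinite(scores).all():
                y0, y1, y2 = scores[best - 1:best + 2]
                denom = y0 - 2 * y1 + y2
                if denom < 0:
                    raw += 0.5 * (y0 - y2) / denom
        # the gain shrinks the newly measured increment toward the
        # mechanical prior; earlier segments' shifts are already committed
        est = shifts[k - 1] + registration_gain * (raw - shifts[k - 1])
        if registration_error_sigma > 0:
            est += float(rng.normal(0.0, registration_error_sigma))
        shifts.append(est)
        shifted = seg_images[k] if est == 0.0 else ndimage.shift(
            seg_images[k], (est, 0.0), order=1, mode="constant",
            cval=background)
        np.maximum(composite, shifted, out=composite)

    # provenance: each bead belongs to the segment whose core center is
    # nearest its mapped position, and inherits that segment's shift
    provenance = {}
    core_centers = [(k + 0.5) * h_core for k in range(n_seg)]
    for lab in pos:
        k_star = int(np.argmin([abs(seg_beads[k][lab][0] - core_centers[k])
                                for k in range(n_seg)]))
        row, col, dia = seg_beads[k_star][lab]
        provenance[lab] = {
            "center_px": (row + shifts[k_star], col),
            "diameter_px": dia,
            "magnification": dia * geometry.pixel_spacing / layout.bead_diameter_true,
            "segment": k_star,
        }

    if noise is not None:
        composite = noise.apply(composite)
    return Radiograph(
        image=composite, pixel_spacing=geometry.pixel_spacing,
        geometry=geometry, provenance=provenance,
        meta={"segment_shifts": shifts, "segment_midpoints_mm": mids,
              "unregistered_segments": unregistered},
    )
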