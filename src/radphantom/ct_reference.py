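"""CT gold standard: bead segmentation, sphere fitting, 3-D distances.

The reference distances l_CT come from a CT scan of the bead phantom: the
metal beads are segmented by intensity thresholding, each connected
component is fitted as a sphere, and the Euclidean distances between fitted
centers over the nine canonical within-plane marker pairs form the gold
standard against which radiographic measurements are scored.

Sphere fitting acts on the component's *surface* voxels (those with at
least one background 6-neighbor) — interior voxels carry no shape
information — using the algebraic least-squares (Coope) formulation
followed by one geometric Gauss–Newton refinement step.  A plain centroid
estimator is also provided; for a symmetric, fully sampled sphere the two
agree to well below the voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .phantom import CtVolume, MarkerPair, PLANE_OF_LABEL, canonical_pairs

__all__ = [
    "GoldStandard",
    "CtReferenceError",
    "segment_beads",
    "fit_sphere",
    "centroid_center",
    "gold_distances",
    "gold_standard_from_volume",
]


class CtReferenceError(ValueError):
    pass


@dataclass
class GoldStandard:
    """Gold-standard 3-D distances l_CT with the fitted bead centers."""

    distances: dict[MarkerPair, float]
    centers: dict[str, np.ndarray] = field(default_factory=dict)
    fit_residuals: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        missing = [p for p in canonical_pairs() if p not in self.distances]
        if missing:
            raise CtReferenceError(f"gold standard missing pairs {missing}")
        for p, d in self.distances.items():
            if d <= 0:
                raise CtReferenceError(f"non-positive distance for {p}")

    def distance(self, pair: MarkerPair) -> float:
        for k, v in self.distances.items():
            if k == pair:
                return v
        raise CtReferenceError(f"no gold distance for {pair}")


def segment_beads(
    volume: CtVolume,
    threshold: float | None = None,
    nominal_diameter_mm: float = 8.0,
    expected_count: int = 7,
):
    """Threshold-segment the bead voxels and label connected components.

    Components are 26-connected and filtered to a plausible bead volume
    (0.25x–4x the nominal sphere volume).  Exactly ``expected_count``
    surviving components are required.  Returns ``(labels, component_ids)``
    where ``labels`` is an int array over the volume grid.
    """
    data = volume.data
    if threshold is None:
        threshold = float(threshold_otsu(np.asarray(data, dtype=float)))
    if not (data.min() <= threshold <= data.max()):
        raise CtReferenceError(
            f"threshold {threshold} outside intensity range "
            f"[{data.min()}, {data.max()}]"
        )
    mask = data >= threshold
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labels, n_raw = ndimage.label(mask, structure=structure)

    voxel_vol = float(np.prod(volume.spacing))
    nominal = (4.0 / 3.0) * np.pi * (nominal_diameter_mm / 2.0) ** 3
    lo, hi = 0.25 * nominal, 4.0 * nominal
    counts = ndimage.sum_labels(np.ones_like(labels), labels,
                                index=np.arange(1, n_raw + 1))
    keep = [i + 1 for i, c in enumerate(counts) if lo <= c * voxel_vol <= hi]
    if len(keep) != expected_count:
        raise CtReferenceError(
            f"expected {expected_count} bead components, found {len(keep)} "
            f"(raw components: {n_raw}, voxel counts: "
            f"{[int(c) for c in counts]})"
        )
    out = np.zeros_like(labels)
    for new_id, old_id in enumerate(keep, start=1):
        out[labels == old_id] = new_id
    return out, list(range(1, expected_count + 1))


def _surface_voxels(component_mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(
        component_mask, structure=ndimage.generate_binary_structure(3, 1)
    )
    surface = component_mask & ~eroded
    return np.argwhere(surface)


def _algebraic_sphere(points: np.ndarray):
    """Coope linear least squares: ||p||^2 = 2 c.p + (r^2 - ||c||^2)."""
    a = np.hstack([2.0 * points, np.ones((len(points), 1))])
    b = (points**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise CtReferenceError("degenerate algebraic sphere fit")
    return center, float(np.sqrt(r2))


def _geometric_step(points: np.ndarray, center: np.ndarray, radius: float):
    """One Gauss–Newton step on sum (|p - c| - r)^2 over (c, r)."""
    diff = points - center
    dist = np.linalg.norm(diff, axis=1)
    ok = dist > 1e-12
    jac = np.zeros((len(points), 4))
    jac[ok, :3] = -diff[ok] / dist[ok, None]
    jac[:, 3] = -1.0
    res = dist - radius
    step, *_ = np.linalg.lstsq(jac, res, rcond=None)
    return center - step[:3], radius - step[3]


def fit_sphere(component_voxels: np.ndarray, spacing, origin=(0.0, 0.0, 0.0)):
    """Fit a sphere to a bead component.

    ``component_voxels`` is either a boolean mask over the volume grid or an
    (n, 3) array of voxel indices.  Only surface voxels enter the fit.
    Voxel index i maps to world coordinate origin + spacing * (i + 1/2).
    Returns ``(center_mm, radius_mm, rms_residual_mm)``.
    """
    vox = np.asarray(component_voxels)
    if vox.dtype == bool:
        if vox.sum() < 10:
            raise CtReferenceError("component has fewer than 10 voxels")
        idx = _surface_voxels(vox)
    else:
        if len(vox) < 10:
            raise CtReferenceError("component has fewer than 10 voxels")
        idx = vox
    sp = np.asarray(spacing, dtype=float)
    pts = np.asarray(origin, dtype=float) + sp * (idx + 0.5)

    # coplanarity check: a plane of points cannot constrain a sphere
    centered = pts - pts.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[-1] < 1e-9 * max(svals[0], 1.0):
        raise CtReferenceError("surface voxels are coplanar; sphere fit degenerate")

    center, radius = _algebraic_sphere(pts)
    center, radius = _geometric_step(pts, center, radius)
    rms = float(np.sqrt(np.mean((np.linalg.norm(pts - center, axis=1) - radius) ** 2)))
    return center, float(radius), rms


def centroid_center(component_voxels: np.ndarray, spacing, origin=(0.0, 0.0, 0.0)):
    """Centroid of all component voxels in world mm (brute-force center
    estimate; agrees with the sphere fit on symmetric discretizations)."""
    vox = np.asarray(component_voxels)
    idx = np.argwhere(vox) if vox.dtype == bool else vox
    sp = np.asarray(spacing, dtype=float)
    pts = np.asarray(origin, dtype=float) + sp * (idx + 0.5)
    return pts.mean(axis=0)


def gold_distances(centers: dict[str, np.ndarray],
                   fit_residuals: dict[str, float] | None = None) -> GoldStandard:
    """Euclidean 3-D distances over the nine canonical pairs."""
    missing = [lab for lab in PLANE_OF_LABEL if lab not in centers]
    if missing:
        raise CtReferenceError(f"missing bead centers for {missing}")
    dists = {
        p: float(np.linalg.norm(np.asarray(centers[p.a]) - np.asarray(centers[p.b])))
        for p in canonical_pairs()
    }
    return GoldStandard(distances=dists,
                        centers={k: np.asarray(v, float) for k, v in centers.items()},
                        fit_residuals=fit_residuals or {})


def gold_standard_from_volume(
    volume: CtVolume,
    layout_positions: dict[str, np.ndarray],
    threshold: float | None = None,
    nominal_diameter_mm: float = 8.0,
) -> GoldStandard:
    """Full gold-standard loop: segment, fit spheres, label components by
    proximity to the known marker positions, measure pair distances.

    ``layout_positions`` (label -> approximate 3-D position, mm) is only
    used to attach marker labels to the anonymous components; the measured
    centers come entirely from the sphere fits.
    """
    labels, ids = segment_beads(volume, threshold=threshold,
                                nominal_diameter_mm=nominal_diameter_mm,
                                expected_count=len(layout_positions))
    centers, residuals = {}, {}
    fitted = []
    for cid in ids:
        mask = labels == cid
        c, r, rms = fit_sphere(mask, volume.spacing, volume.origin)
        fitted.append((c, rms))
    for lab, approx in layout_positions.items():
        dists = [np.linalg.norm(c - np.asarray(approx)) for c, _ in fitted]
        j = int(np.argmin(dists))
        centers[lab] = fitted[j][0]
        residuals[lab] = fitted[j][1]
    if len({tuple(np.round(c, 6)) for c in centers.values()}) != len(centers):
        raise CtReferenceError("component-to-label assignment is ambiguous")
    return gold_distances(centers, residuals)
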