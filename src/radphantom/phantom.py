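"""Bead phantom geometry.

The measurement phantom carries seven 8.00 mm steel fiducial beads glued at
anatomical landmarks — chest (C), left/right shoulder (LS, RS), left/right
pelvis (LP, RP) and left/right hip (LH, RH) — arranged on two coronal planes
at different depths: {C, LH, RH} on plane 1 (nearer the X-ray source) and
{RS, LS, RP, LP} on plane 2.  Only the nine within-plane pairwise distances
enter the downstream analysis, so a concrete 3-D layout is reconstructed here
from a printed distance table: the 3-bead plane by exact triangle
construction, the 4-bead plane by classical multidimensional scaling followed
by a Gauss–Newton refinement pass on the six distances.

The module also rasterizes a layout into a synthetic CT volume (beads as
solid spheres on a uniform background) for the gold-standard extraction
pipeline in :mod:`radphantom.ct_reference`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LABELS",
    "PLANE_OF_LABEL",
    "MarkerPair",
    "BeadLandmark",
    "PhantomLayout",
    "CtVolume",
    "canonical_pairs",
    "reconstruct_layout",
    "voxelize",
]

#: Marker labels and their plane membership.  Plane 1 is the coronal plane
#: nearer the X-ray source (its beads image with the larger magnification).
PLANE_OF_LABEL = {
    "C": 1, "LH": 1, "RH": 1,
    "RS": 2, "LS": 2, "RP": 2, "LP": 2,
}
LABELS = tuple(PLANE_OF_LABEL)

#: Deterministic in-plane embedding orders (first bead at the origin, second
#: on the +x axis, third with +y >= 0).  The orders are chosen so that the
#: long anatomical axis of each plane maps to the second in-plane axis, which
#: the projection module treats as the longitudinal (cranio-caudal) direction.
_PLANE_ORDER = {1: ("LH", "RH", "C"), 2: ("RS", "LS", "RP", "LP")}


class PhantomError(ValueError):
    """Invalid phantom geometry or distance table."""


@dataclass(frozen=True)
class MarkerPair:
    """Unordered within-plane pair of marker labels."""

    a: str
    b: str

    def __post_init__(self):
        for lab in (self.a, self.b):
            if lab not in PLANE_OF_LABEL:
                raise PhantomError(f"unknown marker label {lab!r}")
        if self.a == self.b:
            raise PhantomError("a pair needs two distinct markers")
        if PLANE_OF_LABEL[self.a] != PLANE_OF_LABEL[self.b]:
            raise PhantomError(
                f"pair {self.a}-{self.b} spans planes; only within-plane "
                "distances are defined"
            )

    @property
    def plane_id(self) -> int:
        return PLANE_OF_LABEL[self.a]

    @property
    def name(self) -> str:
        return f"{self.a}-{self.b}"

    @classmethod
    def from_name(cls, name: str) -> "MarkerPair":
        a, _, b = name.partition("-")
        return cls(a, b)

    # equality/hashing are order-free: RS-LP == LP-RS
    def __eq__(self, other):
        if not isinstance(other, MarkerPair):
            return NotImplemented
        return {self.a, self.b} == {other.a, other.b}

    def __hash__(self):
        return hash(frozenset((self.a, self.b)))

    def __str__(self):
        return self.name


def canonical_pairs() -> list[MarkerPair]:
    """The nine within-plane pairs: three on plane 1, six on plane 2."""
    pairs = []
    for plane in (1, 2):
        labs = [l for l in LABELS if PLANE_OF_LABEL[l] == plane]
        for i, a in enumerate(labs):
            for b in labs[i + 1:]:
                pairs.append(MarkerPair(a, b))
    return pairs


@dataclass(frozen=True)
class BeadLandmark:
    """One fiducial bead: label, plane membership and 3-D position in mm.

    Position axes are (x, y, z) = (transverse, depth along the beam,
    longitudinal/cranio-caudal).  All beads of a plane share the same depth.
    """

    label: str
    plane_id: int
    position: tuple[float, float, float]


@dataclass
class PhantomLayout:
    """Seven-bead layout with the true bead diameter R* (caliper, mm)."""

    landmarks: dict[str, BeadLandmark]
    bead_diameter_true: float = 8.0
    plane_separation: float = 75.0
    #: per-pair |reconstructed - requested| residuals from the embedding, mm
    embedding_residuals: dict[MarkerPair, float] = field(default_factory=dict)

    def __post_init__(self):
        # an empty layout is tolerated as a degenerate case (uniform volume);
        # anything else must be the full 7-marker set
        if self.landmarks and set(self.landmarks) != set(LABELS):
            raise PhantomError(
                f"layout needs exactly the 7 markers {sorted(LABELS)}, "
                f"got {sorted(self.landmarks)}"
            )
        if self.bead_diameter_true <= 0:
            raise PhantomError("bead_diameter_true must be positive")
        if self.plane_separation < 0:
            raise PhantomError("plane_separation must be >= 0")
        for lab, lm in self.landmarks.items():
            if lm.plane_id != PLANE_OF_LABEL[lab]:
                raise PhantomError(f"{lab} assigned to wrong plane")
        for plane in (1, 2) if self.landmarks else ():
            depths = {round(lm.position[1], 9) for lm in self.landmarks.values()
                      if lm.plane_id == plane}
            if len(depths) != 1:
                raise PhantomError(f"plane {plane} beads are not coplanar")

    def position(self, label: str) -> np.ndarray:
        return np.asarray(self.landmarks[label].position, dtype=float)

    def positions(self) -> dict[str, np.ndarray]:
        return {lab: self.position(lab) for lab in LABELS}

    def distance(self, pair: MarkerPair) -> float:
        return float(np.linalg.norm(self.position(pair.a) - self.position(pair.b)))

    def distances(self) -> dict[MarkerPair, float]:
        return {p: self.distance(p) for p in canonical_pairs()}

    def plane_depth(self, plane_id: int) -> float:
        for lm in self.landmarks.values():
            if lm.plane_id == plane_id:
                return lm.position[1]
        raise PhantomError(f"no beads on plane {plane_id}")


@dataclass
class CtVolume:
    """Intensity grid with world metadata.

    World coordinates follow the voxel-center convention: the center of voxel
    (0, 0, 0) lies at ``origin + spacing / 2``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise PhantomError("CtVolume data must be 3-D")
        if any(s <= 0 for s in self.spacing):
            raise PhantomError("voxel spacing must be strictly positive")

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        sp = np.asarray(self.spacing, float)
        org = np.asarray(self.origin, float)
        return tuple(
            org[i] + sp[i] * (np.arange(self.data.shape[i]) + 0.5)
            for i in range(3)
        )


# ---------------------------------------------------------------------------
# layout reconstruction from a printed distance table
# ---------------------------------------------------------------------------

def _table_lookup(table: dict, a: str, b: str) -> float:
    pair = MarkerPair(a, b)
    for key, val in table.items():
        k = key if isinstance(key, MarkerPair) else MarkerPair.from_name(str(key))
        if k == pair:
            if val <= 0:
                raise PhantomError(f"distance for {pair} must be positive")
            return float(val)
    raise PhantomError(f"distance table is missing pair {pair}")


def _embed_triangle(d_ab: float, d_ac: float, d_bc: float) -> np.ndarray:
    """Exact planar triangle: A at origin, B on +x, C with y >= 0."""
    if d_ab + d_ac <= d_bc or d_ab + d_bc <= d_ac or d_ac + d_bc <= d_ab:
        raise PhantomError("triangle inequality violated in 3-bead plane")
    xc = (d_ac**2 + d_ab**2 - d_bc**2) / (2 * d_ab)
    yc2 = d_ac**2 - xc**2
    yc = float(np.sqrt(max(yc2, 0.0)))
    return np.array([[0.0, 0.0], [d_ab, 0.0], [xc, yc]])


def _classical_mds_2d(dmat: np.ndarray) -> np.ndarray:
    """Classical (Torgerson) scaling of a squared-distance matrix into 2-D."""
    n = dmat.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dmat**2) @ j
    w, v = np.linalg.eigh(b)
    idx = np.argsort(w)[::-1][:2]
    coords = v[:, idx] * np.sqrt(np.clip(w[idx], 0.0, None))
    return coords


def _gauss_newton_pass(coords: np.ndarray, dmat: np.ndarray) -> np.ndarray:
    """One Gauss–Newton step on the stress of all pairwise distances."""
    n = coords.shape[0]
    pairs = [(i, k) for i in range(n) for k in range(i + 1, n)]
    x = coords.ravel().copy()
    jac = np.zeros((len(pairs), 2 * n))
    res = np.zeros(len(pairs))
    for row, (i, k) in enumerate(pairs):
        diff = x[2 * i:2 * i + 2] - x[2 * k:2 * k + 2]
        dist = np.linalg.norm(diff)
        res[row] = dist - dmat[i, k]
        if dist > 0:
            g = diff / dist
            jac[row, 2 * i:2 * i + 2] = g
            jac[row, 2 * k:2 * k + 2] = -g
    step, *_ = np.linalg.lstsq(jac, res, rcond=None)
    return (x - step).reshape(n, 2)


def _apply_gauge(coords: np.ndarray) -> np.ndarray:
    """Fix the rigid-motion ambiguity: point 0 at origin, point 1 on +x,
    point 2 with y >= 0."""
    c = coords - coords[0]
    v = c[1]
    theta = np.arctan2(v[1], v[0])
    rot = np.array([[np.cos(-theta), -np.sin(-theta)],
                    [np.sin(-theta), np.cos(-theta)]])
    c = c @ rot.T
    if c[2, 1] < 0:
        c[:, 1] = -c[:, 1]
    return c


def reconstruct_layout(
    ct_distance_table: dict,
    plane_separation: float = 75.0,
    bead_diameter_true: float = 8.0,
) -> PhantomLayout:
    """Build a concrete 3-D bead layout from within-plane distances.

    Parameters
    ----------
    ct_distance_table
        Mapping of :class:`MarkerPair` (or ``"A-B"`` strings) to distance in
        mm; must contain all nine canonical pairs.
    plane_separation
        Depth offset in mm between the two coronal planes (plane 1 is placed
        at depth 0, plane 2 at ``plane_separation``).

    The 3-bead plane is reconstructed exactly; the 4-bead plane by classical
    MDS plus one Gauss–Newton refinement pass, with per-pair residuals
    recorded on the returned layout.  Both planes use a deterministic
    orientation gauge, so identical inputs give identical coordinates.
    """
    if plane_separation < 0:
        raise PhantomError("plane_separation must be >= 0")

    in_plane: dict[int, np.ndarray] = {}
    for plane, order in _PLANE_ORDER.items():
        n = len(order)
        dmat = np.zeros((n, n))
        for i, a in enumerate(order):
            for k in range(i + 1, n):
                dmat[i, k] = dmat[k, i] = _table_lookup(ct_distance_table, a, order[k])
        if n == 3:
            coords = _embed_triangle(dmat[0, 1], dmat[0, 2], dmat[1, 2])
        else:
            coords = _classical_mds_2d(dmat)
            coords = _gauss_newton_pass(coords, dmat)
            coords = _apply_gauge(coords)
        in_plane[plane] = coords

    landmarks = {}
    residuals: dict[MarkerPair, float] = {}
    for plane, order in _PLANE_ORDER.items():
        coords = in_plane[plane]
        # center each plane's beads transversely and longitudinally
        coords = coords - coords.mean(axis=0)
        depth = 0.0 if plane == 1 else float(plane_separation)
        for lab, (x, z) in zip(order, coords):
            landmarks[lab] = BeadLandmark(lab, plane, (float(x), depth, float(z)))
        for i, a in enumerate(order):
            for k in range(i + 1, len(order)):
                pair = MarkerPair(a, order[k])
                want = _table_lookup(ct_distance_table, a, order[k])
                got = float(np.linalg.norm(coords[i] - coords[k]))
                residuals[pair] = abs(got - want)

    return PhantomLayout(
        landmarks=landmarks,
        bead_diameter_true=bead_diameter_true,
        plane_separation=plane_separation,
        embedding_residuals=residuals,
    )


# ---------------------------------------------------------------------------
# rasterization into a CT volume
# ---------------------------------------------------------------------------

def voxelize(
    layout: PhantomLayout,
    spacing: tuple[float, float, float] = (0.8, 0.8, 1.0),
    intensity_bead: float = 1000.0,
    intensity_background: float = 0.0,
    margin_mm: float = 10.0,
    dtype=np.float32,
) -> CtVolume:
    """Rasterize the layout: voxels whose centers lie inside a bead sphere
    get ``intensity_bead``, everything else ``intensity_background``.

    The grid is sized to enclose every bead plus ``margin_mm`` on all sides.
    A bead radius smaller than one voxel on any axis is rejected (the sphere
    fit downstream would be degenerate).
    """
    sp = np.asarray(spacing, dtype=float)
    if np.any(sp <= 0):
        raise PhantomError("voxel spacing must be strictly positive")
    radius = layout.bead_diameter_true / 2.0
    if np.any(radius < sp):
        raise PhantomError(
            f"bead radius {radius} mm is below one voxel "
            f"({tuple(sp)}); rasterization would be degenerate"
        )

    labels = tuple(layout.landmarks)
    if not labels:
        shape = np.ceil(2 * margin_mm / sp).astype(int)
        return CtVolume(
            data=np.full(shape, intensity_background, dtype=dtype),
            spacing=tuple(float(s) for s in sp),
            origin=(0.0, 0.0, 0.0),
        )
    pos = np.array([layout.position(lab) for lab in labels])
    lo = pos.min(axis=0) - radius - margin_mm
    hi = pos.max(axis=0) + radius + margin_mm
    shape = np.ceil((hi - lo) / sp).astype(int)
    origin = tuple(float(v) for v in lo)

    vol = np.full(shape, intensity_background, dtype=dtype)
    axes = [lo[i] + sp[i] * (np.arange(shape[i]) + 0.5) for i in range(3)]
    for lab in labels:
        c = layout.position(lab)
        if np.any(c - radius < lo) or np.any(c + radius > hi):
            raise PhantomError(f"bead {lab} extends outside the voxel grid")
        # restrict to the bounding box of the sphere for speed
        sl = []
        for i in range(3):
            i0 = int(np.searchsorted(axes[i], c[i] - radius - sp[i]))
            i1 = int(np.searchsorted(axes[i], c[i] + radius + sp[i]))
            sl.append(slice(max(i0, 0), min(i1, shape[i])))
        xs = axes[0][sl[0]][:, None, None]
        ys = axes[1][sl[1]][None, :, None]
        zs = axes[2][sl[2]][None, None, :]
        inside = ((xs - c[0]) ** 2 + (ys - c[1]) ** 2 + (zs - c[2]) ** 2
                  <= radius**2)
        region = vol[sl[0], sl[1], sl[2]]
        region[inside] = intensity_bead
    return CtVolume(data=vol, spacing=tuple(float(s) for s in sp), origin=origin)
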