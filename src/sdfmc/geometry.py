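"""Signed distance functions, CSG algebra, rigid transforms and scenes.

All distances are in cm in a right-handed world frame.  The sign
convention is: negative strictly inside a shape, zero on its surface,
positive outside.  Every exact primitive is 1-Lipschitz and satisfies
|grad D| = 1 away from the medial axis, which is what makes sphere
tracing safe: stepping by |D| can never cross a surface.

The classes here are the user-facing scene description; transport runs
on a flattened copy produced by :mod:`sdfmc._compile`.  Distance methods
accept a single point of shape ``(3,)`` or a batch ``(..., 3)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

from .errors import (ConfigError, DegenerateNormalError, OutOfDomainError,
                     ParameterError)

__all__ = [
    "OpticalMedium", "VACUUM", "SdfNode", "Sphere", "Box", "Capsule",
    "Cylinder", "Union", "SmoothUnion", "Intersection", "Subtraction",
    "Transform", "Scene", "GridSpec",
    "distance_sphere", "distance_box", "distance_capsule",
    "distance_cylinder", "combine", "transform_point", "rotation_matrix",
    "surface_normal", "rasterize",
]

DEFAULT_NORMAL_STEP = 1.0e-6  # cm; << mm-cm features, >> double-precision noise


def _as_points(p) -> np.ndarray:
    a = np.asarray(p, dtype=np.float64)
    if a.shape[-1] != 3:
        raise ParameterError(f"points must have a trailing axis of size 3, got {a.shape}")
    return a


# ---------------------------------------------------------------------------
# media


@dataclass(frozen=True)
class OpticalMedium:
    """Homogeneous optical properties of a region.

    Parameters
    ----------
    mu_s : float
        Scattering coefficient (cm^-1), >= 0.
    mu_a : float
        Absorption coefficient (cm^-1), >= 0.
    g : float
        Henyey-Greenstein anisotropy, in (-1, 1).
    n : float
        Refractive index, >= 1.
    """

    mu_s: float = 0.0
    mu_a: float = 0.0
    g: float = 0.0
    n: float = 1.0

    def __post_init__(self):
        if self.mu_s < 0 or self.mu_a < 0:
            raise ParameterError("mu_s and mu_a must be non-negative")
        if not -1.0 < self.g < 1.0:
            raise ParameterError("anisotropy g must lie in (-1, 1)")
        if self.n < 1.0:
            raise ParameterError("refractive index must be >= 1")

    @property
    def mu_t(self) -> float:
        """Extinction coefficient mu_s + mu_a (cm^-1)."""
        return self.mu_s + self.mu_a

    @property
    def albedo(self) -> float:
        """Single-scattering albedo mu_s / mu_t; 0 for a non-interacting medium."""
        mt = self.mu_t
        return self.mu_s / mt if mt > 0.0 else 0.0


VACUUM = OpticalMedium(0.0, 0.0, 0.0, 1.0)


# ---------------------------------------------------------------------------
# free distance functions


def distance_sphere(p, r: float):
    """Signed distance |p| - r to a sphere of radius ``r`` at the origin."""
    if r <= 0:
        raise ParameterError("sphere radius must be > 0")
    p = _as_points(p)
    return np.linalg.norm(p, axis=-1) - r


def distance_box(p, half_extents):
    """Exact signed distance to an axis-aligned box at the origin."""
    he = np.asarray(half_extents, dtype=np.float64)
    if he.shape != (3,) or np.any(he <= 0):
        raise ParameterError("box half extents must be three positive numbers")
    p = _as_points(p)
    q = np.abs(p) - he
    outside = np.linalg.norm(np.maximum(q, 0.0), axis=-1)
    inside = np.minimum(np.max(q, axis=-1), 0.0)
    return outside + inside


def distance_capsule(p, a, b, r: float):
    """Signed distance to the capsule with axis segment ``a``-``b``, radius ``r``."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    ba = b - a
    denom = float(ba @ ba)
    if denom == 0.0:
        raise ParameterError("capsule segment is degenerate (a == b)")
    if r <= 0:
        raise ParameterError("capsule radius must be > 0")
    p = _as_points(p)
    pa = p - a
    h = np.clip((pa @ ba) / denom, 0.0, 1.0)
    return np.linalg.norm(pa - np.multiply.outer(h, ba), axis=-1) - r


def distance_cylinder(p, half_height: float, r: float):
    """Exact signed distance to a capped cylinder (axis z) at the origin."""
    if half_height <= 0 or r <= 0:
        raise ParameterError("cylinder half height and radius must be > 0")
    p = _as_points(p)
    dr = np.hypot(p[..., 0], p[..., 1]) - r
    dz = np.abs(p[..., 2]) - half_height
    inside = np.minimum(np.maximum(dr, dz), 0.0)
    outside = np.hypot(np.maximum(dr, 0.0), np.maximum(dz, 0.0))
    return inside + outside


_COMBINE_KINDS = ("union", "intersection", "subtraction", "smooth_union")


def combine(kind: str, d1, d2, k: Optional[float] = None):
    """CSG-combine two signed distances.

    union -> min; intersection -> max; subtraction (d1 minus d2) ->
    max(d1, -d2); smooth_union -> quadratic polynomial smooth-min with
    blend radius ``k`` (reduces to min when |d1 - d2| >= k).  The smooth
    union is a bound on the true distance, not an exact distance.
    """
    d1 = np.asarray(d1, dtype=np.float64)
    d2 = np.asarray(d2, dtype=np.float64)
    if kind == "union":
        return np.minimum(d1, d2)
    if kind == "intersection":
        return np.maximum(d1, d2)
    if kind == "subtraction":
        return np.maximum(d1, -d2)
    if kind == "smooth_union":
        if k is None or k <= 0:
            raise ParameterError("smooth_union requires a blend radius k > 0")
        h = np.maximum(k - np.abs(d1 - d2), 0.0) / k
        return np.minimum(d1, d2) - h * h * k * 0.25
    raise ParameterError(f"unknown CSG kind {kind!r}")


def rotation_matrix(axis, angle_deg: float) -> np.ndarray:
    """Right-handed rotation by ``angle_deg`` about ``axis`` (Rodrigues)."""
    a = np.asarray(axis, dtype=np.float64)
    norm = np.linalg.norm(a)
    if norm == 0:
        raise ParameterError("rotation axis must be non-zero")
    a = a / norm
    th = np.deg2rad(angle_deg)
    kmat = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(th) * kmat + (1 - np.cos(th)) * (kmat @ kmat)


def _check_orthonormal(rotation: np.ndarray):
    if rotation.shape != (3, 3) or not np.allclose(
            rotation @ rotation.T, np.eye(3), atol=1e-9):
        raise ParameterError("rotation must be a 3x3 orthonormal matrix")


def transform_point(p, rotation, translation):
    """Map a world point into the local frame of a rigidly placed shape.

    The shape is placed by rotating with ``rotation`` then translating by
    ``translation``; the returned point is ``rotation.T @ (p - translation)``
    so that a child SDF evaluated there sees its own local frame.  Rigid
    maps preserve distances, so the child's signed distance is unchanged.
    """
    rotation = np.asarray(rotation, dtype=np.float64)
    _check_orthonormal(rotation)
    p = _as_points(p)
    t = np.asarray(translation, dtype=np.float64)
    return (p - t) @ rotation  # == rotation.T applied to each point


# ---------------------------------------------------------------------------
# node classes


class SdfNode:
    """A shape, combinator or rigid-transform node of a scene tree.

    ``medium`` and ``layer`` are meaningful on scene roots (and are
    ignored on interior nodes): the medium fills the region where the
    root's signed distance is negative, and ``layer`` resolves nested /
    overlapping regions (higher layer wins).
    """

    kind: str = "abstract"

    def __init__(self, medium: Optional[OpticalMedium] = None, layer: int = 0):
        self.medium = medium
        self.layer = int(layer)
        self.children: Tuple["SdfNode", ...] = ()

    def distance(self, p):
        raise NotImplementedError

    def __call__(self, p):
        return self.distance(p)


class Sphere(SdfNode):
    kind = "sphere"

    def __init__(self, radius: float, medium=None, layer: int = 0):
        super().__init__(medium, layer)
        if radius <= 0:
            raise ParameterError("sphere radius must be > 0")
        self.radius = float(radius)

    def distance(self, p):
        return distance_sphere(p, self.radius)


class Box(SdfNode):
    kind = "box"

    def __init__(self, half_extents, medium=None, layer: int = 0):
        super().__init__(medium, layer)
        he = np.asarray(half_extents, dtype=np.float64)
        if he.shape != (3,) or np.any(he <= 0):
            raise ParameterError("box half extents must be three positive numbers")
        self.half_extents = he

    def distance(self, p):
        return distance_box(p, self.half_extents)


class Capsule(SdfNode):
    kind = "capsule"

    def __init__(self, a, b, radius: float, medium=None, layer: int = 0):
        super().__init__(medium, layer)
        self.a = np.asarray(a, dtype=np.float64)
        self.b = np.asarray(b, dtype=np.float64)
        if np.array_equal(self.a, self.b):
            raise ParameterError("capsule segment is degenerate (a == b)")
        if radius <= 0:
            raise ParameterError("capsule radius must be > 0")
        self.radius = float(radius)

    def distance(self, p):
        return distance_capsule(p, self.a, self.b, self.radius)


class Cylinder(SdfNode):
    """Finite capped cylinder with axis along z."""

    kind = "cylinder"

    def __init__(self, half_height: float, radius: float, medium=None, layer: int = 0):
        super().__init__(medium, layer)
        if half_height <= 0 or radius <= 0:
            raise ParameterError("cylinder half height and radius must be > 0")
        self.half_height = float(half_height)
        self.radius = float(radius)

    def distance(self, p):
        return distance_cylinder(p, self.half_height, self.radius)


class _Csg(SdfNode):
    def __init__(self, first: SdfNode, second: SdfNode, medium=None, layer: int = 0):
        super().__init__(medium, layer)
        self.children = (first, second)

    def distance(self, p):
        return combine(self.kind, self.children[0].distance(p),
                       self.children[1].distance(p))


class Union(_Csg):
    kind = "union"


class Intersection(_Csg):
    kind = "intersection"


class Subtraction(_Csg):
    """First child minus second child."""

    kind = "subtraction"


class SmoothUnion(_Csg):
    kind = "smooth_union"

    def __init__(self, first, second, k: float, medium=None, layer: int = 0):
        super().__init__(first, second, medium, layer)
        if k <= 0:
            raise ParameterError("smooth_union blend radius k must be > 0")
        self.k = float(k)

    def distance(self, p):
        return combine("smooth_union", self.children[0].distance(p),
                       self.children[1].distance(p), self.k)


class Transform(SdfNode):
    """Rigid placement (rotation then translation) of a child shape.

    Only rigid maps are supported: they preserve the exact-distance
    property that sphere tracing relies on.
    """

    kind = "transform"

    def __init__(self, child: SdfNode, rotation=None, translation=(0.0, 0.0, 0.0),
                 medium=None, layer: int = 0):
        super().__init__(medium, layer)
        rotation = np.eye(3) if rotation is None else np.asarray(rotation, float)
        _check_orthonormal(rotation)
        self.rotation = rotation
        self.translation = np.asarray(translation, dtype=np.float64)
        self.children = (child,)

    def distance(self, p):
        return self.children[0].distance(
            transform_point(p, self.rotation, self.translation))


def union_of(nodes: Sequence[SdfNode], medium=None, layer: int = 0) -> SdfNode:
    """Fold a sequence of shapes into a (left-deep) union tree."""
    if not nodes:
        raise ParameterError("union_of requires at least one node")
    node = nodes[0]
    for other in nodes[1:]:
        node = Union(node, other)
    node.medium = medium
    node.layer = int(layer)
    return node


# ---------------------------------------------------------------------------
# normals


def surface_normal(node: SdfNode, p, h: float = DEFAULT_NORMAL_STEP) -> np.ndarray:
    """Outward unit normal of ``node`` near ``p`` by central differences.

    Component ``i`` of the (unnormalized) gradient is
    ``(D(p + h e_i) - D(p - h e_i)) / 2h``; the result is normalized to
    unit length.  Raises :class:`DegenerateNormalError` where the
    gradient vanishes (medial-axis points).
    """
    if h <= 0:
        raise ParameterError("normal finite-difference step must be > 0")
    p = np.asarray(p, dtype=np.float64)
    grad = np.empty(3)
    for i in range(3):
        e = np.zeros(3)
        e[i] = h
        grad[i] = (float(node.distance(p + e)) - float(node.distance(p - e))) / (2 * h)
    norm = np.linalg.norm(grad)
    if norm < 1e-12:
        raise DegenerateNormalError(f"vanishing SDF gradient at {p}")
    return grad / norm


# ---------------------------------------------------------------------------
# scene


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned voxel lattice: ``dims`` voxels of size ``spacing``
    starting at corner ``origin`` (cm)."""

    dims: Tuple[int, int, int]
    origin: Tuple[float, float, float]
    spacing: Tuple[float, float, float]

    def __post_init__(self):
        if any(int(d) <= 0 for d in self.dims):
            raise ConfigError("grid dims must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ConfigError("grid spacing must be positive")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))

    @property
    def voxel_volume(self) -> float:
        return self.spacing[0] * self.spacing[1] * self.spacing[2]

    @property
    def upper(self) -> Tuple[float, float, float]:
        return tuple(o + n * s for o, n, s in zip(self.origin, self.dims, self.spacing))

    def centers(self, axis: int) -> np.ndarray:
        n = self.dims[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def center_points(self) -> np.ndarray:
        """All voxel centers as an (nx, ny, nz, 3) array."""
        cx, cy, cz = (self.centers(i) for i in range(3))
        gx, gy, gz = np.meshgrid(cx, cy, cz, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)


class Scene:
    """SDF roots plus an axis-aligned bounding box and ambient medium.

    The bounding box terminates packets on exit; every root should be
    (essentially) inside it.  ``surface_threshold`` is the sphere-trace
    boundary threshold delta_s.
    """

    def __init__(self, roots: Iterable[SdfNode], bbox_center, bbox_half_extents,
                 ambient_medium: OpticalMedium = VACUUM,
                 surface_threshold: float = 1.0e-6,
                 normal_step: Optional[float] = None):
        self.roots = list(roots)
        if not self.roots:
            raise ConfigError("scene must contain at least one SDF root")
        for i, root in enumerate(self.roots):
            if root.medium is None:
                raise ConfigError(f"scene root {i} has no optical medium")
        self.bbox_center = np.asarray(bbox_center, dtype=np.float64)
        self.bbox_half_extents = np.asarray(bbox_half_extents, dtype=np.float64)
        if np.any(self.bbox_half_extents <= 0):
            raise ConfigError("bounding box half extents must be positive")
        if surface_threshold <= 0:
            raise ConfigError("surface threshold must be positive")
        self.ambient_medium = ambient_medium
        self.surface_threshold = float(surface_threshold)
        # finite-difference step for boundary normals, tied to delta_s
        self.normal_step = float(normal_step) if normal_step else max(
            DEFAULT_NORMAL_STEP, self.surface_threshold)

    # -- queries ----------------------------------------------------------

    def bbox_distance(self, p):
        return distance_box(_as_points(p) - self.bbox_center, self.bbox_half_extents)

    def contains(self, p) -> bool:
        return bool(self.bbox_distance(p) <= 0.0)

    def scene_distance(self, p) -> Tuple[float, SdfNode]:
        """Nearest-surface distance magnitude over all roots and the
        arg-min root.  The magnitude is the sphere-trace marching step,
        valid both inside and outside shapes."""
        best = np.inf
        best_node = None
        for root in self.roots:
            d = abs(float(root.distance(p)))
            if d < best:
                best = d
                best_node = root
        return best, best_node

    def signed_distances(self, p) -> np.ndarray:
        return np.array([float(root.distance(p)) for root in self.roots])

    def medium_at(self, p) -> OpticalMedium:
        """Medium at a point: highest-layer root with negative distance,
        first-declared winning ties; ambient if no root is interior."""
        p = np.asarray(p, dtype=np.float64)
        if self.bbox_distance(p) > 0.0:
            raise OutOfDomainError(f"point {p} lies outside the bounding box")
        best_layer = None
        best = None
        for root in self.roots:
            if float(root.distance(p)) < 0.0:
                if best_layer is None or root.layer > best_layer:
                    best_layer = root.layer
                    best = root
        return best.medium if best is not None else self.ambient_medium

    # -- rasterization ----------------------------------------------------

    def root_labels(self, points: np.ndarray) -> np.ndarray:
        """Vectorized layer-rule labelling: index of the owning root per
        point, -1 for ambient."""
        pts = _as_points(points)
        flat = pts.reshape(-1, 3)
        labels = np.full(flat.shape[0], -1, dtype=np.int32)
        best_layer = np.full(flat.shape[0], np.iinfo(np.int32).min, dtype=np.int64)
        for idx, root in enumerate(self.roots):
            inside = np.asarray(root.distance(flat)) < 0.0
            take = inside & (root.layer > best_layer)
            labels[take] = idx
            best_layer[take] = root.layer
        return labels.reshape(pts.shape[:-1])


def rasterize(scene: Scene, grid: GridSpec) -> np.ndarray:
    """Per-voxel root labels (-1 = ambient) evaluated at voxel centers.

    Export/visualization aid only -- transport never uses voxels.
    """
    lo = np.asarray(grid.origin)
    hi = np.asarray(grid.upper)
    blo = scene.bbox_center - scene.bbox_half_extents
    bhi = scene.bbox_center + scene.bbox_half_extents
    if np.any(lo < blo - 1e-12) or np.any(hi > bhi + 1e-12):
        raise ConfigError("rasterization grid exceeds the scene bounding box")
    return scene.root_labels(grid.center_points())
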