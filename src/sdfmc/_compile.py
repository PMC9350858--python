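"""Flatten a :class:`~sdfmc.geometry.Scene` into kernel-ready arrays.

Rigid transforms are folded down to the leaves at compile time (rigid
maps commute with distance evaluation), so the kernel only ever sees
post-order node lists whose leaves carry a composed world->local affine
``q = A p + b``.
"""

from __future__ import annotations

from typing import List, NamedTuple

import numpy as np

from . import _kernel, geometry
from .errors import ConfigError

_KIND_CODE = {
    "sphere": _kernel.KIND_SPHERE,
    "box": _kernel.KIND_BOX,
    "capsule": _kernel.KIND_CAPSULE,
    "cylinder": _kernel.KIND_CYLINDER,
    "union": _kernel.KIND_UNION,
    "smooth_union": _kernel.KIND_SMOOTH_UNION,
    "intersection": _kernel.KIND_INTERSECTION,
    "subtraction": _kernel.KIND_SUBTRACTION,
}

_PARAM_WIDTH = 8


class CompiledScene(NamedTuple):
    kind: np.ndarray          # int32 (n,)
    params: np.ndarray        # float64 (n, 8)
    rot: np.ndarray           # float64 (n, 3, 3) leaf world->local linear part
    trans: np.ndarray         # float64 (n, 3)   leaf world->local offset
    child: np.ndarray         # int32 (n, 2)
    root_lo: np.ndarray       # int32 (nroots,)
    root_hi: np.ndarray       # int32 (nroots,)
    root_layer: np.ndarray    # int32 (nroots,)
    root_med: np.ndarray      # int32 (nroots,)  index into media
    media: np.ndarray         # float64 (nmedia, 6): mu_s mu_a g n mu_t albedo
    bbox_center: np.ndarray   # float64 (3,)
    bbox_half: np.ndarray     # float64 (3,)
    delta_s: float
    normal_step: float

    def new_scratch(self) -> np.ndarray:
        return np.empty(self.kind.shape[0], dtype=np.float64)

    def query(self, p):
        """Python-callable scene query: (|d|min, argmin root, medium idx,
        signed d of argmin)."""
        p = np.asarray(p, dtype=np.float64)
        return _kernel.scene_query(
            self.kind, self.params, self.rot, self.trans, self.child,
            self.root_lo, self.root_hi, self.root_layer, self.root_med,
            p[0], p[1], p[2], self.new_scratch())


def _medium_row(m: geometry.OpticalMedium) -> List[float]:
    return [m.mu_s, m.mu_a, m.g, m.n, m.mu_t, m.albedo]


def _emit(node: geometry.SdfNode, A: np.ndarray, b: np.ndarray,
          kind: list, params: list, rot: list, trans: list, child: list) -> int:
    """Post-order emit; returns the index of ``node``'s entry."""
    if isinstance(node, geometry.Transform):
        # world->local of the child: q = R^T (p - t) composed with (A, b)
        R = node.rotation
        t = node.translation
        A2 = R.T @ A
        b2 = R.T @ (b - t)
        return _emit(node.children[0], A2, b2, kind, params, rot, trans, child)
    code = _KIND_CODE.get(node.kind)
    if code is None:
        raise ConfigError(f"node kind {node.kind!r} is not supported in transport")
    row = np.zeros(_PARAM_WIDTH)
    if code >= 10:
        c0 = _emit(node.children[0], A, b, kind, params, rot, trans, child)
        c1 = _emit(node.children[1], A, b, kind, params, rot, trans, child)
        if isinstance(node, geometry.SmoothUnion):
            row[0] = node.k
        kind.append(code)
        params.append(row)
        rot.append(np.eye(3))
        trans.append(np.zeros(3))
        child.append([c0, c1])
        return len(kind) - 1
    if isinstance(node, geometry.Sphere):
        row[0] = node.radius
    elif isinstance(node, geometry.Box):
        row[:3] = node.half_extents
    elif isinstance(node, geometry.Capsule):
        row[0:3] = node.a
        row[3:6] = node.b
        row[6] = node.radius
    elif isinstance(node, geometry.Cylinder):
        row[0] = node.half_height
        row[1] = node.radius
    else:  # pragma: no cover
        raise ConfigError(f"unsupported leaf {type(node).__name__}")
    kind.append(code)
    params.append(row)
    rot.append(A.copy())
    trans.append(b.copy())
    child.append([-1, -1])
    return len(kind) - 1


def compile_scene(scene: geometry.Scene) -> CompiledScene:
    kind: list = []
    params: list = []
    rot: list = []
    trans: list = []
    child: list = []
    root_lo = []
    root_hi = []
    root_layer = []
    root_med = []
    media_rows = [_medium_row(scene.ambient_medium)]
    for root in scene.roots:
        lo = len(kind)
        hi = _emit(root, np.eye(3), np.zeros(3), kind, params, rot, trans, child)
        root_lo.append(lo)
        root_hi.append(hi)
        root_layer.append(root.layer)
        media_rows.append(_medium_row(root.medium))
        root_med.append(len(media_rows) - 1)
    return CompiledScene(
        kind=np.asarray(kind, dtype=np.int32),
        params=np.asarray(params, dtype=np.float64),
        rot=np.asarray(rot, dtype=np.float64),
        trans=np.asarray(trans, dtype=np.float64),
        child=np.asarray(child, dtype=np.int32),
        root_lo=np.asarray(root_lo, dtype=np.int32),
        root_hi=np.asarray(root_hi, dtype=np.int32),
        root_layer=np.asarray(root_layer, dtype=np.int32),
        root_med=np.asarray(root_med, dtype=np.int32),
        media=np.asarray(media_rows, dtype=np.float64),
        bbox_center=scene.bbox_center.copy(),
        bbox_half=scene.bbox_half_extents.copy(),
        delta_s=scene.surface_threshold,
        normal_step=scene.normal_step,
    )
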