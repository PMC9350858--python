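"""Photon launch distributions."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from . import _kernel
from .errors import ConfigError

__all__ = ["SourceSpec", "isotropic_point", "uniform_top", "collimated_strip"]

_KINDS = ("isotropic_point", "uniform_top", "collimated_strip")


@dataclass(frozen=True)
class SourceSpec:
    """Launch distribution.

    kind:
      - ``isotropic_point``: fixed origin, direction uniform on the sphere
        (cos theta = 2u - 1, phi = 2 pi u').
      - ``uniform_top`` / ``collimated_strip``: position uniform over an
        axis-aligned rectangle centered at ``origin`` with half widths
        ``half_widths`` in x and y, fixed ``direction``.

    Launch positions are nudged one surface threshold along the
    direction so packets starting exactly on a face begin inside it.
    """

    kind: str
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    half_widths: Tuple[float, float] = (0.0, 0.0)
    direction: Tuple[float, float, float] = (0.0, 0.0, -1.0)

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ConfigError(f"unknown source kind {self.kind!r}")
        d = np.asarray(self.direction, dtype=np.float64)
        norm = np.linalg.norm(d)
        if norm == 0:
            raise ConfigError("source direction must be non-zero")
        object.__setattr__(self, "direction", tuple(float(v) for v in d / norm))
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "half_widths",
                           tuple(float(v) for v in self.half_widths))

    # -- kernel plumbing --------------------------------------------------

    @property
    def kernel_kind(self) -> int:
        return (_kernel.SRC_ISOTROPIC_POINT if self.kind == "isotropic_point"
                else _kernel.SRC_RECT_BEAM)

    @property
    def kernel_params(self) -> np.ndarray:
        p = np.zeros(8)
        p[0:3] = self.origin
        p[3:5] = self.half_widths
        p[5:8] = self.direction
        return p

    # -- sampling ---------------------------------------------------------

    def emit(self, stream, delta_s: float = 0.0):
        """Sample a launch (position, direction) from a photon substream."""
        if self.kind == "isotropic_point":
            pos = np.array(self.origin)
            cos_t = 2.0 * stream.uniform() - 1.0
            sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
            phi = 2.0 * math.pi * stream.uniform()
            d = np.array([sin_t * math.cos(phi), sin_t * math.sin(phi), cos_t])
        else:
            pos = np.array(self.origin, dtype=np.float64)
            pos[0] += (2.0 * stream.uniform() - 1.0) * self.half_widths[0]
            pos[1] += (2.0 * stream.uniform() - 1.0) * self.half_widths[1]
            d = np.array(self.direction)
        return pos + delta_s * d, d


def isotropic_point(origin) -> SourceSpec:
    return SourceSpec("isotropic_point", origin=tuple(origin))


def uniform_top(center, half_widths, direction=(0.0, 0.0, -1.0)) -> SourceSpec:
    """Uniform illumination of a rectangle (e.g. a slab's top face)."""
    return SourceSpec("uniform_top", origin=tuple(center),
                      half_widths=tuple(half_widths), direction=tuple(direction))


def collimated_strip(center, width: float, half_length: float,
                     direction=(0.0, 0.0, -1.0)) -> SourceSpec:
    """Collimated beam uniform over a strip of full ``width`` in x and
    half length ``half_length`` in y."""
    if width <= 0:
        raise ConfigError("strip width must be positive")
    return SourceSpec("collimated_strip", origin=tuple(center),
                      half_widths=(width / 2.0, half_length),
                      direction=tuple(direction))
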