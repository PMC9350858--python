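"""Free-path / scattering-angle sampling and Fresnel boundary physics.

The scalar math lives as jitted kernels in :mod:`sdfmc._kernel` so the
exact same code paths run in the compiled transport loop and here; this
module adds validation and array conveniences.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from . import _kernel
from .errors import GeometryError, ParameterError

__all__ = [
    "RandomStream", "PhotonStream", "bulk_uniforms", "sample_optical_depth",
    "hg_cosine", "fresnel_reflectance", "reflect_direction",
    "refract_direction",
]


class PhotonStream:
    """One xoshiro256++ substream; yields uniforms on (0, 1]."""

    def __init__(self, seed: int, index: int):
        self.state = np.empty(4, dtype=np.uint64)
        _kernel.stream_init(seed, index, self.state)

    def uniform(self) -> float:
        return _kernel.next_uniform(self.state)

    def uniforms(self, n: int) -> np.ndarray:
        return np.array([_kernel.next_uniform(self.state) for _ in range(n)])


def bulk_uniforms(seed: int, index: int, n: int) -> np.ndarray:
    """Fast array of (0, 1] uniforms from the (seed, index) substream."""
    return _kernel.bulk_uniforms(seed, index, n)


class RandomStream:
    """Seedable RNG with independent, counter-derived per-photon substreams.

    The substream for photon ``i`` depends only on (seed, i), never on
    scheduling, so single- and multi-threaded runs with the same
    photon-to-stream mapping are bit-identical.
    """

    def __init__(self, seed: int):
        self.seed = int(seed)

    def substream(self, index: int) -> PhotonStream:
        return PhotonStream(self.seed, index)


def sample_optical_depth(u: float) -> float:
    """Dimensionless optical depth tau = -ln(u) for u on (0, 1].

    The physical free path in a uniform medium is tau / mu_t.  u = 0 is
    excluded by construction (the stream samples (0, 1]); a zero is
    rejected here rather than clamped.
    """
    if not 0.0 < u <= 1.0:
        raise ParameterError("uniform deviate must lie in (0, 1]")
    return -math.log(u)


def hg_cosine(g: float, u: float) -> float:
    """Henyey-Greenstein scattering cosine sampled from uniform ``u``.

    For |g| < 1e-6 the isotropic limit cos = 2u - 1 is used.  The
    azimuth about the incoming direction is uniform on [0, 2 pi) and is
    sampled separately by the caller.
    """
    if not abs(g) < 1.0:
        raise ParameterError("anisotropy g must satisfy |g| < 1")
    return _kernel.hg_cos(g, u)


def fresnel_reflectance(n1: float, n2: float, cos_i: float) -> float:
    """Unpolarized Fresnel reflectance (mean of s and p intensities).

    ``cos_i`` is the cosine of the incidence angle measured against the
    surface normal oriented into the incidence side; returns 1.0 under
    total internal reflection.
    """
    if n1 < 1.0 or n2 < 1.0:
        raise ParameterError("refractive indices must be >= 1")
    if not 0.0 < cos_i <= 1.0:
        raise GeometryError(
            f"cos of incidence must lie in (0, 1], got {cos_i} "
            "(surface normal likely mis-oriented)")
    return _kernel.fresnel_unpolarized(n1, n2, cos_i)


def _unit(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    norm = np.linalg.norm(v)
    if norm == 0.0:
        raise ParameterError(f"{name} must be non-zero")
    if abs(norm - 1.0) > 1e-9:
        warnings.warn(f"{name} was not unit length; normalizing", stacklevel=3)
        v = v / norm
    return v


def reflect_direction(d, n) -> np.ndarray:
    """Specular reflection d - 2 (d . n) n; ``n`` oriented so d . n < 0."""
    d = _unit(d, "direction")
    n = _unit(n, "normal")
    dot = float(d @ n)
    if dot >= 0.0:
        raise GeometryError("normal must oppose the incident direction (d.n < 0)")
    return d - 2.0 * dot * n


def refract_direction(d, n, n1: float, n2: float):
    """Vector Snell refraction of ``d`` across a surface with normal ``n``.

    Returns ``(direction, tir)``: the transmitted unit direction and
    False, or the unchanged direction and True under total internal
    reflection (the caller should then reflect instead).
    """
    d = _unit(d, "direction")
    n = _unit(n, "normal")
    dot = float(d @ n)
    if dot >= 0.0:
        raise GeometryError("normal must oppose the incident direction (d.n < 0)")
    cos_i = -dot
    eta = n1 / n2
    sin_t2 = eta * eta * (1.0 - cos_i * cos_i)
    if sin_t2 >= 1.0:
        return d, True
    cos_t = math.sqrt(1.0 - sin_t2)
    t = eta * d + (eta * cos_i - cos_t) * n
    return t / np.linalg.norm(t), False
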