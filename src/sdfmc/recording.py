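"""Path-length fluence estimation on a voxel grid.

Each traversed segment is split exactly at voxel boundaries (3D digital
differential analysis) and every voxel accumulates weight x sub-segment
length, so the deposited total equals weight x segment length exactly.
This path-length estimator is unbiased for fluence; dividing the
accumulator by (n_photons x voxel volume) and scaling by the source
power gives fluence rate per voxel.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import _kernel
from .errors import ParameterError
from .geometry import GridSpec, Scene

__all__ = ["FluenceGrid", "absorption_map"]


class FluenceGrid:
    """Voxel accumulator of weighted path length (cm).

    Voxels are half-open intervals ``[edge, next_edge)`` with index
    ``floor((x - origin) / spacing)``; points exactly on the outer edge
    belong to the last voxel.
    """

    def __init__(self, spec: GridSpec):
        self.spec = spec
        self.accumulator = np.zeros(spec.dims, dtype=np.float64)

    # -- deposition -------------------------------------------------------

    def deposit_path(self, p0, p1, weight: float = 1.0) -> None:
        """Deposit ``weight x length`` of the segment p0 -> p1, split at
        voxel boundaries.  A zero-length segment is a no-op; parts of the
        segment outside the grid are dropped."""
        p0 = np.asarray(p0, dtype=np.float64)
        p1 = np.asarray(p1, dtype=np.float64)
        o = self.spec.origin
        s = self.spec.spacing
        _kernel.deposit_segment(
            self.accumulator, o[0], o[1], o[2], s[0], s[1], s[2],
            p0[0], p0[1], p0[2], p1[0], p1[1], p1[2], float(weight))

    def voxel_index(self, p) -> tuple:
        p = np.asarray(p, dtype=np.float64)
        idx = []
        for i in range(3):
            j = int(np.floor((p[i] - self.spec.origin[i]) / self.spec.spacing[i]))
            j = min(max(j, 0), self.spec.dims[i] - 1)
            idx.append(j)
        return tuple(idx)

    # -- finalization -----------------------------------------------------

    def finalize_fluence(self, n_photons: int, source_power: float = 1.0) -> np.ndarray:
        """Fluence per voxel: accumulator x power / (n_photons x voxel volume)."""
        if n_photons <= 0:
            raise ParameterError("n_photons must be positive")
        return self.accumulator * (source_power / (n_photons * self.spec.voxel_volume))

    def depth_profile(self, n_photons: int, source_power: float = 1.0,
                      transverse_mask: Optional[np.ndarray] = None) -> np.ndarray:
        """Fluence vs z, averaged over (a mask of) transverse voxels."""
        flu = self.finalize_fluence(n_photons, source_power)
        if transverse_mask is None:
            return flu.mean(axis=(0, 1))
        return flu[transverse_mask].mean(axis=0)


def absorption_map(fluence: np.ndarray, scene: Scene, spec: GridSpec) -> np.ndarray:
    """Absorbed power density per voxel: fluence x mu_a(medium at voxel center)."""
    labels = scene.root_labels(spec.center_points())
    mu_a = np.where(
        labels < 0,
        scene.ambient_medium.mu_a,
        np.array([root.medium.mu_a for root in scene.roots] + [0.0])[labels],
    )
    return fluence * mu_a
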