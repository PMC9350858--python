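"""Sphere-tracing optical-depth integration of photon packets.

Two equivalent implementations live here:

- :func:`propagate` -- a readable, instrumentable pure-Python loop used
  for unit tests, debugging and photon-history dumps;
- :func:`run_simulation` -- the batch driver that flattens the scene and
  hands the same algorithm to the jitted kernel.

Both consume random deviates in the same order from the same
counter-based substreams, so a given (seed, photon index) yields the
same history in either path.

Algorithm per packet: draw an optical depth tau = -ln(u); repeatedly
compare the interaction distance tau/mu_t against the sphere-trace step
(the magnitude of the nearest-surface signed distance).  The shorter one
is taken, path length is deposited along every advance, and tau is spent
at rate mu_t per cm.  Within the surface threshold delta_s the packet is
on a boundary: if the refractive index differs across it, Fresnel
reflection or Snell refraction is applied (outcome sampled with
probability R), otherwise the packet is nudged through.  tau is retained
across boundaries.  A packet terminates by absorption (analog survival
with probability = albedo per interaction), by leaving the bounding box,
or at the step cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from . import _kernel
from ._compile import CompiledScene, compile_scene
from .errors import SdfmcError
from .geometry import OpticalMedium, Scene
from .optics import (RandomStream, fresnel_reflectance, hg_cosine,
                     refract_direction, reflect_direction,
                     sample_optical_depth)
from .recording import FluenceGrid
from .sources import SourceSpec

__all__ = ["PhotonPacket", "TerminalEvent", "SimulationResult",
           "propagate", "interact", "cross_boundary", "run_simulation",
           "DEFAULT_STEP_CAP"]

DEFAULT_STEP_CAP = 1_000_000

_EVENT_NAMES = {
    _kernel.EV_ABSORBED: "absorbed",
    _kernel.EV_ESCAPED: "escaped",
    _kernel.EV_STEP_CAP: "step_cap_killed",
    _kernel.EV_BAD_NORMAL: "degenerate_normal_killed",
}


@dataclass
class PhotonPacket:
    position: np.ndarray
    direction: np.ndarray
    weight: float = 1.0
    alive: bool = True
    medium: Optional[OpticalMedium] = None
    n_scatters: int = 0
    tau_remaining: float = 0.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=np.float64)
        d = np.asarray(self.direction, dtype=np.float64)
        self.direction = d / np.linalg.norm(d)


@dataclass
class TerminalEvent:
    kind: str  # absorbed | escaped | step_cap_killed | degenerate_normal_killed
    position: np.ndarray
    direction: np.ndarray
    n_scatters: int


def interact(photon: PhotonPacket, medium: OpticalMedium, stream) -> bool:
    """Resolve an interaction: scatter (True) or absorb (False).

    Scattering happens with probability ``albedo``; the new direction is
    a Henyey-Greenstein polar angle with uniform azimuth rotated about
    the current direction, and a fresh optical depth is drawn.
    """
    if stream.uniform() < medium.albedo:
        cos_t = hg_cosine(medium.g, stream.uniform())
        phi = 2.0 * math.pi * stream.uniform()
        d = photon.direction
        photon.direction = np.array(
            _kernel.rotate_direction(d[0], d[1], d[2], cos_t, phi))
        photon.n_scatters += 1
        photon.tau_remaining = sample_optical_depth(stream.uniform())
        return True
    photon.alive = False
    return False


def cross_boundary(photon: PhotonPacket, scene: Scene, stream,
                   history: Optional[list] = None) -> str:
    """Handle a packet sitting within delta_s of the nearest surface.

    Media on either side are probed at p +/- 2 delta_s along the travel
    direction.  Matched indices pass the packet through; otherwise the
    packet reflects with probability equal to the Fresnel reflectance and
    refracts otherwise, then is nudged 2 delta_s off the surface.  tau is
    retained.  Returns "passed", "reflected" or "refracted".
    """
    from .geometry import surface_normal  # local import to avoid cycle noise

    nudge = 2.0 * scene.surface_threshold
    p = photon.position
    d = photon.direction
    back = p - nudge * d
    fwd = p + nudge * d
    n1 = _probe_index(scene, back)
    n2 = _probe_index(scene, fwd)
    if n1 == n2:
        photon.position = fwd
        photon.medium = _probe_medium(scene, fwd)
        return "passed"
    _, node = scene.scene_distance(p)
    normal = surface_normal(node, p, scene.normal_step)
    if float(d @ normal) > 0.0:
        normal = -normal
    cos_i = float(np.clip(-(d @ normal), 1e-12, 1.0))
    refl = fresnel_reflectance(n1, n2, cos_i)
    if stream.uniform() < refl:
        photon.direction = d + 2.0 * cos_i * normal
        outcome = "reflected"
    else:
        eta = n1 / n2
        cos_t = math.sqrt(1.0 - eta * eta * (1.0 - cos_i * cos_i))
        t = eta * d + (eta * cos_i - cos_t) * normal
        photon.direction = t / np.linalg.norm(t)
        outcome = "refracted"
    photon.direction = photon.direction / np.linalg.norm(photon.direction)
    photon.position = p + nudge * photon.direction
    photon.medium = _probe_medium(scene, photon.position)
    if history is not None:
        history.append((outcome, photon.position.copy(), photon.direction.copy()))
    return outcome


def _probe_medium(scene: Scene, p) -> OpticalMedium:
    if scene.bbox_distance(p) > 0.0:
        return scene.ambient_medium
    return scene.medium_at(p)


def _probe_index(scene: Scene, p) -> float:
    return _probe_medium(scene, p).n


def propagate(photon: PhotonPacket, scene: Scene,
              grid: Optional[FluenceGrid], stream,
              step_cap: int = DEFAULT_STEP_CAP,
              history: Optional[list] = None) -> TerminalEvent:
    """Reference transport loop for a single packet (see module docstring).

    ``history``, when a list, receives (event, position, ...) tuples for
    every advance -- used by regression tests and debug dumps.
    """
    delta_s = scene.surface_threshold
    photon.tau_remaining = sample_optical_depth(stream.uniform())
    photon.medium = _probe_medium(scene, photon.position)
    if history is not None:
        history.append(("launch", photon.position.copy(), photon.direction.copy()))

    def advance(dist: float):
        new_pos = photon.position + dist * photon.direction
        if grid is not None:
            grid.deposit_path(photon.position, new_pos, photon.weight)
        photon.position = new_pos

    for _ in range(step_cap):
        p = photon.position
        if np.any(~np.isfinite(p)) or np.any(~np.isfinite(photon.direction)):
            raise SdfmcError(f"non-finite photon state: {p} {photon.direction} "
                             f"history={history}")
        if scene.bbox_distance(p) > 0.0:
            photon.alive = False
            return TerminalEvent("escaped", p.copy(), photon.direction.copy(),
                                 photon.n_scatters)
        d_sdf, _node = scene.scene_distance(p)
        if d_sdf < delta_s:
            outcome = cross_boundary(photon, scene, stream)
            if grid is not None:
                grid.deposit_path(p, photon.position, photon.weight)
            if history is not None:
                history.append((f"boundary_{outcome}", photon.position.copy(),
                                photon.direction.copy()))
            continue
        medium = _probe_medium(scene, p)
        photon.medium = medium
        mu_t = medium.mu_t
        d_int = photon.tau_remaining / mu_t if mu_t > 0.0 else math.inf
        if d_int <= d_sdf:
            advance(d_int)
            photon.tau_remaining = 0.0
            if history is not None:
                history.append(("interaction", photon.position.copy(),
                                photon.direction.copy()))
            if not interact(photon, medium, stream):
                return TerminalEvent("absorbed", photon.position.copy(),
                                     photon.direction.copy(), photon.n_scatters)
        else:
            advance(d_sdf)
            photon.tau_remaining -= d_sdf * mu_t
            if photon.tau_remaining < 0.0:
                photon.tau_remaining = 0.0
            if history is not None:
                history.append(("march", photon.position.copy(),
                                photon.direction.copy()))
    photon.alive = False
    return TerminalEvent("step_cap_killed", photon.position.copy(),
                         photon.direction.copy(), photon.n_scatters)


# ---------------------------------------------------------------------------
# batch driver


@dataclass
class SimulationResult:
    n_photons: int
    events: np.ndarray       # int8 kernel event codes
    n_scatters: np.ndarray   # int64
    exit_positions: np.ndarray
    exit_directions: np.ndarray
    grid: Optional[FluenceGrid]
    seed: int

    @property
    def counts(self) -> dict:
        return {name: int(np.sum(self.events == code))
                for code, name in _EVENT_NAMES.items()}

    @property
    def n_absorbed(self) -> int:
        return int(np.sum(self.events == _kernel.EV_ABSORBED))

    @property
    def n_escaped(self) -> int:
        return int(np.sum(self.events == _kernel.EV_ESCAPED))

    @property
    def n_step_capped(self) -> int:
        return int(np.sum(self.events == _kernel.EV_STEP_CAP))

    @property
    def mean_scatters(self) -> float:
        return float(self.n_scatters.mean())

    @property
    def se_scatters(self) -> float:
        n = len(self.n_scatters)
        return float(self.n_scatters.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0


def run_simulation(scene: Scene, source: SourceSpec, n_photons: int, seed: int,
                   grid: Optional[FluenceGrid] = None,
                   step_cap: int = DEFAULT_STEP_CAP,
                   compiled: Optional[CompiledScene] = None) -> SimulationResult:
    """Trace ``n_photons`` packets through ``scene`` with the jitted kernel.

    Deterministic for a given (scene, source, n_photons, seed).  When
    ``grid`` is given, weighted path lengths are accumulated into it.
    """
    cs = compiled if compiled is not None else compile_scene(scene)
    if grid is not None:
        acc = grid.accumulator
        o = grid.spec.origin
        s = grid.spec.spacing
        deposit = True
    else:
        acc = np.zeros((1, 1, 1))
        o = tuple(cs.bbox_center - cs.bbox_half)
        s = tuple(2.0 * cs.bbox_half)
        deposit = False
    events, nsc, pos, dirs = _kernel.run_photons(
        n_photons, seed, source.kernel_kind, source.kernel_params,
        cs.kind, cs.params, cs.rot, cs.trans, cs.child,
        cs.root_lo, cs.root_hi, cs.root_layer, cs.root_med, cs.media,
        cs.bbox_center[0], cs.bbox_center[1], cs.bbox_center[2],
        cs.bbox_half[0], cs.bbox_half[1], cs.bbox_half[2],
        acc, o[0], o[1], o[2], s[0], s[1], s[2], deposit,
        cs.delta_s, cs.normal_step, step_cap)
    return SimulationResult(n_photons, events, nsc, pos, dirs, grid, seed)


def trace_single(scene: Scene, position, direction, seed: int, index: int,
                 grid: Optional[FluenceGrid] = None,
                 step_cap: int = DEFAULT_STEP_CAP) -> TerminalEvent:
    """Kernel-path trace of one packet from an explicit launch state.

    Consumes the same substream as :func:`propagate` driven by
    ``RandomStream(seed).substream(index)`` -- used to cross-check the
    two implementations against each other.
    """
    cs = compile_scene(scene)
    state = np.empty(4, dtype=np.uint64)
    _kernel.stream_init(seed, index, state)
    if grid is not None:
        acc = grid.accumulator
        o = grid.spec.origin
        s = grid.spec.spacing
        deposit = True
    else:
        acc = np.zeros((1, 1, 1))
        o = (0.0, 0.0, 0.0)
        s = (1.0, 1.0, 1.0)
        deposit = False
    d = np.asarray(direction, dtype=np.float64)
    d = d / np.linalg.norm(d)
    p = np.asarray(position, dtype=np.float64)
    ev, nsc, x, y, z, ux, uy, uz = _kernel.trace_one(
        p[0], p[1], p[2], d[0], d[1], d[2], state,
        cs.kind, cs.params, cs.rot, cs.trans, cs.child,
        cs.root_lo, cs.root_hi, cs.root_layer, cs.root_med, cs.media,
        cs.bbox_center[0], cs.bbox_center[1], cs.bbox_center[2],
        cs.bbox_half[0], cs.bbox_half[1], cs.bbox_half[2],
        acc, o[0], o[1], o[2], s[0], s[1], s[2], deposit,
        cs.delta_s, cs.normal_step, step_cap, cs.new_scratch())
    return TerminalEvent(_EVENT_NAMES[ev], np.array([x, y, z]),
                         np.array([ux, uy, uz]), int(nsc))
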