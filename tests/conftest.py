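"""Shared fixtures and independent geometric oracles.

The surface-sampling oracle estimates |signed distance| by brute force:
densely sample points on a primitive's surface, build a KD-tree and take
the nearest-neighbour distance.  It shares no code with the package's
distance formulas.
"""

import numpy as np
import pytest
from scipy.spatial import cKDTree


# ---------------------------------------------------------------------------
# brute-force surface samplers (analytic parametrizations, not SDFs)


def sample_sphere_surface(r, n=200_000, seed=0):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * r


def sample_box_surface(he, n_per_face=450, seed=0):
    hx, hy, hz = he
    pts = []
    for axis, (u_half, v_half, w_half) in enumerate(
            [(hy, hz, hx), (hx, hz, hy), (hx, hy, hz)]):
        u = np.linspace(-u_half, u_half, n_per_face)
        v = np.linspace(-v_half, v_half, n_per_face)
        uu, vv = np.meshgrid(u, v)
        for sgn in (-1.0, 1.0):
            face = np.empty((uu.size, 3))
            others = [i for i in range(3) if i != axis]
            face[:, others[0]] = uu.ravel()
            face[:, others[1]] = vv.ravel()
            face[:, axis] = sgn * w_half
            pts.append(face)
    return np.vstack(pts)


def sample_capsule_surface(a, b, r, n=300_000, seed=0):
    rng = np.random.default_rng(seed)
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    axis = b - a
    length = np.linalg.norm(axis)
    axis_u = axis / length
    # orthonormal frame
    tmp = np.array([1.0, 0.0, 0.0])
    if abs(axis_u @ tmp) > 0.9:
        tmp = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis_u, tmp)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis_u, e1)
    n_tube = int(n * length / (length + r))
    t = rng.uniform(0, 1, n_tube)
    phi = rng.uniform(0, 2 * np.pi, n_tube)
    tube = (a[None, :] + np.outer(t, axis)
            + r * (np.outer(np.cos(phi), e1) + np.outer(np.sin(phi), e2)))
    n_cap = (n - n_tube) // 2
    caps = []
    for center, sgn in ((a, -1.0), (b, 1.0)):
        v = rng.normal(size=(n_cap, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        keep = (v @ axis_u) * sgn >= 0
        caps.append(center[None, :] + r * v[keep])
    return np.vstack([tube] + caps)


def sample_cylinder_surface(hh, r, spacing=0.002):
    phi = np.arange(0.0, 2 * np.pi, spacing / r)
    z = np.arange(-hh, hh + spacing, spacing)
    pp, zz = np.meshgrid(phi, z)
    wall = np.column_stack([r * np.cos(pp.ravel()), r * np.sin(pp.ravel()),
                            zz.ravel()])
    caps = []
    radii = np.arange(spacing, r + spacing / 2, spacing)
    for sgn in (-1.0, 1.0):
        ring_pts = []
        for rad in radii:
            ph = np.arange(0.0, 2 * np.pi, spacing / rad)
            ring_pts.append(np.column_stack([
                rad * np.cos(ph), rad * np.sin(ph), np.full(ph.size, sgn * hh)]))
        ring_pts.append(np.array([[0.0, 0.0, sgn * hh]]))
        caps.append(np.vstack(ring_pts))
    return np.vstack([wall] + caps)


def surface_oracle(surface_points):
    """Returns f(points) -> unsigned distances by nearest surface sample."""
    tree = cKDTree(surface_points)

    def dist(points):
        return tree.query(np.atleast_2d(points))[0]

    return dist


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def ray_sphere_entry(p, d, center, r):
    """First (outside->in) intersection parameter of a ray with a sphere."""
    oc = p - center
    b = oc @ d
    disc = b * b - oc @ oc + r * r
    if disc < 0:
        return None
    return -b - np.sqrt(disc)


def snell_refract(d, n, n1, n2):
    """Independent vector-Snell implementation for oracle ray traces."""
    ci = -d @ n
    eta = n1 / n2
    s2 = eta * eta * (1 - ci * ci)
    if s2 >= 1:
        return None  # TIR
    ct = np.sqrt(1 - s2)
    t = eta * d + (eta * ci - ct) * n
    return t / np.linalg.norm(t)


def glass_sphere_tt_oracle(x0, center, r, n_glass, n_out=1.0):
    """Two-interface (transmit-transmit) ray trace of a -z ray at offset
    ``x0`` through a glass sphere; returns (exit point, exit direction)."""
    center = np.asarray(center, float)
    p = np.array([x0, 0.0, center[2] + r + 1.0])
    d = np.array([0.0, 0.0, -1.0])
    t = ray_sphere_entry(p, d, center, r)
    assert t is not None, "oracle ray misses the sphere"
    p1 = p + t * d
    d1 = snell_refract(d, (p1 - center) / r, n_out, n_glass)
    oc = p1 - center
    b = oc @ d1
    t2 = -b + np.sqrt(b * b - oc @ oc + r * r)
    p2 = p1 + t2 * d1
    d2 = snell_refract(d1, -(p2 - center) / r, n_glass, n_out)
    assert d2 is not None
    return p2, d2
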