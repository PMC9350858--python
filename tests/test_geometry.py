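"""Geometry module: primitives, CSG, transforms, normals, scene queries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdfmc.errors import (ConfigError, DegenerateNormalError,
                          OutOfDomainError, ParameterError)
from sdfmc.geometry import (Box, Capsule, Cylinder, GridSpec, Intersection,
                            OpticalMedium, Scene, SmoothUnion, Sphere,
                            Subtraction, Transform, Union, combine, distance_box,
                            distance_capsule, distance_cylinder,
                            distance_sphere, rasterize, rotation_matrix,
                            surface_normal, transform_point)

from conftest import (sample_box_surface, sample_capsule_surface,
                      sample_cylinder_surface, sample_sphere_surface,
                      surface_oracle)

coord = st.floats(-3.0, 3.0, allow_nan=False)
point = st.tuples(coord, coord, coord)


# ---------------------------------------------------------------------------
# primitive examples


class TestPrimitiveExamples:
    def test_sphere_center(self):
        assert distance_sphere((0, 0, 0), 0.5) == pytest.approx(-0.5)

    def test_sphere_on_surface(self):
        assert distance_sphere((0.5, 0, 0), 0.5) == pytest.approx(0.0, abs=1e-12)

    def test_sphere_outside(self):
        assert distance_sphere((3, 4, 0), 1.0) == pytest.approx(4.0)

    def test_sphere_bad_radius(self):
        with pytest.raises(ParameterError):
            distance_sphere((0, 0, 0), 0.0)

    def test_box_center(self):
        assert distance_box((0, 0, 0), (1, 1, 1)) == pytest.approx(-1.0)

    def test_box_face_exterior(self):
        assert distance_box((2, 0, 0), (1, 1, 1)) == pytest.approx(1.0)

    def test_box_edge_exterior(self):
        # frozen from the surface-sampling oracle: min distance from
        # (2, 2, 0) to the unit-half cube surface is sqrt(2)
        assert distance_box((2, 2, 0), (1, 1, 1)) == pytest.approx(np.sqrt(2.0))

    def test_box_bad_extent(self):
        with pytest.raises(ParameterError):
            distance_box((0, 0, 0), (1, -1, 1))

    def test_capsule_endpoint(self):
        assert distance_capsule((0, 0, 0), (0, 0, 0), (1, 0, 0), 0.25) == \
            pytest.approx(-0.25)

    def test_capsule_midpoint(self):
        assert distance_capsule((0.5, 0, 0), (0, 0, 0), (1, 0, 0), 0.1) == \
            pytest.approx(-0.1)

    def test_capsule_degenerate(self):
        with pytest.raises(ParameterError):
            distance_capsule((0, 0, 0), (1, 1, 1), (1, 1, 1), 0.1)

    def test_cylinder_center(self):
        assert distance_cylinder((0, 0, 0), 0.4, 0.7) == pytest.approx(-0.4)
        assert distance_cylinder((0, 0, 0), 0.9, 0.6) == pytest.approx(-0.6)

    def test_cylinder_on_wall(self):
        assert distance_cylinder((0.7, 0, 0.1), 0.4, 0.7) == \
            pytest.approx(0.0, abs=1e-12)

    def test_cylinder_bad_params(self):
        with pytest.raises(ParameterError):
            distance_cylinder((0, 0, 0), -1.0, 1.0)


# ---------------------------------------------------------------------------
# surface-sampling oracle agreement


class TestSurfaceOracle:
    N_QUERY = 150

    def _check(self, dist_fn, surface_pts, rng, lo=-1.5, hi=1.5, min_abs=0.05):
        oracle = surface_oracle(surface_pts)
        pts = rng.uniform(lo, hi, size=(self.N_QUERY, 3))
        d = np.abs(dist_fn(pts))
        keep = d > min_abs  # oracle sampling error blows up only near zero
        assert keep.sum() > 50
        err = np.abs(d[keep] - oracle(pts[keep]))
        assert err.max() < 1e-4

    def test_sphere(self, rng):
        self._check(lambda p: distance_sphere(p, 0.6),
                    sample_sphere_surface(0.6), rng)

    def test_box(self, rng):
        he = (0.5, 0.35, 0.6)
        self._check(lambda p: distance_box(p, he),
                    sample_box_surface(he, n_per_face=700), rng)

    def test_capsule(self, rng):
        a, b, r = (-0.3, -0.1, -0.2), (0.4, 0.2, 0.3), 0.2
        self._check(lambda p: distance_capsule(p, a, b, r),
                    sample_capsule_surface(a, b, r), rng)

    def test_cylinder(self, rng):
        self._check(lambda p: distance_cylinder(p, 0.5, 0.35),
                    sample_cylinder_surface(0.5, 0.35), rng)


# ---------------------------------------------------------------------------
# sign convention / Lipschitz / eikonal properties


PRIMITIVES = [
    Sphere(0.7),
    Box((0.8, 0.5, 0.6)),
    Capsule((-0.4, 0, 0), (0.4, 0.1, 0.2), 0.3),
    Cylinder(0.6, 0.45),
]


def _interior_points(node, rng, n=200):
    """Construct strictly interior points from each primitive's own
    parametrization (independent of the SDF being tested)."""
    u = rng.uniform(size=n)
    dirs = rng.normal(size=(n, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    if isinstance(node, Sphere):
        return dirs * (0.9 * node.radius * u[:, None])
    if isinstance(node, Box):
        return rng.uniform(-0.9, 0.9, size=(n, 3)) * node.half_extents
    if isinstance(node, Capsule):
        t = rng.uniform(size=(n, 1))
        axis_pts = node.a + t * (node.b - node.a)
        return axis_pts + dirs * (0.9 * node.radius * u[:, None])
    if isinstance(node, Cylinder):
        rad = 0.9 * node.radius * np.sqrt(u)
        phi = rng.uniform(0, 2 * np.pi, n)
        z = rng.uniform(-0.9, 0.9, n) * node.half_height
        return np.column_stack([rad * np.cos(phi), rad * np.sin(phi), z])
    raise AssertionError(node)


@pytest.mark.parametrize("node", PRIMITIVES, ids=lambda n: n.kind)
def test_sign_convention(node, rng):
    inside = _interior_points(node, rng)
    assert np.all(node.distance(inside) < 0)
    far = rng.uniform(2.0, 3.0, size=(200, 3)) * rng.choice([-1, 1], size=(200, 3))
    assert np.all(node.distance(far) > 0)


@pytest.mark.parametrize("node", PRIMITIVES, ids=lambda n: n.kind)
def test_on_surface_zero(node, rng):
    # walk from an interior point to the surface by bisection on the SDF,
    # then confirm |D| ~ 0 there
    for _ in range(20):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        lo, hi = 0.0, 5.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if node.distance(mid * direction) < 0:
                lo = mid
            else:
                hi = mid
        assert abs(node.distance(0.5 * (lo + hi) * direction)) < 1e-9


@settings(max_examples=150, deadline=None)
@given(p=point, q=point)
def test_lipschitz_primitives(p, q):
    p = np.array(p)
    q = np.array(q)
    gap = np.linalg.norm(p - q)
    for node in PRIMITIVES:
        assert abs(float(node.distance(p)) - float(node.distance(q))) <= gap + 1e-12


@settings(max_examples=100, deadline=None)
@given(p=point, q=point)
def test_lipschitz_smooth_union(p, q):
    node = SmoothUnion(Sphere(0.5), Transform(Sphere(0.4),
                                              translation=(0.6, 0, 0)), k=0.2)
    p = np.array(p)
    q = np.array(q)
    gap = np.linalg.norm(p - q)
    assert abs(float(node.distance(p)) - float(node.distance(q))) <= gap + 1e-6


@pytest.mark.parametrize("node", PRIMITIVES, ids=lambda n: n.kind)
def test_eikonal(node, rng):
    h = 1e-5
    pts = rng.uniform(-1.2, 1.2, size=(300, 3))
    # exclude medial-axis neighbourhoods: keep points where the gradient is
    # stable under a small shift
    grads = []
    for p in pts:
        g = np.array([
            (float(node.distance(p + h * e)) - float(node.distance(p - h * e)))
            / (2 * h)
            for e in np.eye(3)
        ])
        grads.append(np.linalg.norm(g))
    grads = np.array(grads)
    # off the medial axis |grad| = 1; on it the magnitude drops below 1
    near_axis = grads < 1 - 1e-3
    assert near_axis.mean() < 0.2
    assert np.all(np.abs(grads[~near_axis] - 1.0) < 1e-4)


# ---------------------------------------------------------------------------
# CSG


class TestCombine:
    def test_union(self):
        assert combine("union", -1.0, 2.0) == -1.0

    def test_subtraction(self):
        assert combine("subtraction", -1.0, -2.0) == 2.0

    def test_intersection(self):
        assert combine("intersection", -1.0, 2.0) == 2.0

    def test_smooth_union_below_min(self):
        # closed form: h = max(k - |d1 - d2|, 0)/k, smin = min - h^2 k / 4
        v = combine("smooth_union", 0.5, 0.5, k=0.1)
        assert v < 0.5
        assert v == pytest.approx(0.5 - 0.1 / 4.0)

    def test_smooth_union_reduces_to_min(self):
        assert combine("smooth_union", 0.0, 0.5, k=0.1) == 0.0

    def test_smooth_union_needs_k(self):
        with pytest.raises(ParameterError):
            combine("smooth_union", 0.0, 0.5)

    def test_unknown_kind(self):
        with pytest.raises(ParameterError):
            combine("xor", 0.0, 0.5)

    def test_csg_bounds(self, rng):
        a = Sphere(0.5)
        b = Transform(Sphere(0.45), translation=(0.4, 0.1, 0))
        for p in rng.uniform(-1.5, 1.5, size=(100, 3)):
            da = float(a.distance(p))
            db = float(b.distance(p))
            assert float(Union(a, b).distance(p)) == min(da, db)
            assert float(Intersection(a, b).distance(p)) >= max(da, db) - 1e-15
            smooth = SmoothUnion(a, b, k=0.1)
            assert float(smooth.distance(p)) <= min(da, db) + 1e-15


# ---------------------------------------------------------------------------
# transforms


class TestTransform:
    def test_identity(self):
        p = np.array([0.3, -0.2, 0.9])
        assert np.allclose(transform_point(p, np.eye(3), (0, 0, 0)), p)

    def test_translation_equivalence(self):
        p = np.array([1.2, 0.3, -0.5])
        t = np.array([0.4, -0.1, 0.2])
        assert distance_sphere(transform_point(p, np.eye(3), t), 0.5) == \
            pytest.approx(float(distance_sphere(p - t, 0.5)))

    def test_z_rotation_convention(self):
        # placement rotation of +90 deg about z maps the local +x axis to
        # world +y; the inverse map sends world (1,0,0) to local (0,-1,0)
        rot = rotation_matrix((0, 0, 1), 90.0)
        assert np.linalg.det(rot) == pytest.approx(1.0)
        q = transform_point((1.0, 0.0, 0.0), rot, (0, 0, 0))
        assert np.allclose(q, (0.0, -1.0, 0.0), atol=1e-12)

    def test_non_orthonormal_rejected(self):
        with pytest.raises(ParameterError):
            transform_point((1, 0, 0), np.diag([2.0, 1.0, 1.0]), (0, 0, 0))

    def test_rigid_preserves_distance(self, rng):
        rot = rotation_matrix((1, 2, 3), 37.0)
        node = Transform(Box((0.5, 0.4, 0.3)), rotation=rot,
                         translation=(0.2, -0.1, 0.4))
        base = Box((0.5, 0.4, 0.3))
        for p in rng.uniform(-1, 1, size=(50, 3)):
            local = rot.T @ (p - np.array([0.2, -0.1, 0.4]))
            assert float(node.distance(p)) == pytest.approx(
                float(base.distance(local)), abs=1e-12)


# ---------------------------------------------------------------------------
# normals


class TestSurfaceNormal:
    def test_sphere_radial(self):
        n = surface_normal(Sphere(1.0), (1.0, 0.0, 0.0))
        assert np.allclose(n, (1, 0, 0), atol=1e-9)
        n = surface_normal(Sphere(1.0), (0.0, -1.0, 0.0))
        assert np.allclose(n, (0, -1, 0), atol=1e-9)

    def test_box_face(self):
        n = surface_normal(Box((1, 1, 1)), (0.3, -0.2, 1.0))
        assert np.allclose(n, (0, 0, 1), atol=1e-6)

    def test_unit_length(self, rng):
        node = Capsule((-0.3, 0, 0), (0.3, 0, 0), 0.2)
        for _ in range(50):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            p = np.array([0.3, 0, 0]) + 0.2 * v  # on an end cap
            n = surface_normal(node, p)
            assert abs(np.linalg.norm(n) - 1.0) < 1e-12

    def test_analytic_sphere_agreement(self, rng):
        for _ in range(30):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            n = surface_normal(Sphere(0.8), 0.8 * v)
            assert np.linalg.norm(n - v) < 1e-5

    def test_degenerate_normal(self):
        with pytest.raises(DegenerateNormalError):
            surface_normal(Sphere(1.0), (0.0, 0.0, 0.0))


# ---------------------------------------------------------------------------
# scene queries


def _simple_scene():
    m = OpticalMedium(mu_s=1.0, mu_a=0.1, g=0.0, n=1.4)
    return Scene([Sphere(0.5, medium=m)], bbox_center=(0, 0, 0),
                 bbox_half_extents=(2, 2, 2))


class TestScene:
    def test_scene_distance_outside(self):
        scene = _simple_scene()
        d, node = scene.scene_distance((2, 0, 0))
        assert d == pytest.approx(1.5)
        assert node is scene.roots[0]

    def test_scene_distance_inside_magnitude(self):
        scene = _simple_scene()
        d, _ = scene.scene_distance((0, 0, 0))
        assert d == pytest.approx(0.5)

    def test_two_spheres_nearer_wins(self, rng):
        m = OpticalMedium(n=1.2)
        s1 = Transform(Sphere(0.3), translation=(-0.6, 0, 0))
        s1.medium = m
        s2 = Transform(Sphere(0.3), translation=(0.6, 0, 0))
        s2.medium = m
        scene = Scene([s1, s2], bbox_center=(0, 0, 0), bbox_half_extents=(2, 2, 2))
        for p in rng.uniform(-1.5, 1.5, size=(50, 3)):
            d, node = scene.scene_distance(p)
            brute = min(abs(float(s1.distance(p))), abs(float(s2.distance(p))))
            assert d == pytest.approx(brute)

    def test_empty_scene_rejected(self):
        with pytest.raises(ConfigError):
            Scene([], bbox_center=(0, 0, 0), bbox_half_extents=(1, 1, 1))

    def test_root_needs_medium(self):
        with pytest.raises(ConfigError):
            Scene([Sphere(0.5)], bbox_center=(0, 0, 0), bbox_half_extents=(1, 1, 1))


class TestMediumAt:
    def _nested(self):
        tissue = OpticalMedium(mu_s=100, mu_a=0.5, g=0.9, n=1.38)
        vessel = OpticalMedium(mu_s=90, mu_a=200, g=0.9, n=1.38)
        box = Box((1, 1, 1), medium=tissue, layer=0)
        cap = Capsule((-0.5, 0, 0), (0.5, 0, 0), 0.1, medium=vessel, layer=1)
        return Scene([box, cap], bbox_center=(0, 0, 0),
                     bbox_half_extents=(1.5, 1.5, 1.5)), tissue, vessel

    def test_vessel_wins_inside_capsule(self):
        scene, tissue, vessel = self._nested()
        assert scene.medium_at((0, 0, 0)) is vessel

    def test_tissue_elsewhere(self):
        scene, tissue, vessel = self._nested()
        assert scene.medium_at((0, 0.5, 0.5)) is tissue

    def test_ambient_in_gap(self):
        scene, _, _ = self._nested()
        assert scene.medium_at((0, 1.3, 0)) is scene.ambient_medium

    def test_outside_bbox_raises(self):
        scene, _, _ = self._nested()
        with pytest.raises(OutOfDomainError):
            scene.medium_at((0, 0, 5.0))


class TestRasterize:
    def test_sphere_volume_fraction(self):
        m = OpticalMedium(n=1.4)
        scene = Scene([Sphere(0.5, medium=m)], bbox_center=(0, 0, 0),
                      bbox_half_extents=(1, 1, 1))
        grid = GridSpec(dims=(100, 100, 100), origin=(-1, -1, -1),
                        spacing=(0.02, 0.02, 0.02))
        labels = rasterize(scene, grid)
        vol = np.sum(labels == 0) * grid.voxel_volume
        analytic = 4.0 / 3.0 * np.pi * 0.5 ** 3
        assert vol == pytest.approx(analytic, rel=0.01)

    def test_nested_layers(self):
        tissue = OpticalMedium(n=1.38)
        vessel = OpticalMedium(n=1.38, mu_a=1.0)
        box = Box((0.8, 0.8, 0.8), medium=tissue, layer=0)
        sph = Sphere(0.2, medium=vessel, layer=1)
        scene = Scene([box, sph], bbox_center=(0, 0, 0),
                      bbox_half_extents=(1, 1, 1))
        grid = GridSpec(dims=(40, 40, 40), origin=(-1, -1, -1),
                        spacing=(0.05, 0.05, 0.05))
        labels = rasterize(scene, grid)
        center = labels[20, 20, 20]
        assert center == 1  # inner shape wins
        assert labels[2, 2, 2] == -1  # ambient corner

    def test_grid_must_fit_bbox(self):
        scene = _simple_scene()
        grid = GridSpec(dims=(10, 10, 10), origin=(-3, -3, -3),
                        spacing=(0.6, 0.6, 0.6))
        with pytest.raises(ConfigError):
            rasterize(scene, grid)


def test_compiled_scene_matches_python(rng):
    """The flattened kernel evaluation must agree with the class tree."""
    from sdfmc._compile import compile_scene
    glass = OpticalMedium(n=1.5)
    water = OpticalMedium(mu_s=2.5, mu_a=0.01, g=0.7, n=1.3)
    rot = rotation_matrix((0, 1, 0), 30.0)
    shell = Subtraction(Cylinder(1.0, 0.6), Cylinder(1.01, 0.5))
    shell.medium = glass
    blob = SmoothUnion(Sphere(0.3),
                       Transform(Sphere(0.25), rotation=rot,
                                 translation=(0.5, 0.2, -0.1)), k=0.15)
    blob.medium = water
    blob.layer = 2
    scene = Scene([shell, blob], bbox_center=(0, 0, 0),
                  bbox_half_extents=(2, 2, 2))
    cs = compile_scene(scene)
    for p in rng.uniform(-1.8, 1.8, size=(200, 3)):
        d_abs, arg, med, d_signed = cs.query(p)
        brute, node = scene.scene_distance(p)
        assert d_abs == pytest.approx(brute, abs=1e-12)
        assert scene.roots[arg] is node
        expected_medium = scene.medium_at(p)
        got = (scene.ambient_medium if med == 0
               else scene.roots[int(np.argmax(cs.root_med == med))].medium)
        assert got is expected_medium
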