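"""Numba-compiled numerical core.

Scalar primitives, a counter-based per-photon RNG, flattened-scene SDF
evaluation, voxel-traversal path deposition and the sphere-tracing
transport loop.  Everything here operates on plain scalars / ndarrays so
it can be JIT compiled; the public modules wrap these functions with
validated, documented interfaces.

Scene flattening convention (see ``_compile.py``): all nodes of all root
trees are concatenated in post-order (children before parents).  Leaf
nodes carry a folded world->local rigid transform ``q = A p + b``; CSG
nodes combine the scalar distances of their children.
"""

import math

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# node kind codes (leaves < 10, combinators >= 10)
KIND_SPHERE = 0
KIND_BOX = 1
KIND_CAPSULE = 2
KIND_CYLINDER = 3
KIND_UNION = 10
KIND_SMOOTH_UNION = 11
KIND_INTERSECTION = 12
KIND_SUBTRACTION = 13

# terminal event codes
EV_ABSORBED = 0
EV_ESCAPED = 1
EV_STEP_CAP = 2
EV_BAD_NORMAL = 3

# source kind codes
SRC_ISOTROPIC_POINT = 0
SRC_RECT_BEAM = 1

_BIG = 1.0e30

# ---------------------------------------------------------------------------
# RNG: xoshiro256++ with splitmix64 stream initialisation.  One statistically
# independent substream per (seed, photon index) pair so results do not
# depend on scheduling.

_U30 = np.uint64(30)
_U27 = np.uint64(27)
_U31 = np.uint64(31)
_U11 = np.uint64(11)
_U17 = np.uint64(17)
_U23 = np.uint64(23)
_U41 = np.uint64(41)
_U45 = np.uint64(45)
_U19 = np.uint64(19)
_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)
_STREAM_SALT = np.uint64(0xD1B54A32D192ED03)
_INV53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(cache=True)
def stream_init(seed, index, state):
    """Fill ``state`` (uint64[4]) for photon ``index`` under ``seed``."""
    z = (np.uint64(seed) * _STREAM_SALT) ^ (np.uint64(index) * _GAMMA)
    nonzero = False
    for i in range(4):
        z = z + _GAMMA
        x = z
        x = (x ^ (x >> _U30)) * _MIX1
        x = (x ^ (x >> _U27)) * _MIX2
        x = x ^ (x >> _U31)
        state[i] = x
        if x != np.uint64(0):
            nonzero = True
    if not nonzero:  # pragma: no cover - probability ~2**-256
        state[0] = np.uint64(1)


@njit(cache=True)
def _next_u64(state):
    s0 = state[0]
    s3 = state[3]
    x = s0 + s3
    result = ((x << _U23) | (x >> _U41)) + s0
    t = state[1] << _U17
    state[2] ^= state[0]
    state[3] ^= state[1]
    state[1] ^= state[2]
    state[0] ^= state[3]
    state[2] ^= t
    s3 = state[3]
    state[3] = (s3 << _U45) | (s3 >> _U19)
    return result


@njit(cache=True)
def next_uniform(state):
    """Uniform deviate on the half-open interval (0, 1]."""
    return (np.float64(_next_u64(state) >> _U11) + 1.0) * _INV53


@njit(cache=True)
def bulk_uniforms(seed, index, n):
    """n uniforms on (0, 1] from the (seed, index) substream."""
    state = np.empty(4, dtype=np.uint64)
    stream_init(seed, index, state)
    out = np.empty(n, dtype=np.float64)
    for i in range(n):
        out[i] = next_uniform(state)
    return out


# ---------------------------------------------------------------------------
# primitive signed distances (scalar, local frame)


@njit(cache=True, inline="always")
def d_sphere(x, y, z, r):
    return math.sqrt(x * x + y * y + z * z) - r


@njit(cache=True, inline="always")
def d_box(x, y, z, hx, hy, hz):
    qx = abs(x) - hx
    qy = abs(y) - hy
    qz = abs(z) - hz
    ox = qx if qx > 0.0 else 0.0
    oy = qy if qy > 0.0 else 0.0
    oz = qz if qz > 0.0 else 0.0
    outside = math.sqrt(ox * ox + oy * oy + oz * oz)
    m = qx
    if qy > m:
        m = qy
    if qz > m:
        m = qz
    inside = m if m < 0.0 else 0.0
    return outside + inside


@njit(cache=True, inline="always")
def d_capsule(x, y, z, ax, ay, az, bx, by, bz, r):
    pax = x - ax
    pay = y - ay
    paz = z - az
    bax = bx - ax
    bay = by - ay
    baz = bz - az
    h = (pax * bax + pay * bay + paz * baz) / (bax * bax + bay * bay + baz * baz)
    if h < 0.0:
        h = 0.0
    elif h > 1.0:
        h = 1.0
    dx = pax - bax * h
    dy = pay - bay * h
    dz = paz - baz * h
    return math.sqrt(dx * dx + dy * dy + dz * dz) - r


@njit(cache=True, inline="always")
def d_cylinder(x, y, z, half_height, r):
    dr = math.sqrt(x * x + y * y) - r
    dz = abs(z) - half_height
    mx = dr if dr > dz else dz
    inside = mx if mx < 0.0 else 0.0
    or_ = dr if dr > 0.0 else 0.0
    oz = dz if dz > 0.0 else 0.0
    return inside + math.sqrt(or_ * or_ + oz * oz)


@njit(cache=True, inline="always")
def smooth_min(d1, d2, k):
    h = (k - abs(d1 - d2)) / k
    if h < 0.0:
        h = 0.0
    m = d1 if d1 < d2 else d2
    return m - h * h * k * 0.25


# ---------------------------------------------------------------------------
# flattened-scene evaluation


@njit(cache=True)
def eval_root(kind, params, rot, trans, child, lo, hi, px, py, pz, scratch):
    """Signed distance of the root tree stored in nodes [lo, hi]."""
    for i in range(lo, hi + 1):
        k = kind[i]
        if k < 10:
            qx = rot[i, 0, 0] * px + rot[i, 0, 1] * py + rot[i, 0, 2] * pz + trans[i, 0]
            qy = rot[i, 1, 0] * px + rot[i, 1, 1] * py + rot[i, 1, 2] * pz + trans[i, 1]
            qz = rot[i, 2, 0] * px + rot[i, 2, 1] * py + rot[i, 2, 2] * pz + trans[i, 2]
            if k == KIND_SPHERE:
                scratch[i] = d_sphere(qx, qy, qz, params[i, 0])
            elif k == KIND_BOX:
                scratch[i] = d_box(qx, qy, qz, params[i, 0], params[i, 1], params[i, 2])
            elif k == KIND_CAPSULE:
                scratch[i] = d_capsule(
                    qx, qy, qz,
                    params[i, 0], params[i, 1], params[i, 2],
                    params[i, 3], params[i, 4], params[i, 5],
                    params[i, 6],
                )
            else:
                scratch[i] = d_cylinder(qx, qy, qz, params[i, 0], params[i, 1])
        else:
            d1 = scratch[child[i, 0]]
            d2 = scratch[child[i, 1]]
            if k == KIND_UNION:
                scratch[i] = d1 if d1 < d2 else d2
            elif k == KIND_SMOOTH_UNION:
                scratch[i] = smooth_min(d1, d2, params[i, 0])
            elif k == KIND_INTERSECTION:
                scratch[i] = d1 if d1 > d2 else d2
            else:  # subtraction: d1 minus d2
                scratch[i] = d1 if d1 > -d2 else -d2
    return scratch[hi]


@njit(cache=True)
def scene_query(kind, params, rot, trans, child, root_lo, root_hi,
                root_layer, root_med, px, py, pz, scratch):
    """Nearest-surface magnitude, arg-min root and medium index at a point.

    Returns (d_abs_min, argmin_root, medium_index, signed_d_of_argmin).
    Medium index 0 is the ambient medium; roots are resolved by highest
    layer, first-declared winning ties.
    """
    n_roots = root_lo.shape[0]
    d_abs = _BIG
    arg = -1
    d_signed = _BIG
    best_layer = -2147483647
    med = 0
    for r in range(n_roots):
        d = eval_root(kind, params, rot, trans, child,
                      root_lo[r], root_hi[r], px, py, pz, scratch)
        ad = abs(d)
        if ad < d_abs:
            d_abs = ad
            arg = r
            d_signed = d
        if d < 0.0 and root_layer[r] > best_layer:
            best_layer = root_layer[r]
            med = root_med[r]
    return d_abs, arg, med, d_signed


@njit(cache=True)
def root_normal(kind, params, rot, trans, child, root_lo, root_hi,
                r_idx, px, py, pz, h, scratch):
    """Central-difference outward normal of one root SDF; returns
    (nx, ny, nz, gradient_norm)."""
    lo = root_lo[r_idx]
    hi = root_hi[r_idx]
    gx = (eval_root(kind, params, rot, trans, child, lo, hi, px + h, py, pz, scratch)
          - eval_root(kind, params, rot, trans, child, lo, hi, px - h, py, pz, scratch))
    gy = (eval_root(kind, params, rot, trans, child, lo, hi, px, py + h, pz, scratch)
          - eval_root(kind, params, rot, trans, child, lo, hi, px, py - h, pz, scratch))
    gz = (eval_root(kind, params, rot, trans, child, lo, hi, px, py, pz + h, scratch)
          - eval_root(kind, params, rot, trans, child, lo, hi, px, py, pz - h, scratch))
    norm = math.sqrt(gx * gx + gy * gy + gz * gz)
    if norm == 0.0:
        return 0.0, 0.0, 0.0, 0.0
    return gx / norm, gy / norm, gz / norm, norm / (2.0 * h)


# ---------------------------------------------------------------------------
# boundary physics


@njit(cache=True, inline="always")
def fresnel_unpolarized(n1, n2, cos_i):
    """Unpolarized Fresnel intensity reflectance; 1.0 under TIR."""
    eta = n1 / n2
    sin_t2 = eta * eta * (1.0 - cos_i * cos_i)
    if sin_t2 >= 1.0:
        return 1.0
    cos_t = math.sqrt(1.0 - sin_t2)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, inline="always")
def hg_cos(g, u):
    """Henyey-Greenstein scattering cosine from a uniform deviate."""
    if abs(g) < 1.0e-6:
        return 2.0 * u - 1.0
    f = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    c = (1.0 + g * g - f * f) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(cache=True, inline="always")
def rotate_direction(ux, uy, uz, cos_t, phi):
    """Rotate a unit vector by polar angle acos(cos_t), azimuth phi."""
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    cos_p = math.cos(phi)
    sin_p = math.sin(phi)
    if abs(uz) > 0.999999:
        nx = sin_t * cos_p
        ny = sin_t * sin_p
        nz = cos_t if uz > 0.0 else -cos_t
    else:
        tmp = math.sqrt(1.0 - uz * uz)
        nx = sin_t * (ux * uz * cos_p - uy * sin_p) / tmp + ux * cos_t
        ny = sin_t * (uy * uz * cos_p + ux * sin_p) / tmp + uy * cos_t
        nz = -sin_t * cos_p * tmp + uz * cos_t
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


# ---------------------------------------------------------------------------
# voxel path deposition (Amanatides-Woo traversal, exact splitting)


@njit(cache=True)
def deposit_segment(acc, ox, oy, oz, sx, sy, sz,
                    x0, y0, z0, x1, y1, z1, w):
    """Add ``w *`` (sub-segment length) to every voxel the segment crosses.

    ``acc`` is the (nx, ny, nz) accumulator; the part of the segment
    outside the grid is dropped.  The total deposited equals ``w`` times
    the in-grid length exactly (up to fp rounding).
    """
    nx = acc.shape[0]
    ny = acc.shape[1]
    nz = acc.shape[2]
    ex = x1 - x0
    ey = y1 - y0
    ez = z1 - z0
    length = math.sqrt(ex * ex + ey * ey + ez * ez)
    if length == 0.0:
        return
    dx = ex / length
    dy = ey / length
    dz = ez / length
    # clip [0, length] against the grid box
    tmin = 0.0
    tmax = length
    lox = ox
    hix = ox + nx * sx
    if dx != 0.0:
        ta = (lox - x0) / dx
        tb = (hix - x0) / dx
        if ta > tb:
            ta, tb = tb, ta
        if ta > tmin:
            tmin = ta
        if tb < tmax:
            tmax = tb
    elif x0 < lox or x0 > hix:
        return
    loy = oy
    hiy = oy + ny * sy
    if dy != 0.0:
        ta = (loy - y0) / dy
        tb = (hiy - y0) / dy
        if ta > tb:
            ta, tb = tb, ta
        if ta > tmin:
            tmin = ta
        if tb < tmax:
            tmax = tb
    elif y0 < loy or y0 > hiy:
        return
    loz = oz
    hiz = oz + nz * sz
    if dz != 0.0:
        ta = (loz - z0) / dz
        tb = (hiz - z0) / dz
        if ta > tb:
            ta, tb = tb, ta
        if ta > tmin:
            tmin = ta
        if tb < tmax:
            tmax = tb
    elif z0 < loz or z0 > hiz:
        return
    if tmax <= tmin:
        return
    # entry voxel
    cx = x0 + dx * tmin
    cy = y0 + dy * tmin
    cz = z0 + dz * tmin
    ix = int(math.floor((cx - ox) / sx))
    iy = int(math.floor((cy - oy) / sy))
    iz = int(math.floor((cz - oz) / sz))
    if ix < 0:
        ix = 0
    elif ix > nx - 1:
        ix = nx - 1
    if iy < 0:
        iy = 0
    elif iy > ny - 1:
        iy = ny - 1
    if iz < 0:
        iz = 0
    elif iz > nz - 1:
        iz = nz - 1
    # stepping setup
    if dx > 0.0:
        step_x = 1
        t_max_x = ((ox + (ix + 1) * sx) - x0) / dx
        t_dx = sx / dx
    elif dx < 0.0:
        step_x = -1
        t_max_x = ((ox + ix * sx) - x0) / dx
        t_dx = -sx / dx
    else:
        step_x = 0
        t_max_x = _BIG
        t_dx = _BIG
    if dy > 0.0:
        step_y = 1
        t_max_y = ((oy + (iy + 1) * sy) - y0) / dy
        t_dy = sy / dy
    elif dy < 0.0:
        step_y = -1
        t_max_y = ((oy + iy * sy) - y0) / dy
        t_dy = -sy / dy
    else:
        step_y = 0
        t_max_y = _BIG
        t_dy = _BIG
    if dz > 0.0:
        step_z = 1
        t_max_z = ((oz + (iz + 1) * sz) - z0) / dz
        t_dz = sz / dz
    elif dz < 0.0:
        step_z = -1
        t_max_z = ((oz + iz * sz) - z0) / dz
        t_dz = -sz / dz
    else:
        step_z = 0
        t_max_z = _BIG
        t_dz = _BIG
    t = tmin
    while True:
        tn = t_max_x
        axis = 0
        if t_max_y < tn:
            tn = t_max_y
            axis = 1
        if t_max_z < tn:
            tn = t_max_z
            axis = 2
        if tn >= tmax:
            if tmax > t:
                acc[ix, iy, iz] += w * (tmax - t)
            return
        if tn > t:
            acc[ix, iy, iz] += w * (tn - t)
        t = tn
        if axis == 0:
            ix += step_x
            t_max_x += t_dx
            if ix < 0 or ix >= nx:
                return
        elif axis == 1:
            iy += step_y
            t_max_y += t_dy
            if iy < 0 or iy >= ny:
                return
        else:
            iz += step_z
            t_max_z += t_dz
            if iz < 0 or iz >= nz:
                return


# ---------------------------------------------------------------------------
# transport loop


@njit(cache=True)
def trace_one(px, py, pz, dx, dy, dz, state,
              kind, params, rot, trans, child, root_lo, root_hi,
              root_layer, root_med, media,
              bcx, bcy, bcz, bhx, bhy, bhz,
              acc, gox, goy, goz, gsx, gsy, gsz, do_deposit,
              delta_s, h_norm, step_cap, scratch):
    """Sphere-tracing optical-depth integration for one packet.

    Returns (event_code, n_scatters, x, y, z, ux, uy, uz).
    RNG consumption order (must match the pure-Python reference loop):
    initial tau; at an index-mismatched boundary one deviate for the
    reflect/refract choice; at an interaction one deviate for the
    scatter/absorb choice, then (if scattering) cos-theta, azimuth and a
    fresh tau.
    """
    tau = -math.log(next_uniform(state))
    n_sc = 0
    nudge = 2.0 * delta_s
    for _ in range(step_cap):
        # (5) outside the bounding box -> escaped
        if d_box(px - bcx, py - bcy, pz - bcz, bhx, bhy, bhz) > 0.0:
            return EV_ESCAPED, n_sc, px, py, pz, dx, dy, dz
        d_abs, arg, med_i, _ds = scene_query(
            kind, params, rot, trans, child, root_lo, root_hi,
            root_layer, root_med, px, py, pz, scratch)
        # (6) on a surface -> boundary handling
        if d_abs < delta_s and arg >= 0:
            bx = px - nudge * dx
            by = py - nudge * dy
            bz = pz - nudge * dz
            fx = px + nudge * dx
            fy = py + nudge * dy
            fz = pz + nudge * dz
            _, _, med_b, _ = scene_query(kind, params, rot, trans, child,
                                         root_lo, root_hi, root_layer,
                                         root_med, bx, by, bz, scratch)
            _, _, med_f, _ = scene_query(kind, params, rot, trans, child,
                                         root_lo, root_hi, root_layer,
                                         root_med, fx, fy, fz, scratch)
            n1 = media[med_b, 3]
            n2 = media[med_f, 3]
            if n1 == n2:
                # index matched: nudge through
                if do_deposit:
                    deposit_segment(acc, gox, goy, goz, gsx, gsy, gsz,
                                    px, py, pz, fx, fy, fz, 1.0)
                px = fx
                py = fy
                pz = fz
            else:
                nnx, nny, nnz, grad = root_normal(
                    kind, params, rot, trans, child, root_lo, root_hi,
                    arg, px, py, pz, h_norm, scratch)
                if grad < 1.0e-8:
                    return EV_BAD_NORMAL, n_sc, px, py, pz, dx, dy, dz
                dot = dx * nnx + dy * nny + dz * nnz
                if dot > 0.0:
                    nnx = -nnx
                    nny = -nny
                    nnz = -nnz
                    dot = -dot
                cos_i = -dot
                if cos_i > 1.0:
                    cos_i = 1.0
                elif cos_i < 1.0e-12:
                    cos_i = 1.0e-12
                refl = fresnel_unpolarized(n1, n2, cos_i)
                if next_uniform(state) < refl:
                    # specular reflection
                    dx = dx + 2.0 * cos_i * nnx
                    dy = dy + 2.0 * cos_i * nny
                    dz = dz + 2.0 * cos_i * nnz
                else:
                    eta = n1 / n2
                    cos_t = math.sqrt(1.0 - eta * eta * (1.0 - cos_i * cos_i))
                    f = eta * cos_i - cos_t
                    dx = eta * dx + f * nnx
                    dy = eta * dy + f * nny
                    dz = eta * dz + f * nnz
                norm = math.sqrt(dx * dx + dy * dy + dz * dz)
                dx /= norm
                dy /= norm
                dz /= norm
                fx = px + nudge * dx
                fy = py + nudge * dy
                fz = pz + nudge * dz
                if do_deposit:
                    deposit_segment(acc, gox, goy, goz, gsx, gsy, gsz,
                                    px, py, pz, fx, fy, fz, 1.0)
                px = fx
                py = fy
                pz = fz
            continue
        mu_t = media[med_i, 4]
        d_int = tau / mu_t if mu_t > 0.0 else _BIG
        if d_int <= d_abs:
            # interaction point reached
            nx_ = px + d_int * dx
            ny_ = py + d_int * dy
            nz_ = pz + d_int * dz
            if do_deposit:
                deposit_segment(acc, gox, goy, goz, gsx, gsy, gsz,
                                px, py, pz, nx_, ny_, nz_, 1.0)
            px = nx_
            py = ny_
            pz = nz_
            if next_uniform(state) < media[med_i, 5]:  # scatter (albedo)
                g = media[med_i, 2]
                cos_t = hg_cos(g, next_uniform(state))
                phi = 2.0 * math.pi * next_uniform(state)
                dx, dy, dz = rotate_direction(dx, dy, dz, cos_t, phi)
                n_sc += 1
                tau = -math.log(next_uniform(state))
            else:
                return EV_ABSORBED, n_sc, px, py, pz, dx, dy, dz
        else:
            # march the sphere-trace step
            nx_ = px + d_abs * dx
            ny_ = py + d_abs * dy
            nz_ = pz + d_abs * dz
            if do_deposit:
                deposit_segment(acc, gox, goy, goz, gsx, gsy, gsz,
                                px, py, pz, nx_, ny_, nz_, 1.0)
            px = nx_
            py = ny_
            pz = nz_
            tau -= d_abs * mu_t
            if tau < 0.0:
                tau = 0.0
    return EV_STEP_CAP, n_sc, px, py, pz, dx, dy, dz


@njit(cache=True)
def sample_source(src_kind, src_params, state, delta_s):
    """Draw a launch position/direction for the configured source."""
    if src_kind == SRC_ISOTROPIC_POINT:
        px = src_params[0]
        py = src_params[1]
        pz = src_params[2]
        cos_t = 2.0 * next_uniform(state) - 1.0
        sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
        phi = 2.0 * math.pi * next_uniform(state)
        dx = sin_t * math.cos(phi)
        dy = sin_t * math.sin(phi)
        dz = cos_t
    else:
        # rectangular beam: uniform over a rectangle, fixed direction
        px = src_params[0] + (2.0 * next_uniform(state) - 1.0) * src_params[3]
        py = src_params[1] + (2.0 * next_uniform(state) - 1.0) * src_params[4]
        pz = src_params[2]
        dx = src_params[5]
        dy = src_params[6]
        dz = src_params[7]
    # nudge off any launch face
    px += delta_s * dx
    py += delta_s * dy
    pz += delta_s * dz
    return px, py, pz, dx, dy, dz


@njit(cache=True)
def run_photons(n_photons, seed,
                src_kind, src_params,
                kind, params, rot, trans, child, root_lo, root_hi,
                root_layer, root_med, media,
                bcx, bcy, bcz, bhx, bhy, bhz,
                acc, gox, goy, goz, gsx, gsy, gsz, do_deposit,
                delta_s, h_norm, step_cap):
    """Trace ``n_photons`` packets; fills ``acc`` in place and returns
    per-photon (event, n_scatters, exit position, exit direction) arrays."""
    out_event = np.empty(n_photons, dtype=np.int8)
    out_nsc = np.empty(n_photons, dtype=np.int64)
    out_pos = np.empty((n_photons, 3), dtype=np.float64)
    out_dir = np.empty((n_photons, 3), dtype=np.float64)
    state = np.empty(4, dtype=np.uint64)
    scratch = np.empty(kind.shape[0], dtype=np.float64)
    for i in range(n_photons):
        stream_init(seed, i, state)
        px, py, pz, dx, dy, dz = sample_source(src_kind, src_params, state, delta_s)
        ev, nsc, px, py, pz, dx, dy, dz = trace_one(
            px, py, pz, dx, dy, dz, state,
            kind, params, rot, trans, child, root_lo, root_hi,
            root_layer, root_med, media,
            bcx, bcy, bcz, bhx, bhy, bhz,
            acc, gox, goy, goz, gsx, gsy, gsz, do_deposit,
            delta_s, h_norm, step_cap, scratch)
        out_event[i] = ev
        out_nsc[i] = nsc
        out_pos[i, 0] = px
        out_pos[i, 1] = py
        out_pos[i, 2] = pz
        out_dir[i, 0] = dx
        out_dir[i, 1] = dy
        out_dir[i, 2] = dz
    return out_event, out_nsc, out_pos, out_dir
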