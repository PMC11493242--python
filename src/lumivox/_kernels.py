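"""Compiled inner loops for photon tracing and ray casting.

These numba kernels mirror the pure-Python primitives in
:mod:`lumivox.volume_io` and :mod:`lumivox.render` operation-for-operation
(same clamping, same interpolation order, same deposition rule), so results
agree with the Python reference path to floating-point round-off.  All state
is passed as plain arrays; nothing here touches Python objects.

Geometry conventions (shared with the rest of the package):

* voxel-center convention — voxel (i,j,k) sits at ``origin + (i,j,k)*spacing``;
* the physical box extends half a voxel beyond the outer voxel centers;
* rays are clipped to the box with the slab method and sampled at
  ``t = t_enter + (s + 0.5) * step`` so the first sample lies strictly inside.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# stack capacity for pending reflected photons; total pushes per trace are
# bounded by initial_energy / epsilon, and epsilon >= 1e-3 in practice
_STACK = 4096


@njit(cache=True)
def _interp1(x, xs, ys):
    """Piecewise-linear interpolation with end clamping (np.interp semantics)."""
    n = xs.shape[0]
    if x <= xs[0]:
        return ys[0]
    if x >= xs[n - 1]:
        return ys[n - 1]
    lo = 0
    hi = n - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if xs[mid] <= x:
            lo = mid
        else:
            hi = mid
    t = (x - xs[lo]) / (xs[hi] - xs[lo])
    return ys[lo] + (ys[hi] - ys[lo]) * t


@njit(cache=True)
def _trilinear(vol, origin, spacing, px, py, pz):
    """Clamped trilinear sample; 0 outside the physical box."""
    nx, ny, nz = vol.shape
    fx = (px - origin[0]) / spacing[0]
    fy = (py - origin[1]) / spacing[1]
    fz = (pz - origin[2]) / spacing[2]
    if (
        fx < -0.5 or fx > nx - 0.5
        or fy < -0.5 or fy > ny - 0.5
        or fz < -0.5 or fz > nz - 0.5
    ):
        return 0.0
    if fx < 0.0:
        fx = 0.0
    elif fx > nx - 1.0:
        fx = nx - 1.0
    if fy < 0.0:
        fy = 0.0
    elif fy > ny - 1.0:
        fy = ny - 1.0
    if fz < 0.0:
        fz = 0.0
    elif fz > nz - 1.0:
        fz = nz - 1.0
    i0 = min(int(fx), nx - 2)
    j0 = min(int(fy), ny - 2)
    k0 = min(int(fz), nz - 2)
    tx = fx - i0
    ty = fy - j0
    tz = fz - k0
    c00 = vol[i0, j0, k0] * (1 - tx) + vol[i0 + 1, j0, k0] * tx
    c10 = vol[i0, j0 + 1, k0] * (1 - tx) + vol[i0 + 1, j0 + 1, k0] * tx
    c01 = vol[i0, j0, k0 + 1] * (1 - tx) + vol[i0 + 1, j0, k0 + 1] * tx
    c11 = vol[i0, j0 + 1, k0 + 1] * (1 - tx) + vol[i0 + 1, j0 + 1, k0 + 1] * tx
    c0 = c00 * (1 - ty) + c10 * ty
    c1 = c01 * (1 - ty) + c11 * ty
    return c0 * (1 - tz) + c1 * tz


@njit(cache=True)
def _gradient(vol, origin, spacing, px, py, pz, out):
    """Central-difference gradient of the trilinear interpolant (per mm)."""
    p = (px, py, pz)
    for ax in range(3):
        lo_c = origin[ax]
        hi_c = origin[ax] + (vol.shape[ax] - 1.0) * spacing[ax]
        a = p[ax] + spacing[ax]
        b = p[ax] - spacing[ax]
        if a > hi_c:
            a = hi_c
        if b < lo_c:
            b = lo_c
        if a == b:
            out[ax] = 0.0
            continue
        if ax == 0:
            vp = _trilinear(vol, origin, spacing, a, py, pz)
            vm = _trilinear(vol, origin, spacing, b, py, pz)
        elif ax == 1:
            vp = _trilinear(vol, origin, spacing, px, a, pz)
            vm = _trilinear(vol, origin, spacing, px, b, pz)
        else:
            vp = _trilinear(vol, origin, spacing, px, py, a)
            vm = _trilinear(vol, origin, spacing, px, py, b)
        out[ax] = (vp - vm) / (a - b)


@njit(cache=True)
def _schlick(cos_hv, f0):
    c = cos_hv
    if c < 0.0:
        c = 0.0
    elif c > 1.0:
        c = 1.0
    return f0 + (1.0 - f0) * (1.0 - c) ** 5


@njit(cache=True)
def _clip_box(px, py, pz, dx, dy, dz, lo, hi):
    """Slab ray/box intersection; returns (hit, t_enter>=0, t_exit)."""
    t0 = 0.0
    t1 = np.inf
    p = (px, py, pz)
    d = (dx, dy, dz)
    for ax in range(3):
        if abs(d[ax]) < 1e-300:
            if p[ax] < lo[ax] or p[ax] > hi[ax]:
                return False, 0.0, 0.0
        else:
            ta = (lo[ax] - p[ax]) / d[ax]
            tb = (hi[ax] - p[ax]) / d[ax]
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
    if t1 <= t0:
        return False, 0.0, 0.0
    return True, t0, t1


@njit(cache=True)
def _deposit_cell(shape0, shape1, shape2, origin, spacing, px, py, pz):
    """Index of the field cell containing a physical point (nearest voxel)."""
    i = int(np.floor((px - origin[0]) / spacing[0] + 0.5))
    j = int(np.floor((py - origin[1]) / spacing[1] + 0.5))
    k = int(np.floor((pz - origin[2]) / spacing[2] + 0.5))
    if i < 0:
        i = 0
    elif i >= shape0:
        i = shape0 - 1
    if j < 0:
        j = 0
    elif j >= shape1:
        j = shape1 - 1
    if k < 0:
        k = 0
    elif k >= shape2:
        k = shape2 - 1
    return i, j, k


@njit(cache=True)
def trace_photon_kernel(
    pos,
    direction,
    energy,
    depth0,
    vol,
    origin,
    spacing,
    tf_v,
    tf_a,
    field,
    epsilon,
    max_depth,
    f0,
    grad_threshold,
    step_mm,
):
    """Trace one photon (and all its reflected descendants) through the volume.

    At every ray-march sample whose transfer-function opacity is non-zero the
    photon splits: a transmitted share ``E*(1-alpha)`` continues straight, a
    reflected share ``E*min(F_schlick, alpha)`` is mirrored about the local
    gradient normal and pushed for later tracing, and the remainder is
    deposited into the ambient field cell containing the sample.  Children
    whose energy falls below ``epsilon`` or whose reflection depth exceeds
    ``max_depth`` are dropped.  Where the gradient magnitude is below
    ``grad_threshold`` the surface normal is undefined and the would-be
    reflected share is folded into the deposit, keeping conservation exact.

    Mutates ``field`` in place and returns ``(deposited, exited, dropped)``;
    the three always sum to the initial energy up to round-off.
    """
    nx, ny, nz = vol.shape
    lo0 = origin[0] - 0.5 * spacing[0]
    lo1 = origin[1] - 0.5 * spacing[1]
    lo2 = origin[2] - 0.5 * spacing[2]
    hi0 = origin[0] + (nx - 0.5) * spacing[0]
    hi1 = origin[1] + (ny - 0.5) * spacing[1]
    hi2 = origin[2] + (nz - 0.5) * spacing[2]
    lo = (lo0, lo1, lo2)
    hi = (hi0, hi1, hi2)

    stack = np.empty((_STACK, 8))
    stack[0, 0] = pos[0]
    stack[0, 1] = pos[1]
    stack[0, 2] = pos[2]
    stack[0, 3] = direction[0]
    stack[0, 4] = direction[1]
    stack[0, 5] = direction[2]
    stack[0, 6] = energy
    stack[0, 7] = depth0
    nstack = 1

    deposited = 0.0
    exited = 0.0
    dropped = 0.0
    grad = np.empty(3)

    while nstack > 0:
        nstack -= 1
        px = stack[nstack, 0]
        py = stack[nstack, 1]
        pz = stack[nstack, 2]
        dx = stack[nstack, 3]
        dy = stack[nstack, 4]
        dz = stack[nstack, 5]
        e = stack[nstack, 6]
        depth = int(stack[nstack, 7])

        hit, t0, t1 = _clip_box(px, py, pz, dx, dy, dz, lo, hi)
        if not hit:
            exited += e
            continue

        t = t0 + 0.5 * step_mm
        alive = True
        while t < t1:
            sx = px + t * dx
            sy = py + t * dy
            sz = pz + t * dz
            intensity = _trilinear(vol, origin, spacing, sx, sy, sz)
            alpha = _interp1(intensity, tf_v, tf_a)
            if alpha > 0.0:
                _gradient(vol, origin, spacing, sx, sy, sz, grad)
                gnorm = np.sqrt(grad[0] ** 2 + grad[1] ** 2 + grad[2] ** 2)
                lt = e * (1.0 - alpha)
                if gnorm >= grad_threshold:
                    cos_hv = abs(grad[0] * dx + grad[1] * dy + grad[2] * dz) / gnorm
                    fr = _schlick(cos_hv, f0)
                    if fr > alpha:
                        fr = alpha  # deposits never go negative
                    lr = e * fr
                    lc = e - lt - lr
                    if lc < 0.0:  # round-off when fr == alpha
                        lc = 0.0
                    if lr > 0.0:
                        if lr >= epsilon and depth + 1 <= max_depth and nstack < _STACK:
                            ndot = (grad[0] * dx + grad[1] * dy + grad[2] * dz) / gnorm
                            rx = dx - 2.0 * ndot * grad[0] / gnorm
                            ry = dy - 2.0 * ndot * grad[1] / gnorm
                            rz = dz - 2.0 * ndot * grad[2] / gnorm
                            rn = np.sqrt(rx * rx + ry * ry + rz * rz)
                            stack[nstack, 0] = sx
                            stack[nstack, 1] = sy
                            stack[nstack, 2] = sz
                            stack[nstack, 3] = rx / rn
                            stack[nstack, 4] = ry / rn
                            stack[nstack, 5] = rz / rn
                            stack[nstack, 6] = lr
                            stack[nstack, 7] = depth + 1
                            nstack += 1
                        else:
                            dropped += lr
                else:
                    # undefined normal: reflected share folds into the deposit
                    lc = e - lt
                i, j, k = _deposit_cell(nx, ny, nz, origin, spacing, sx, sy, sz)
                field[i, j, k] += lc
                deposited += lc
                e = lt
                if e < epsilon:
                    dropped += e
                    alive = False
                    break
            t += step_mm
        if alive:
            exited += e
    return deposited, exited, dropped


@njit(cache=True)
def precompute_kernel(
    origins,
    direction,
    energies,
    vol,
    origin,
    spacing,
    tf_v,
    tf_a,
    field,
    epsilon,
    max_depth,
    f0,
    grad_threshold,
    step_mm,
):
    """Trace a batch of photons sharing one direction (one area light source)."""
    deposited = 0.0
    exited = 0.0
    dropped = 0.0
    for r in range(origins.shape[0]):
        d, x, dr = trace_photon_kernel(
            origins[r],
            direction,
            energies[r],
            0,
            vol,
            origin,
            spacing,
            tf_v,
            tf_a,
            field,
            epsilon,
            max_depth,
            f0,
            grad_threshold,
            step_mm,
        )
        deposited += d
        exited += x
        dropped += dr
    return deposited, exited, dropped


@njit(cache=True)
def _interp_ambient(field, origin, spacing, px, py, pz, mode):
    """Ambient light at a physical point: inverse-distance (mode 0) over the
    8 surrounding field cells, or plain trilinear (mode 1).  0 outside."""
    nx, ny, nz = field.shape
    fx = (px - origin[0]) / spacing[0]
    fy = (py - origin[1]) / spacing[1]
    fz = (pz - origin[2]) / spacing[2]
    if (
        fx < -0.5 or fx > nx - 0.5
        or fy < -0.5 or fy > ny - 0.5
        or fz < -0.5 or fz > nz - 0.5
    ):
        return 0.0
    if mode == 1:
        return _trilinear(field, origin, spacing, px, py, pz)
    if fx < 0.0:
        fx = 0.0
    elif fx > nx - 1.0:
        fx = nx - 1.0
    if fy < 0.0:
        fy = 0.0
    elif fy > ny - 1.0:
        fy = ny - 1.0
    if fz < 0.0:
        fz = 0.0
    elif fz > nz - 1.0:
        fz = nz - 1.0
    i0 = min(int(fx), nx - 2)
    j0 = min(int(fy), ny - 2)
    k0 = min(int(fz), nz - 2)
    wsum = 0.0
    acc = 0.0
    for di in range(2):
        for dj in range(2):
            for dk in range(2):
                cx = (i0 + di - fx) * spacing[0]
                cy = (j0 + dj - fy) * spacing[1]
                cz = (k0 + dk - fz) * spacing[2]
                dist = np.sqrt(cx * cx + cy * cy + cz * cz)
                if dist < 1e-9:
                    return field[i0 + di, j0 + dj, k0 + dk]
                w = 1.0 / dist
                wsum += w
                acc += w * field[i0 + di, j0 + dj, k0 + dk]
    return acc / wsum


@njit(cache=True)
def cast_ray_kernel(
    pos,
    direction,
    vol,
    origin,
    spacing,
    tf_v,
    tf_rgba,
    field,
    forigin,
    fspacing,
    dim1,
    dim2,
    step_mm,
    interp_mode,
    background,
    out,
):
    """March one view ray, fusing ambient and transmitted light per sample.

    Per sample with alpha > 0: classify the trilinear intensity, look up the
    ambient light, peel the transmitted share ``LCT = E*alpha`` off the ray
    energy (initial E = 1), and accumulate
    ``C * alpha * (L_ambient*dim1 + LCT*dim2)``.  Marching stops when the
    accumulated opacity reaches 1 or the ray leaves the box.  Rays that never
    meet material return the background color.  Output is NOT clamped here.
    """
    nx, ny, nz = vol.shape
    lo = (
        origin[0] - 0.5 * spacing[0],
        origin[1] - 0.5 * spacing[1],
        origin[2] - 0.5 * spacing[2],
    )
    hi = (
        origin[0] + (nx - 0.5) * spacing[0],
        origin[1] + (ny - 0.5) * spacing[1],
        origin[2] + (nz - 0.5) * spacing[2],
    )
    out[0] = 0.0
    out[1] = 0.0
    out[2] = 0.0
    hit, t0, t1 = _clip_box(pos[0], pos[1], pos[2], direction[0], direction[1], direction[2], lo, hi)
    if not hit:
        out[0] = background[0]
        out[1] = background[1]
        out[2] = background[2]
        return
    e = 1.0
    acc_alpha = 0.0
    t = t0 + 0.5 * step_mm
    while t < t1:
        sx = pos[0] + t * direction[0]
        sy = pos[1] + t * direction[1]
        sz = pos[2] + t * direction[2]
        intensity = _trilinear(vol, origin, spacing, sx, sy, sz)
        alpha = _interp1(intensity, tf_v, tf_rgba[:, 3])
        if alpha > 0.0:
            l_amb = _interp_ambient(field, forigin, fspacing, sx, sy, sz, interp_mode)
            lct = e * alpha
            e = e - lct
            w = alpha * (l_amb * dim1 + lct * dim2)
            out[0] += _interp1(intensity, tf_v, tf_rgba[:, 0]) * w
            out[1] += _interp1(intensity, tf_v, tf_rgba[:, 1]) * w
            out[2] += _interp1(intensity, tf_v, tf_rgba[:, 2]) * w
            acc_alpha += alpha
            if acc_alpha >= 1.0:
                return
        t += step_mm
    if acc_alpha == 0.0:
        out[0] = background[0]
        out[1] = background[1]
        out[2] = background[2]


@njit(cache=True)
def render_kernel(
    origins,
    directions,
    vol,
    origin,
    spacing,
    tf_v,
    tf_rgba,
    field,
    forigin,
    fspacing,
    dim1,
    dim2,
    step_mm,
    interp_mode,
    background,
    image,
):
    """Cast one ray per pixel; ``image`` is (npix, 3), unclamped."""
    buf = np.empty(3)
    for p in range(origins.shape[0]):
        cast_ray_kernel(
            origins[p],
            directions[p],
            vol,
            origin,
            spacing,
            tf_v,
            tf_rgba,
            field,
            forigin,
            fspacing,
            dim1,
            dim2,
            step_mm,
            interp_mode,
            background,
            buf,
        )
        image[p, 0] = buf[0]
        image[p, 1] = buf[1]
        image[p, 2] = buf[2]
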