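"""Fusion ray casting: combine precomputed ambient light with transmitted light.

The renderer marches a view ray per pixel through the classified volume.  At
every sample with non-zero opacity it (1) classifies the trilinear intensity
through the transfer function, (2) interpolates the precomputed ambient light
field at the sample, (3) peels the absorbed share off the ray's transmitted
energy, and (4) accumulates the fused color

    C_fusion = C * alpha * (L_ambient * dim1 + L_transmitted * dim2)

until the accumulated opacity reaches 1 or the ray leaves the volume.  The
final pixel is the plain sum of the fused contributions, clamped to [0, 1]
at the end; because the sum is linear in (dim1, dim2), ambient-only and
transmitted-only renders are exact linear slices of the fused image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .volume_io import AmbientLightField, TransferFunction, Volume

__all__ = [
    "Camera",
    "RenderSettings",
    "interpolate_ambient",
    "transmitted_update",
    "fuse_sample",
    "cast_ray",
    "render_image",
]


@dataclass
class Camera:
    """Pinhole or parallel-projection camera.

    Orthographic mode (default) places the pixel grid on a plane through
    ``eye`` spanned by right/up, with physical pixel ``pitch`` in mm — so a
    render at the volume's own resolution uses pitch = voxel spacing.
    Perspective mode shoots rays from ``eye`` through a virtual image plane
    with the given vertical field of view (degrees).
    """

    eye: tuple[float, float, float]
    view: tuple[float, float, float]
    up: tuple[float, float, float] = (0.0, 0.0, 1.0)
    width: int = 128
    height: int = 128
    mode: str = "orthographic"
    pitch: float = 1.0
    fov: float = 45.0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("image dimensions must be >= 1")
        v = np.asarray(self.view, dtype=np.float64)
        u = np.asarray(self.up, dtype=np.float64)
        if np.linalg.norm(np.cross(v, u)) < 1e-12:
            raise ValueError("view and up directions must not be parallel")
        if self.mode not in ("orthographic", "perspective"):
            raise ValueError(f"unknown camera mode {self.mode!r}")

    def rays(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-pixel (origins, directions), row-major, shape (H*W, 3)."""
        view = np.asarray(self.view, dtype=np.float64)
        view = view / np.linalg.norm(view)
        up = np.asarray(self.up, dtype=np.float64)
        right = np.cross(view, up)
        right /= np.linalg.norm(right)
        true_up = np.cross(right, view)
        eye = np.asarray(self.eye, dtype=np.float64)

        jj, ii = np.meshgrid(
            np.arange(self.width, dtype=np.float64),
            np.arange(self.height, dtype=np.float64),
        )
        sx = jj - (self.width - 1) / 2.0
        sy = (self.height - 1) / 2.0 - ii  # image row 0 at the top
        if self.mode == "orthographic":
            origins = (
                eye[None, :]
                + (sx.ravel() * self.pitch)[:, None] * right[None, :]
                + (sy.ravel() * self.pitch)[:, None] * true_up[None, :]
            )
            directions = np.broadcast_to(view, origins.shape).copy()
            return np.ascontiguousarray(origins), np.ascontiguousarray(directions)
        # perspective: image plane at unit distance, vertical half-extent tan(fov/2)
        half = np.tan(np.deg2rad(self.fov) / 2.0)
        py = sy.ravel() / ((self.height - 1) / 2.0 or 1.0) * half
        px = sx.ravel() / ((self.height - 1) / 2.0 or 1.0) * half
        directions = (
            view[None, :] + px[:, None] * right[None, :] + py[:, None] * true_up[None, :]
        )
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        origins = np.broadcast_to(eye, directions.shape).copy()
        return np.ascontiguousarray(origins), np.ascontiguousarray(directions)


@dataclass
class RenderSettings:
    """Fusion weights and marching parameters.

    ``dim1`` scales the ambient term, ``dim2`` the transmitted term; both are
    plain brightness knobs.  ``step`` is the march step as a fraction of the
    smallest voxel spacing.  ``interpolation`` selects how the ambient field
    is read: ``"inverse_distance"`` (default) or ``"trilinear"``.
    """

    dim1: float = 0.5
    dim2: float = 0.5
    step: float = 0.5
    background: tuple[float, float, float] = (0.0, 0.0, 0.0)
    interpolation: str = "inverse_distance"

    def __post_init__(self) -> None:
        if self.dim1 < 0 or self.dim2 < 0:
            raise ValueError("brightness coefficients must be non-negative")
        if self.dim1 + self.dim2 <= 0:
            raise ValueError("dim1 + dim2 must be positive")
        if self.interpolation not in ("inverse_distance", "trilinear"):
            raise ValueError(f"unknown interpolation {self.interpolation!r}")

    @property
    def interp_mode(self) -> int:
        return 0 if self.interpolation == "inverse_distance" else 1


def interpolate_ambient(fld: AmbientLightField, p, mode: str = "inverse_distance") -> float:
    """Ambient light intensity at physical point ``p``.

    Inverse-distance weighting over the 8 surrounding field cells: weights
    are 1/distance, normalized; a query closer than 1e-9 mm to a cell center
    returns that cell's value exactly.  Because precomputed energy lives only
    where material absorbed photons, neighboring cells can legitimately hold
    0 — the distance weighting still blends across such cells smoothly.
    Points outside the field's box return 0.
    """
    p = np.asarray(p, dtype=np.float64)
    return float(
        _kernels._interp_ambient(
            fld.data,
            np.asarray(fld.origin),
            np.asarray(fld.spacing),
            p[0],
            p[1],
            p[2],
            0 if mode == "inverse_distance" else 1,
        )
    )


def transmitted_update(energy: float, alpha: float) -> tuple[float, float]:
    """One absorption event of the view ray's transmitted light.

    With no refraction on the view ray, the share absorbed at the sample is
    ``LCT = E*alpha`` and ``E*(1-alpha)`` carries on; the two sum to the
    input exactly.
    """
    if energy < 0:
        raise ValueError("energy must be non-negative")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    lct = energy * alpha
    return lct, energy - lct


def fuse_sample(
    color, alpha: float, l_ambient: float, lct: float, s: RenderSettings
) -> np.ndarray:
    """Fused color contribution of one sample:
    ``C * alpha * (L_ambient*dim1 + LCT*dim2)`` per channel."""
    c = np.asarray(color, dtype=np.float64)
    return c * alpha * (l_ambient * s.dim1 + lct * s.dim2)


def _tf_kernel_arrays(tf: TransferFunction):
    return (
        np.ascontiguousarray(tf.values, dtype=np.float64),
        np.ascontiguousarray(tf.rgba, dtype=np.float64),
    )


def cast_ray(
    origin,
    direction,
    vol: Volume,
    tf: TransferFunction,
    fld: AmbientLightField,
    s: RenderSettings | None = None,
    clamp: bool = True,
) -> np.ndarray:
    """March one view ray and return its RGB color.

    Accumulates fused sample contributions until the summed opacity reaches 1
    or the ray exits; a ray that never meets material (or misses the box)
    returns the background color.  ``clamp=False`` returns the raw sum,
    useful for checking the linearity of the fusion weights.
    """
    d = np.asarray(direction, dtype=np.float64)
    n = np.linalg.norm(d)
    if n < 1e-12:
        raise ValueError("degenerate ray direction")
    s = s or RenderSettings()
    tf_v, tf_rgba = _tf_kernel_arrays(tf)
    out = np.empty(3)
    _kernels.cast_ray_kernel(
        np.asarray(origin, dtype=np.float64),
        d / n,
        vol.data,
        np.asarray(vol.origin),
        np.asarray(vol.spacing),
        tf_v,
        tf_rgba,
        fld.data,
        np.asarray(fld.origin),
        np.asarray(fld.spacing),
        s.dim1,
        s.dim2,
        s.step * min(vol.spacing),
        s.interp_mode,
        np.asarray(s.background, dtype=np.float64),
        out,
    )
    return np.clip(out, 0.0, 1.0) if clamp else out


def render_image(
    camera: Camera,
    vol: Volume,
    tf: TransferFunction,
    fld: AmbientLightField,
    s: RenderSettings | None = None,
    clamp: bool = True,
) -> np.ndarray:
    """Render an (H, W, 3) image, one cast ray per pixel.

    The ambient field must be co-registered with the volume (same grid).
    Deterministic: identical inputs give bit-identical images.
    """
    if fld.shape != vol.shape:
        raise ValueError(
            f"ambient field shape {fld.shape} does not match volume {vol.shape}"
        )
    s = s or RenderSettings()
    origins, directions = camera.rays()
    tf_v, tf_rgba = _tf_kernel_arrays(tf)
    image = np.empty((origins.shape[0], 3))
    _kernels.render_kernel(
        origins,
        directions,
        vol.data,
        np.asarray(vol.origin),
        np.asarray(vol.spacing),
        tf_v,
        tf_rgba,
        fld.data,
        np.asarray(fld.origin),
        np.asarray(fld.spacing),
        s.dim1,
        s.dim2,
        s.step * min(vol.spacing),
        s.interp_mode,
        np.asarray(s.background, dtype=np.float64),
        image,
    )
    image = image.reshape(camera.height, camera.width, 3)
    return np.clip(image, 0.0, 1.0) if clamp else image


def orbit_camera(
    vol: Volume,
    azimuth_deg: float = 0.0,
    elevation_deg: float = 0.0,
    width: int = 128,
    height: int = 128,
    pitch: float | None = None,
) -> Camera:
    """Orthographic camera on the volume's circumscribed sphere, looking at
    its center; a convenience for turntable views.

    ``pitch`` defaults to the smallest voxel spacing so that image resolution
    matches the dataset's own sampling.
    """
    az = np.deg2rad(azimuth_deg)
    el = np.deg2rad(elevation_deg)
    d = np.array(
        [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)]
    )
    center = vol.center
    eye = center + 2.0 * vol.circumradius * d
    up = (0.0, 0.0, 1.0) if abs(d[2]) < 0.99 else (1.0, 0.0, 0.0)
    return Camera(
        eye=tuple(eye),
        view=tuple(-d),
        up=up,
        width=width,
        height=height,
        pitch=pitch if pitch is not None else min(vol.spacing),
    )
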