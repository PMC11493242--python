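"""Volumes, transfer functions, ambient light fields, images: containers and I/O.

Coordinate convention
---------------------
Everything downstream works in physical millimetres.  Voxel index
``(i, j, k)`` maps to the physical point ``origin + (i, j, k) * spacing``
(voxel-*center* convention, 0-based indices).  The physical bounding box of a
volume extends half a voxel beyond the first/last voxel centers on every axis,
so each voxel owns an equal slab of space.

Formats
-------
* NIfTI-1 (``.nii`` / ``.nii.gz``) via nibabel, axis order (x, y, z).
* Raw little-endian binary + JSON sidecar
  ``{"dims": [x,y,z], "dtype": "...", "spacing": [...], "origin": [...]}``.
  The sidecar lives next to the raw file with a ``.json`` extension.
* Transfer functions: JSON ``{"points": [{"v": .., "rgba": [r,g,b,a]}, ...]}``.
* Ambient light fields: the raw+JSON dialect (float32) with an extra
  ``"provenance"`` block recording the light configuration, seed and a hash
  of the transfer function used during precomputation.
* Images: 8-bit RGB PNG, channel values clamped from [0, 1].
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "Volume",
    "TransferFunction",
    "AmbientLightField",
    "read_volume",
    "write_volume",
    "read_transfer_function",
    "write_transfer_function",
    "read_field",
    "write_field",
    "write_image",
    "evaluate_tf",
    "sample_trilinear",
    "gradient_at",
    "field_dimensions",
]


class VolumeError(ValueError):
    """Raised for invalid volume/transfer-function/field inputs."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class Volume:
    """A 3-D scalar grid (e.g. CT in Hounsfield units) with physical placement.

    Parameters
    ----------
    data
        Array of shape ``(Vx, Vy, Vz)``; cast to float64 on construction.
    spacing
        Physical size of one voxel per axis, in mm.  All entries > 0.
    origin
        Physical coordinate of the center of voxel (0, 0, 0), in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.ascontiguousarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise VolumeError(f"volume must be 3-D, got {self.data.ndim}-D")
        if min(self.data.shape) < 2:
            raise VolumeError(f"every dimension must be >= 2, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise VolumeError(f"spacings must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise VolumeError("volume contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def center(self) -> np.ndarray:
        """Physical center of the volume's bounding box (mm)."""
        dims = np.asarray(self.shape, dtype=float)
        return np.asarray(self.origin) + (dims - 1.0) * np.asarray(self.spacing) / 2.0

    @property
    def circumradius(self) -> float:
        """Radius of the circumscribed sphere of the full physical box (mm)."""
        extent = np.asarray(self.shape, dtype=float) * np.asarray(self.spacing)
        return float(0.5 * np.linalg.norm(extent))

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical box (lo, hi) including the half-voxel margin on each side."""
        o = np.asarray(self.origin)
        sp = np.asarray(self.spacing)
        dims = np.asarray(self.shape, dtype=float)
        return o - 0.5 * sp, o + (dims - 0.5) * sp


@dataclass
class TransferFunction:
    """Piecewise-linear map from scalar intensity to (r, g, b, alpha).

    Control points are sorted by intensity; evaluation clamps outside the
    covered range.  ``alpha`` is the opacity driving every light interaction:
    a voxel with alpha = 0 is vacuum for both photons and view rays.
    """

    points: list[tuple[float, tuple[float, float, float, float]]]

    def __post_init__(self) -> None:
        if not self.points:
            raise VolumeError("transfer function needs at least one control point")
        pts = sorted((float(v), tuple(float(c) for c in rgba)) for v, rgba in self.points)
        for v, rgba in pts:
            if len(rgba) != 4:
                raise VolumeError("each control point needs 4 channels (r,g,b,a)")
            if any(c < 0 or c > 1 for c in rgba):
                raise VolumeError(f"rgba channels must lie in [0,1], got {rgba} at v={v}")
        self.points = pts
        self._vs = np.asarray([p[0] for p in pts])
        self._rgba = np.asarray([p[1] for p in pts])  # (n, 4)

    @property
    def values(self) -> np.ndarray:
        return self._vs

    @property
    def rgba(self) -> np.ndarray:
        return self._rgba

    def __call__(self, intensity):
        return evaluate_tf(self, intensity)

    def content_hash(self) -> str:
        """Stable hash of the control points, used for field provenance."""
        blob = json.dumps(
            [[v, list(rgba)] for v, rgba in self.points], sort_keys=True
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class AmbientLightField:
    """Voxel grid of precomputed scalar ambient light energy.

    Co-registered with its source volume: identical shape, spacing and origin,
    so field cell ``(i, j, k)`` sits exactly on voxel ``(i, j, k)``.  Values
    are non-negative deposited photon energies.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.ascontiguousarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise VolumeError("ambient field must be 3-D")
        if np.any(self.data < 0):
            raise VolumeError("ambient field cells must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


# ---------------------------------------------------------------------------
# volume I/O
# ---------------------------------------------------------------------------

_RAW_DTYPES = {"int16", "uint8", "uint16", "int32", "float32", "float64"}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_volume(path, format_hint: str | None = None) -> Volume:
    """Read a volume from NIfTI or from raw binary + JSON sidecar.

    The format is inferred from the extension (``.nii``/``.nii.gz`` vs
    ``.raw``); ``format_hint`` (``"nifti"`` or ``"raw"``) overrides.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume file not found: {path}")
    fmt = format_hint or ("nifti" if ".nii" in path.suffixes else "raw")
    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        zooms = img.header.get_zooms()[:3]
        origin = tuple(float(x) for x in img.affine[:3, 3])
        return Volume(data, spacing=tuple(float(z) for z in zooms), origin=origin)
    if fmt == "raw":
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise IOError(f"missing JSON sidecar for raw volume: {sidecar}")
        meta = json.loads(sidecar.read_text())
        dims = tuple(int(d) for d in meta["dims"])
        dtype = meta["dtype"]
        if dtype not in _RAW_DTYPES:
            raise IOError(f"unsupported raw dtype {dtype!r}")
        arr = np.fromfile(path, dtype=np.dtype(dtype).newbyteorder("<"))
        if arr.size != int(np.prod(dims)):
            raise IOError(
                f"raw file {path} holds {arr.size} values, sidecar promises {np.prod(dims)}"
            )
        data = arr.reshape(dims, order="C")
        return Volume(
            data,
            spacing=tuple(meta.get("spacing", (1.0, 1.0, 1.0))),
            origin=tuple(meta.get("origin", (0.0, 0.0, 0.0))),
        )
    raise ValueError(f"unknown format hint {format_hint!r}")


def write_volume(vol: Volume, path, dtype: str = "float32") -> None:
    """Write ``vol`` as NIfTI (``.nii``/``.nii.gz``) or raw+JSON (``.raw``)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if ".nii" in path.suffixes:
        import nibabel as nib

        affine = np.diag(list(vol.spacing) + [1.0])
        affine[:3, 3] = vol.origin
        img = nib.Nifti1Image(vol.data.astype(dtype), affine)
        img.header.set_zooms(vol.spacing)
        nib.save(img, str(path))
        return
    vol.data.astype(np.dtype(dtype).newbyteorder("<")).tofile(path)
    meta = {
        "dims": list(vol.shape),
        "dtype": dtype,
        "spacing": list(vol.spacing),
        "origin": list(vol.origin),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


# ---------------------------------------------------------------------------
# transfer function I/O and evaluation
# ---------------------------------------------------------------------------


def read_transfer_function(path) -> TransferFunction:
    path = Path(path)
    if not path.exists():
        raise IOError(f"transfer function file not found: {path}")
    doc = json.loads(path.read_text())
    return TransferFunction([(p["v"], tuple(p["rgba"])) for p in doc["points"]])


def write_transfer_function(tf: TransferFunction, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {"points": [{"v": v, "rgba": list(rgba)} for v, rgba in tf.points]}
    path.write_text(json.dumps(doc, indent=2))


def evaluate_tf(tf: TransferFunction, intensity) -> np.ndarray:
    """Evaluate the transfer function at scalar intensity (or an array).

    Piecewise-linear between control points, clamped to the end points
    outside their range.  Returns rgba of shape ``(..., 4)``.
    """
    v = np.asarray(intensity, dtype=np.float64)
    out = np.empty(v.shape + (4,))
    for c in range(4):
        out[..., c] = np.interp(v, tf.values, tf.rgba[:, c])
    return out


# ---------------------------------------------------------------------------
# sampling primitives
# ---------------------------------------------------------------------------


def _fractional_index(vol, p) -> np.ndarray:
    return (np.asarray(p, dtype=np.float64) - np.asarray(vol.origin)) / np.asarray(
        vol.spacing
    )


def sample_trilinear(vol: Volume, p, clamp: bool = False) -> float:
    """Trilinear interpolation of the volume at physical point ``p`` (mm).

    With ``clamp=False`` a point outside the physical bounding box raises;
    with ``clamp=True`` it returns 0 (empty space), and points in the
    half-voxel margin clamp to the nearest face value.  The result is always
    within the [min, max] of the 8 surrounding voxels, and a query at a voxel
    center reproduces that voxel's stored value.
    """
    f = _fractional_index(vol, p)
    nx, ny, nz = vol.shape
    if np.any(f < -0.5) or np.any(f > np.asarray(vol.shape) - 0.5):
        if clamp:
            return 0.0
        raise VolumeError(f"point {p} outside volume bounds")
    fx = min(max(f[0], 0.0), nx - 1.0)
    fy = min(max(f[1], 0.0), ny - 1.0)
    fz = min(max(f[2], 0.0), nz - 1.0)
    i0 = min(int(fx), nx - 2)
    j0 = min(int(fy), ny - 2)
    k0 = min(int(fz), nz - 2)
    tx, ty, tz = fx - i0, fy - j0, fz - k0
    d = vol.data
    c00 = d[i0, j0, k0] * (1 - tx) + d[i0 + 1, j0, k0] * tx
    c10 = d[i0, j0 + 1, k0] * (1 - tx) + d[i0 + 1, j0 + 1, k0] * tx
    c01 = d[i0, j0, k0 + 1] * (1 - tx) + d[i0 + 1, j0, k0 + 1] * tx
    c11 = d[i0, j0 + 1, k0 + 1] * (1 - tx) + d[i0 + 1, j0 + 1, k0 + 1] * tx
    c0 = c00 * (1 - ty) + c10 * ty
    c1 = c01 * (1 - ty) + c11 * ty
    return float(c0 * (1 - tz) + c1 * tz)


def gradient_at(vol: Volume, p) -> np.ndarray:
    """Central-difference intensity gradient at physical point ``p``.

    Units are intensity per mm.  The gradient is evaluated by sampling the
    trilinear interpolant one voxel spacing apart along each axis (one-sided
    near the faces), which is exact for fields linear in each axis.
    """
    p = np.asarray(p, dtype=np.float64)
    sp = np.asarray(vol.spacing)
    lo = np.asarray(vol.origin)
    hi = lo + (np.asarray(vol.shape) - 1.0) * sp
    g = np.zeros(3)
    for ax in range(3):
        step = sp[ax]
        pp, pm = p.copy(), p.copy()
        pp[ax] = min(p[ax] + step, hi[ax])
        pm[ax] = max(p[ax] - step, lo[ax])
        if pp[ax] == pm[ax]:
            continue
        g[ax] = (sample_trilinear(vol, pp) - sample_trilinear(vol, pm)) / (
            pp[ax] - pm[ax]
        )
    return g


def field_dimensions(vol: Volume, mode: str = "voxel") -> tuple[int, int, int]:
    """Grid dimensions of the ambient light field for ``vol``.

    ``mode="voxel"`` (default): one field cell per voxel, the field is
    co-registered with the volume.  ``mode="physical"``: the in-plane
    dimensions still match the image, while the z extent is re-expressed on
    the in-plane pixel pitch, ``Vpz = (Vz - 1) * Ps`` with ``Ps`` the
    in-plane pixel spacing — useful when slices are much thicker than pixels
    and the field should be resampled isotropically along z.
    """
    nx, ny, nz = vol.shape
    if mode == "voxel":
        return (nx, ny, nz)
    if mode == "physical":
        ps = vol.spacing[0]
        vpz = max(1, int(round((nz - 1) * ps)))
        return (nx, ny, vpz)
    raise ValueError(f"unknown field mode {mode!r}")


# ---------------------------------------------------------------------------
# ambient field + image I/O
# ---------------------------------------------------------------------------


def write_field(fld: AmbientLightField, path) -> None:
    """Write an ambient light field as raw float32 + JSON sidecar with provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fld.data.astype("<f4").tofile(path)
    meta = {
        "dims": list(fld.shape),
        "dtype": "float32",
        "spacing": list(fld.spacing),
        "origin": list(fld.origin),
        "provenance": fld.provenance,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_field(path) -> AmbientLightField:
    path = Path(path)
    if not path.exists():
        raise IOError(f"ambient field file not found: {path}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise IOError(f"missing JSON sidecar for ambient field: {sidecar}")
    meta = json.loads(sidecar.read_text())
    dims = tuple(int(d) for d in meta["dims"])
    arr = np.fromfile(path, dtype="<f4").reshape(dims, order="C")
    return AmbientLightField(
        arr,
        spacing=tuple(meta.get("spacing", (1.0, 1.0, 1.0))),
        origin=tuple(meta.get("origin", (0.0, 0.0, 0.0))),
        provenance=meta.get("provenance", {}),
    )


def write_image(img: np.ndarray, path) -> None:
    """Write an (H, W, 3) float image in [0,1] as 8-bit RGB PNG."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.clip(np.asarray(img, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(path, (arr * 255.0 + 0.5).astype(np.uint8))
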