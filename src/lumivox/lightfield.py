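"""Precompute the global ambient light field by spherical multi-light photon mapping.

The idea follows the shadowless surgical lamp: a single large-area light
source removes the umbra behind an occluder, and many such sources arranged
on a sphere around the subject remove directional shading altogether, leaving
smooth low-frequency illumination.  Here the "lamps" are circular area
emitters placed on the circumscribed sphere of the volume, all facing its
center, each wide enough to cover the whole dataset.  Photons are launched
from each disk, marched through the classified volume, split at every
interaction into transmitted / reflected / deposited shares, and the
deposited energy accumulates into a voxel-aligned scalar field that the
renderer later samples as ambient light.

Energy bookkeeping is exact: for every photon the deposited, exited and
dropped (sub-threshold) shares sum to the launch energy, which makes the
whole precompute auditable — the field total can never exceed the total
emitted energy.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import NamedTuple

import numpy as np

from . import _kernels
from .volume_io import AmbientLightField, TransferFunction, Volume

__all__ = [
    "LightSource",
    "Photon",
    "PrecomputeConfig",
    "TraceResult",
    "sphere_directions",
    "build_lights",
    "disk_ray_origins",
    "schlick",
    "split_photon",
    "trace_photon",
    "precompute_field",
]


@dataclass
class LightSource:
    """Circular area emitter on the volume's circumscribed sphere.

    ``center`` lies on the sphere, ``direction`` is the unit vector pointing
    at the volume center, and ``disk_radius`` exceeds the sphere radius so the
    emitted parallel beam covers the whole dataset.
    """

    center: np.ndarray
    direction: np.ndarray
    disk_radius: float
    intensity: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=np.float64)
        self.direction = np.asarray(self.direction, dtype=np.float64)
        n = np.linalg.norm(self.direction)
        if not np.isclose(n, 1.0, atol=1e-9):
            raise ValueError(f"light direction must be unit length, |d| = {n}")


@dataclass
class Photon:
    """A traveling energy packet: position (mm), unit direction, energy, depth."""

    position: np.ndarray
    direction: np.ndarray
    energy: float
    depth: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=np.float64)
        self.direction = np.asarray(self.direction, dtype=np.float64)
        if self.energy < 0:
            raise ValueError("photon energy must be non-negative")


@dataclass
class PrecomputeConfig:
    """Knobs of the ambient-field precompute.

    Parameters
    ----------
    n_lights
        Number of area light sources, uniformly spread on the sphere.
    rays_per_light
        Photons launched per source; each carries ``intensity/rays_per_light``.
    epsilon
        Minimum live photon energy; children below it are dropped.
    max_depth
        Maximum reflection recursion depth (the transmitted continuation does
        not count — depth grows only through mirror bounces).
    f0
        Fresnel reflectance at normal incidence (Schlick); 0.04 is the usual
        dielectric value.
    gradient_threshold
        Minimum gradient magnitude (intensity/mm) for a defined surface
        normal; below it the reflected share folds into the deposit.
    step
        Ray-march step as a fraction of the smallest voxel spacing.
    disk_radius_factor
        Light disk radius as a multiple of the circumscribed-sphere radius.
        Values above 1 guarantee each beam covers the whole volume (the
        default 1.05 keeps it strictly larger); smaller values deliberately
        under-cover and are useful for studying how illuminated coverage
        grows with source area.
    seed
        Drives the stratified disk sampling; fully determines the field.
    """

    n_lights: int = 72
    rays_per_light: int = 1024
    epsilon: float = 1e-3
    max_depth: int = 8
    f0: float = 0.04
    gradient_threshold: float = 1e-6
    step: float = 0.5
    disk_radius_factor: float = 1.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lights < 1:
            raise ValueError("n_lights must be >= 1")
        if self.rays_per_light < 1:
            raise ValueError("rays_per_light must be >= 1")
        if not 0 < self.epsilon < 1:
            raise ValueError("epsilon must lie in (0, 1)")
        if not 0 <= self.f0 <= 1:
            raise ValueError("f0 must lie in [0, 1]")
        if self.disk_radius_factor <= 0.0:
            raise ValueError("disk_radius_factor must be positive")


class TraceResult(NamedTuple):
    """Energy ledger of one photon trace; the three shares sum to the input."""

    deposited: float
    exited: float
    dropped: float


# ---------------------------------------------------------------------------
# light-source geometry
# ---------------------------------------------------------------------------


def sphere_directions(n: int, seed: int = 0) -> np.ndarray:
    """``n`` near-uniform unit vectors from a spherical Fibonacci lattice.

    The lattice is deterministic; the seed applies a fixed random rotation so
    different seeds decorrelate light placement without touching uniformity.
    Returns an (n, 3) array of unit vectors whose sum is nearly zero for
    n >= 12 (antipodal balance).
    """
    if n < 1:
        raise ValueError("need at least one direction")
    i = np.arange(n, dtype=np.float64)
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * i
    dirs = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    # seeded rigid rotation (QR of a random matrix, det forced positive)
    rng = np.random.default_rng(seed)
    q, rr = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q * np.sign(np.diag(rr))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    dirs = dirs @ q.T
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def build_lights(vol: Volume, cfg: PrecomputeConfig) -> list[LightSource]:
    """Place one light per sphere direction, all with equal intensity.

    Centers sit exactly on the circumscribed sphere (radius = half the box
    diagonal) and directions point at the volume center.  Intensities are
    ``1/n_lights`` each so the total emission is normalized to 1.
    """
    center = vol.center
    radius = vol.circumradius
    dirs = sphere_directions(cfg.n_lights, cfg.seed)
    lights = []
    for d in dirs:
        lights.append(
            LightSource(
                center=center + radius * d,
                direction=-d,
                disk_radius=cfg.disk_radius_factor * radius,
                intensity=1.0 / cfg.n_lights,
            )
        )
    return lights


def _orthonormal_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors spanning the plane perpendicular to unit vector d."""
    if abs(d[0]) > 0.9:
        u = np.cross(d, np.array([0.0, 1.0, 0.0]))
    else:
        u = np.cross(d, np.array([1.0, 0.0, 0.0]))
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def disk_ray_origins(src: LightSource, k: int, seed: int = 0) -> np.ndarray:
    """``k`` stratified ray origins on the source disk (all rays share
    ``src.direction``).

    Uses a jittered sqrt-radial / golden-angle spiral: sample ``i`` sits at
    radius ``R*sqrt((i+u_i)/k)`` and azimuth ``i*golden + v_i`` with seeded
    jitters, giving low-discrepancy coverage of the disk that stays
    deterministic for a fixed seed.
    """
    if k < 1:
        raise ValueError("need at least one ray origin")
    rng = np.random.default_rng(seed)
    i = np.arange(k, dtype=np.float64)
    radii = src.disk_radius * np.sqrt((i + rng.random(k)) / k)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    angles = golden * i + 2.0 * np.pi * rng.random(k) / k
    u, v = _orthonormal_basis(src.direction)
    return (
        src.center[None, :]
        + radii[:, None] * np.cos(angles)[:, None] * u[None, :]
        + radii[:, None] * np.sin(angles)[:, None] * v[None, :]
    )


# ---------------------------------------------------------------------------
# photon physics
# ---------------------------------------------------------------------------


def schlick(cos_hv: float, f0: float) -> float:
    """Schlick approximation of Fresnel reflectance.

    ``F = F0 + (1 - F0) * (1 - cos)^5`` with the cosine clamped to [0, 1]:
    F0 at normal incidence, rising monotonically to 1 at grazing angles.
    """
    if not 0 <= f0 <= 1:
        raise ValueError("F0 must lie in [0, 1]")
    c = min(max(float(cos_hv), 0.0), 1.0)
    return f0 + (1.0 - f0) * (1.0 - c) ** 5


def split_photon(energy: float, alpha: float, fresnel: float) -> tuple[float, float, float]:
    """Split photon energy at one interaction into (transmitted, reflected, deposited).

    ``LT = E*(1-alpha)`` passes through, ``LR = E*F'`` mirrors off the local
    surface, and the remainder ``LC = E - LT - LR = E*(alpha - F')`` is
    deposited as ambient light.  The reflectance is clamped to
    ``F' = min(F, alpha)`` so the deposit can never go negative; the three
    shares always sum exactly to the input energy.
    """
    if energy < 0:
        raise ValueError("photon energy must be non-negative")
    if not 0 < alpha <= 1:
        raise ValueError("split only happens where alpha is in (0, 1]")
    if not 0 <= fresnel <= 1:
        raise ValueError("reflectance must lie in [0, 1]")
    fp = min(fresnel, alpha)
    lt = energy * (1.0 - alpha)
    lr = energy * fp
    lc = max(energy - lt - lr, 0.0)  # round-off guard when fp == alpha
    return lt, lr, lc


def _tf_arrays(tf: TransferFunction) -> tuple[np.ndarray, np.ndarray]:
    return (
        np.ascontiguousarray(tf.values, dtype=np.float64),
        np.ascontiguousarray(tf.rgba[:, 3], dtype=np.float64),
    )


def trace_photon(
    photon: Photon,
    vol: Volume,
    tf: TransferFunction,
    field: np.ndarray,
    cfg: PrecomputeConfig,
) -> TraceResult:
    """Trace one photon, accumulating deposits into ``field`` (same shape as
    the volume), and return the energy ledger.

    The trace marches at ``cfg.step * min(spacing)`` millimetres; every
    sample with non-zero opacity splits the photon (see :func:`split_photon`),
    deposits into the cell containing the sample, continues the transmitted
    share straight and queues the reflected share mirrored about the gradient
    normal.  See :func:`lumivox._kernels.trace_photon_kernel` for the inner
    loop.
    """
    if not np.all(np.isfinite(photon.position)) or not np.all(
        np.isfinite(photon.direction)
    ):
        raise ValueError("non-finite photon state")
    if field.shape != vol.shape:
        raise ValueError("field accumulator must match the volume shape")
    tf_v, tf_a = _tf_arrays(tf)
    step_mm = cfg.step * min(vol.spacing)
    dep, ext, drp = _kernels.trace_photon_kernel(
        np.ascontiguousarray(photon.position),
        np.ascontiguousarray(photon.direction),
        float(photon.energy),
        int(photon.depth),
        vol.data,
        np.asarray(vol.origin),
        np.asarray(vol.spacing),
        tf_v,
        tf_a,
        field,
        cfg.epsilon,
        cfg.max_depth,
        cfg.f0,
        cfg.gradient_threshold,
        step_mm,
    )
    return TraceResult(dep, ext, drp)


def precompute_field(
    vol: Volume, tf: TransferFunction, cfg: PrecomputeConfig | None = None
) -> AmbientLightField:
    """Run the full precompute: all lights, all photons, one ambient field.

    Every light launches ``rays_per_light`` photons of energy
    ``intensity / rays_per_light`` from stratified positions on its disk, all
    parallel to the light direction.  Field cell values are the summed
    deposits, so the field total is bounded by the total emission (= 1).
    Deterministic for a fixed config; per-light seeds are derived from
    ``cfg.seed`` with a seed sequence so light order cannot matter.
    """
    cfg = cfg or PrecomputeConfig()
    tf_v, tf_a = _tf_arrays(tf)
    step_mm = cfg.step * min(vol.spacing)
    field = np.zeros(vol.shape)
    lights = build_lights(vol, cfg)
    totals = np.zeros(3)
    for idx, src in enumerate(lights):
        child_seed = int(np.random.SeedSequence([cfg.seed, idx]).generate_state(1)[0] % (2**31))
        origins = disk_ray_origins(src, cfg.rays_per_light, seed=child_seed)
        energies = np.full(cfg.rays_per_light, src.intensity / cfg.rays_per_light)
        dep, ext, drp = _kernels.precompute_kernel(
            origins,
            np.ascontiguousarray(src.direction),
            energies,
            vol.data,
            np.asarray(vol.origin),
            np.asarray(vol.spacing),
            tf_v,
            tf_a,
            field,
            cfg.epsilon,
            cfg.max_depth,
            cfg.f0,
            cfg.gradient_threshold,
            step_mm,
        )
        totals += (dep, ext, drp)
    provenance = {
        "tf_hash": tf.content_hash(),
        "config": asdict(cfg),
        "energy": {
            "deposited": totals[0],
            "exited": totals[1],
            "dropped": totals[2],
        },
    }
    return AmbientLightField(
        field, spacing=vol.spacing, origin=vol.origin, provenance=provenance
    )


def coverage_experiment(
    vol: Volume,
    tf: TransferFunction,
    cfg: PrecomputeConfig,
    factors: tuple[float, ...] = (0.25, 0.5, 1.0),
) -> list[AmbientLightField]:
    """Grow the light aperture and return one ambient field per disk radius.

    Emulates the growing-source-area study behind the shadowless-lamp
    principle: each light's ray set is generated once at the largest
    requested radius (``max(factors)`` times the circumscribed-sphere
    radius), and for a smaller factor only the rays whose origins fall within
    that aperture are traced.  A smaller disk therefore emits a strict subset
    of the larger disk's photons, so the set of illuminated cells — and with
    it the rendered coverage — can only grow with the source radius; unlit
    material shrinks monotonically, independent of sampling density.

    Per-photon energy is ``1 / (n_lights * rays_per_light)`` at every
    aperture, i.e. the emitted power scales with the open area.
    """
    tf_v, tf_a = _tf_arrays(tf)
    step_mm = cfg.step * min(vol.spacing)
    radius = vol.circumradius
    max_factor = max(factors)
    full_cfg = PrecomputeConfig(**{**asdict(cfg), "disk_radius_factor": max_factor})
    lights = build_lights(vol, full_cfg)
    per_light = []
    for idx, src in enumerate(lights):
        child_seed = int(
            np.random.SeedSequence([cfg.seed, idx]).generate_state(1)[0] % (2**31)
        )
        per_light.append(disk_ray_origins(src, cfg.rays_per_light, seed=child_seed))

    fields = []
    for factor in factors:
        aperture = factor * radius
        field = np.zeros(vol.shape)
        for src, origins in zip(lights, per_light):
            off = origins - src.center[None, :]
            keep = np.linalg.norm(off, axis=1) <= aperture + 1e-12
            if not np.any(keep):
                continue
            kept = np.ascontiguousarray(origins[keep])
            energies = np.full(kept.shape[0], src.intensity / cfg.rays_per_light)
            _kernels.precompute_kernel(
                kept,
                np.ascontiguousarray(src.direction),
                energies,
                vol.data,
                np.asarray(vol.origin),
                np.asarray(vol.spacing),
                tf_v,
                tf_a,
                field,
                cfg.epsilon,
                cfg.max_depth,
                cfg.f0,
                cfg.gradient_threshold,
                step_mm,
            )
        fields.append(
            AmbientLightField(
                field,
                spacing=vol.spacing,
                origin=vol.origin,
                provenance={
                    "tf_hash": tf.content_hash(),
                    "config": asdict(cfg),
                    "aperture_factor": factor,
                },
            )
        )
    return fields
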