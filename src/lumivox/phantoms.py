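"""Synthetic test volumes and transfer functions with known analytic structure.

Every stage of the pipeline is testable without a medical dataset: the
phantoms here have closed-form inside/outside predicates, so quantities like
surface position, projected silhouette diameter or the set of material voxels
are known exactly.  All phantoms are deterministic functions of
``(spec, dims, spacing)``; noise, when requested, comes from a seeded
generator.

Phantom kinds
-------------
uniform
    Constant intensity everywhere.
solid_sphere
    A filled ball of one material in background.
spherical_shell
    A hollow shell (ball minus concentric smaller ball).
two_material_block
    Two axis-aligned half-space slabs with different intensity levels.
single_column
    A 1-voxel-wide chain of material voxels along one axis — the photon
    tracer's hand-computable oracle geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume_io import TransferFunction, Volume

__all__ = ["PhantomSpec", "GroundTruth", "make_phantom", "make_test_tf"]

KINDS = ("uniform", "solid_sphere", "spherical_shell", "two_material_block", "single_column")

#: Intensity assigned to phantom material (background is 0).  Chosen to sit in
#: a CT-like soft-tissue/bone range so transfer functions look realistic.
MATERIAL_LEVEL = 1000.0
SECOND_LEVEL = 500.0


@dataclass
class PhantomSpec:
    """Declarative description of a synthetic volume.

    Parameters
    ----------
    kind
        One of :data:`KINDS`.
    center
        Geometry center in voxel indices; defaults to the grid center.
    radius
        Sphere/shell outer radius in voxels.
    thickness
        Shell thickness in voxels (``spherical_shell`` only).
    level, level2
        Material intensity values (``level2`` for the second material).
    axis
        Column axis for ``single_column``.
    noise_sigma
        Additive Gaussian intensity noise (0 = clean analytic phantom).
    seed
        Fully determines the output for a given spec.
    """

    kind: str = "solid_sphere"
    center: tuple[float, float, float] | None = None
    radius: float = 20.0
    thickness: float = 3.0
    level: float = MATERIAL_LEVEL
    level2: float = SECOND_LEVEL
    axis: int = 2
    column_alphas: tuple[float, ...] | None = None
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; choose from {KINDS}")


@dataclass
class GroundTruth:
    """Analytic record emitted alongside a phantom."""

    material_voxels: int
    analytic_volume: float
    inside: object = field(repr=False, default=None)  # predicate on voxel indices
    levels: dict = field(default_factory=dict)


def _index_grids(dims):
    return np.meshgrid(*[np.arange(n, dtype=np.float64) for n in dims], indexing="ij")


def make_phantom(
    spec: PhantomSpec,
    dims: tuple[int, int, int] = (64, 64, 64),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[Volume, GroundTruth]:
    """Build a synthetic volume plus its analytic ground-truth record.

    The ground truth contains the exact material voxel count, the analytic
    (continuous) volume of the geometry, and the inside-predicate used to
    classify voxels, so tests can compare discrete against analytic measures.
    """
    dims = tuple(int(d) for d in dims)
    if min(dims) < 4:
        raise ValueError(f"phantom grids need >= 4 voxels per axis, got {dims}")
    c = spec.center if spec.center is not None else tuple((d - 1) / 2.0 for d in dims)

    ii, jj, kk = _index_grids(dims)
    data = np.zeros(dims)
    levels = {"background": 0.0}

    if spec.kind == "uniform":
        data[...] = spec.level
        inside = np.ones(dims, dtype=bool)
        analytic = float(np.prod(dims))
        levels["material"] = spec.level
    elif spec.kind in ("solid_sphere", "spherical_shell"):
        if spec.radius > min(d - 1 for d in dims) / 2.0:
            raise ValueError(
                f"radius {spec.radius} does not fit inside grid {dims}"
            )
        r2 = (ii - c[0]) ** 2 + (jj - c[1]) ** 2 + (kk - c[2]) ** 2
        inside = r2 <= spec.radius**2
        analytic = 4.0 / 3.0 * np.pi * spec.radius**3
        if spec.kind == "spherical_shell":
            inner = spec.radius - spec.thickness
            if inner <= 0:
                raise ValueError("shell thickness must be smaller than radius")
            inside &= r2 > inner**2
            analytic -= 4.0 / 3.0 * np.pi * inner**3
        data[inside] = spec.level
        levels["material"] = spec.level
    elif spec.kind == "two_material_block":
        half = dims[spec.axis] // 2
        idx = (ii, jj, kk)[spec.axis]
        first = idx < half
        data[first] = spec.level
        data[~first] = spec.level2
        inside = np.ones(dims, dtype=bool)
        analytic = float(np.prod(dims))
        levels["material"] = spec.level
        levels["material2"] = spec.level2
    elif spec.kind == "single_column":
        # 1-voxel chain along `axis` through the grid center; interior voxels
        # are material, the first and last stay background so the chain is
        # embedded in vacuum.
        inside = np.zeros(dims, dtype=bool)
        ci = tuple(int(round(x)) for x in c)
        sel = [ci[0], ci[1], ci[2]]
        for t in range(1, dims[spec.axis] - 1):
            sel[spec.axis] = t
            inside[tuple(sel)] = True
        data[inside] = spec.level
        analytic = float(dims[spec.axis] - 2)
        levels["material"] = spec.level
    else:  # pragma: no cover - guarded in PhantomSpec
        raise ValueError(spec.kind)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sigma, size=dims)

    gt = GroundTruth(
        material_voxels=int(np.count_nonzero(inside)),
        analytic_volume=analytic,
        inside=inside,
        levels=levels,
    )
    return Volume(data, spacing=spacing), gt


def make_test_tf(kind: str = "opaque_surface", level: float = MATERIAL_LEVEL) -> TransferFunction:
    """Preset transfer functions for the phantom material level.

    opaque_surface
        Background transparent, material fully opaque white (alpha = 1):
        surface-style rendering.
    semi_transparent
        Material at alpha = 0.3, warm grey: translucent-tissue style.
    two_band
        Two intensity bands with distinct colors/opacities (soft band around
        ``SECOND_LEVEL``, hard band around ``level``): two-material styling.
    """
    ramp = 0.25 * level  # narrow linear foot so classification is crisp
    if kind == "opaque_surface":
        return TransferFunction(
            [
                (0.0, (0.0, 0.0, 0.0, 0.0)),
                (level - ramp, (0.0, 0.0, 0.0, 0.0)),
                (level, (1.0, 1.0, 1.0, 1.0)),
            ]
        )
    if kind == "semi_transparent":
        return TransferFunction(
            [
                (0.0, (0.0, 0.0, 0.0, 0.0)),
                (level - ramp, (0.0, 0.0, 0.0, 0.0)),
                (level, (0.9, 0.8, 0.7, 0.3)),
            ]
        )
    if kind == "two_band":
        lo, hi = SECOND_LEVEL, level
        return TransferFunction(
            [
                (0.0, (0.0, 0.0, 0.0, 0.0)),
                (lo - 0.2 * lo, (0.0, 0.0, 0.0, 0.0)),
                (lo, (0.8, 0.2, 0.2, 0.25)),
                (lo + 0.2 * lo, (0.0, 0.0, 0.0, 0.0)),
                (hi - 0.1 * hi, (0.0, 0.0, 0.0, 0.0)),
                (hi, (0.95, 0.95, 0.9, 1.0)),
            ]
        )
    raise ValueError(f"unknown transfer-function preset {kind!r}")
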