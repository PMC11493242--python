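"""Precompute the global ambient light field for the sphere phantom.

72 circular area lights on the circumscribed sphere (each disk wider than the
volume, as a shadowless lamp requires) launch 1024 photons apiece; deposits
accumulate into a voxel-aligned scalar field.  The energy ledger printed at
the end is exact bookkeeping, not an estimate.
"""

from pathlib import Path

import numpy as np

import lumivox as lv

out = Path("scratch/example02")
out.mkdir(parents=True, exist_ok=True)

vol, gt = lv.make_phantom(lv.PhantomSpec(kind="solid_sphere", radius=20.0), dims=(64, 64, 64))
tf = lv.make_test_tf("opaque_surface")
cfg = lv.PrecomputeConfig(n_lights=72, rays_per_light=1024, seed=0)

fld = lv.precompute_field(vol, tf, cfg)
lv.write_field(fld, out / "field.raw")

ledger = fld.provenance["energy"]
print(f"photons traced: {cfg.n_lights * cfg.rays_per_light}")
print(f"deposited: {ledger['deposited']:.4f}  exited: {ledger['exited']:.4f}  "
      f"dropped: {ledger['dropped']:.4f}  (sums to 1.0)")

# the opaque sphere shields its core: deposits live on the surface shell only
idx = np.indices(vol.shape, dtype=float)
r = np.sqrt(((idx - 31.5) ** 2).sum(axis=0))
print(f"max field value in the core (r<15): {fld.data[r < 15].max():.2e}")
print(f"lit fraction of the outermost material layer: "
      f"{(fld.data[gt.inside & (r >= 19)] > 0).mean():.2%}")
# Most emitted energy misses the phantom (the disks cover the whole 64 mm box,
# the sphere is only 40 mm wide) and exits; what is absorbed sits exactly on
# the surface, with the interior in full shadow as physics demands.
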