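"""Render the phantom by fusion ray casting: ambient + transmitted light.

The fused color of each sample is C*alpha*(L_ambient*dim1 + L_transmitted*dim2).
The ambient field stores raw deposited energy (a fraction of unit total
emission per cell), so dim1 is set to ~1/max(field) to bring that term to
display scale; dim2 stays at 0.5.
"""

from pathlib import Path

import lumivox as lv

out = Path("scratch/example03")
out.mkdir(parents=True, exist_ok=True)

vol, _ = lv.make_phantom(lv.PhantomSpec(kind="solid_sphere", radius=20.0), dims=(64, 64, 64))
tf = lv.make_test_tf("opaque_surface")
fld = lv.precompute_field(vol, tf, lv.PrecomputeConfig(n_lights=72, rays_per_light=1024, seed=0))

dim1 = 0.5 / fld.data.max()
settings = lv.RenderSettings(dim1=dim1, dim2=0.5)
cam = lv.orbit_camera(vol, azimuth_deg=30.0, elevation_deg=20.0, width=128, height=128)

img = lv.render_image(cam, vol, tf, fld, settings)
lv.write_image(img, out / "fused.png")

fg = img.mean(axis=2)
print(f"ambient weight dim1 = {dim1:.1f} (1/max field), transmitted weight dim2 = 0.5")
print(f"foreground pixels: {(fg > 0).sum()} of {fg.size}")
print(f"mean foreground brightness: {fg[fg > 0].mean():.3f}")
print(f"wrote {out / 'fused.png'}")
# The silhouette is the sphere's orthographic projection; brightness combines
# the view-independent ambient shell glow with the view ray's absorbed energy.
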