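"""Light geometry, photon splitting, tracing and the ambient-field precompute."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import lumivox as lv
from lumivox.lightfield import coverage_experiment
from reference_tracer import enumerate_split_tree


class TestSphereDirections:
    def test_single_direction_is_unit(self):
        d = lv.sphere_directions(1, seed=0)
        assert d.shape == (1, 3)
        assert np.linalg.norm(d[0]) == pytest.approx(1.0, abs=1e-12)

    def test_72_unit_vectors(self):
        d = lv.sphere_directions(72, seed=0)
        assert d.shape == (72, 3)
        np.testing.assert_allclose(np.linalg.norm(d, axis=1), 1.0, atol=1e-12)

    @pytest.mark.parametrize("n", [12, 72, 100])
    def test_antipodal_balance(self, n):
        d = lv.sphere_directions(n, seed=0)
        assert np.linalg.norm(d.sum(axis=0)) < 0.05 * n

    def test_minimum_pairwise_angle_near_equal_area_ideal(self):
        d = lv.sphere_directions(100, seed=0)
        dots = np.clip(d @ d.T, -1.0, 1.0)
        np.fill_diagonal(dots, -1.0)
        min_angle = np.arccos(dots.max())  # brute-force pairwise scan
        ideal = np.sqrt(4.0 * np.pi / 100)
        assert min_angle > 0.6 * ideal

    def test_seed_rotates_but_preserves_uniformity(self):
        a = lv.sphere_directions(32, seed=0)
        b = lv.sphere_directions(32, seed=5)
        assert not np.allclose(a, b)
        np.testing.assert_allclose(np.linalg.norm(b, axis=1), 1.0, atol=1e-12)

    def test_rejects_nonpositive_count(self):
        with pytest.raises(ValueError):
            lv.sphere_directions(0)


class TestBuildLights:
    def test_centers_on_circumscribed_sphere(self, sphere64):
        vol, _ = sphere64
        cfg = lv.PrecomputeConfig(n_lights=16, seed=0)
        lights = lv.build_lights(vol, cfg)
        assert len(lights) == 16
        r = vol.circumradius
        assert r == pytest.approx(0.5 * np.sqrt(3) * 64.0)
        for src in lights:
            assert np.linalg.norm(src.center - vol.center) == pytest.approx(r)

    def test_all_sources_face_the_volume(self, sphere64):
        vol, _ = sphere64
        for src in lv.build_lights(vol, lv.PrecomputeConfig(n_lights=16)):
            assert src.direction @ (vol.center - src.center) > 0

    def test_intensities_sum_to_one(self, sphere64):
        vol, _ = sphere64
        lights = lv.build_lights(vol, lv.PrecomputeConfig(n_lights=72))
        assert sum(s.intensity for s in lights) == pytest.approx(1.0, abs=1e-12)

    def test_disk_strictly_larger_than_circumsphere_by_default(self, sphere64):
        vol, _ = sphere64
        src = lv.build_lights(vol, lv.PrecomputeConfig(n_lights=4))[0]
        assert src.disk_radius > vol.circumradius


class TestDiskRayOrigins:
    @pytest.fixture()
    def src(self):
        return lv.LightSource(
            center=np.array([10.0, -3.0, 5.0]),
            direction=np.array([0.6, 0.8, 0.0]),
            disk_radius=7.0,
            intensity=1.0,
        )

    def test_single_origin_inside_disk(self, src):
        o = lv.disk_ray_origins(src, 1, seed=0)
        assert o.shape == (1, 3)
        assert np.linalg.norm(o[0] - src.center) <= src.disk_radius

    def test_origins_lie_in_disk_plane(self, src):
        o = lv.disk_ray_origins(src, 200, seed=1)
        offsets = o - src.center
        np.testing.assert_allclose(offsets @ src.direction, 0.0, atol=1e-9)
        assert np.all(np.linalg.norm(offsets, axis=1) <= src.disk_radius + 1e-9)

    def test_empirical_mean_near_disk_center(self, src):
        k = 4096
        o = lv.disk_ray_origins(src, k, seed=2)
        assert np.linalg.norm(o.mean(axis=0) - src.center) < 2 * src.disk_radius / np.sqrt(k)

    def test_deterministic_for_fixed_seed(self, src):
        np.testing.assert_array_equal(
            lv.disk_ray_origins(src, 64, seed=9), lv.disk_ray_origins(src, 64, seed=9)
        )


class TestSchlick:
    def test_normal_incidence_returns_f0(self):
        assert lv.schlick(1.0, 0.04) == pytest.approx(0.04)

    @pytest.mark.parametrize("f0", [0.0, 0.04, 0.5, 1.0])
    def test_grazing_limit_is_one(self, f0):
        assert lv.schlick(0.0, f0) == pytest.approx(1.0)

    def test_half_cosine_hand_value(self):
        # 0.04 + 0.96 * 0.5^5 = 0.07
        assert lv.schlick(0.5, 0.04) == pytest.approx(0.07)

    def test_invalid_f0_rejected(self):
        with pytest.raises(ValueError):
            lv.schlick(0.5, 1.5)

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_range_and_clamping(self, cos_hv, f0):
        f = lv.schlick(cos_hv, f0)
        assert 0.0 <= f <= 1.0
        assert lv.schlick(-0.3, f0) == lv.schlick(0.0, f0)


class TestSplitPhoton:
    def test_opaque_absorber(self):
        assert lv.split_photon(1.0, 1.0, 0.0) == (0.0, 0.0, 1.0)

    def test_half_transparent_with_reflection(self):
        lt, lr, lc = lv.split_photon(1.0, 0.5, 0.1)
        assert (lt, lr, lc) == pytest.approx((0.5, 0.1, 0.4))

    def test_reflectance_clamped_to_alpha(self):
        lt, lr, lc = lv.split_photon(2.0, 0.25, 0.5)
        assert (lt, lr, lc) == pytest.approx((1.5, 0.5, 0.0))
        assert lt + lr + lc == pytest.approx(2.0, abs=1e-12)

    def test_negative_energy_rejected(self):
        with pytest.raises(ValueError):
            lv.split_photon(-1.0, 0.5, 0.1)

    @given(
        st.floats(0, 10, allow_nan=False),
        st.floats(0.01, 1.0),
        st.floats(0, 1),
    )
    def test_conservation_and_nonnegativity(self, energy, alpha, fresnel):
        lt, lr, lc = lv.split_photon(energy, alpha, fresnel)
        assert lt >= 0 and lr >= 0 and lc >= 0
        assert lt + lr + lc == pytest.approx(energy, abs=1e-9)


class TestTracePhoton:
    def test_ray_missing_box_deposits_nothing(self):
        vol = lv.Volume(np.full((4, 4, 4), 1000.0))
        tf = lv.make_test_tf("opaque_surface")
        field = np.zeros(vol.shape)
        ph = lv.Photon((0.0, 0.0, -10.0), (0.0, 0.0, -1.0), 1.0)
        res = lv.trace_photon(ph, vol, tf, field, lv.PrecomputeConfig())
        assert res.deposited == 0.0
        assert res.exited == pytest.approx(1.0)
        assert field.sum() == 0.0

    def test_column_phantom_hand_computed_chain(self):
        vol, _ = lv.make_phantom(lv.PhantomSpec(kind="single_column"), dims=(4, 4, 4))
        tf = lv.TransferFunction([(0.0, (0, 0, 0, 0.0)), (1000.0, (1, 1, 1, 0.5))])
        cfg = lv.PrecomputeConfig(step=1.0, f0=0.0)
        field = np.zeros(vol.shape)
        ph = lv.Photon((2.0, 2.0, -5.0), (0.0, 0.0, 1.0), 1.0)
        res = lv.trace_photon(ph, vol, tf, field, cfg)
        np.testing.assert_allclose(field[2, 2, :], [0.0, 0.5, 0.25, 0.0], atol=1e-12)
        assert res.exited == pytest.approx(0.25, abs=1e-12)

    def test_energy_balance_on_random_phantom(self, rng):
        tf = lv.TransferFunction([(0.0, (0, 0, 0, 0.0)), (1000.0, (1, 1, 1, 0.7))])
        vol = lv.Volume(rng.uniform(0, 1000, size=(8, 8, 8)))
        cfg = lv.PrecomputeConfig(f0=0.2)
        for _ in range(20):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            ph = lv.Photon(rng.uniform(-2, 9, size=3), d, 1.0)
            field = np.zeros(vol.shape)
            res = lv.trace_photon(ph, vol, tf, field, cfg)
            assert sum(res) == pytest.approx(1.0, abs=1e-9)
            assert field.sum() == pytest.approx(res.deposited, abs=1e-9)

    def test_nonfinite_photon_rejected(self):
        vol = lv.Volume(np.zeros((4, 4, 4)))
        tf = lv.make_test_tf("opaque_surface")
        ph = lv.Photon((0.0, 0.0, 0.0), (0.0, 0.0, 1.0), 1.0)
        ph.position = np.array([np.nan, 0.0, 0.0])
        with pytest.raises(ValueError):
            lv.trace_photon(ph, vol, tf, np.zeros((4, 4, 4)), lv.PrecomputeConfig())

    def test_matches_exhaustive_enumeration_on_tiny_volume(self, rng):
        tf = lv.TransferFunction(
            [(0.0, (0, 0, 0, 0.0)), (200.0, (0, 0, 0, 0.0)), (1000.0, (1, 1, 1, 0.8))]
        )
        cfg = lv.PrecomputeConfig(f0=0.3, max_depth=4)
        vol = lv.Volume(rng.uniform(0, 1000, size=(4, 4, 4)))
        for _ in range(5):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            origin = rng.uniform(-3, 6, size=3)
            origin[int(rng.integers(3))] = -4.0
            fast = np.zeros(vol.shape)
            slow = np.zeros(vol.shape)
            lv.trace_photon(lv.Photon(origin, d, 1.0), vol, tf, fast, cfg)
            enumerate_split_tree(origin, d, 1.0, 0, vol, tf, cfg, slow)
            np.testing.assert_allclose(fast, slow, atol=1e-9)


class TestPrecomputeField:
    def test_vacuum_volume_yields_zero_field(self):
        vol = lv.Volume(np.zeros((8, 8, 8)))
        tf = lv.make_test_tf("opaque_surface")
        cfg = lv.PrecomputeConfig(n_lights=4, rays_per_light=16, seed=0)
        fld = lv.precompute_field(vol, tf, cfg)
        assert fld.data.sum() == 0.0

    def test_total_deposit_bounded_by_emitted_energy(self, sphere_field72):
        assert sphere_field72.data.sum() <= 1.0 + 1e-6

    def test_opaque_sphere_lit_surface_dark_interior(self, sphere64, sphere_field72):
        _, gt = sphere64
        shape = sphere_field72.shape
        idx = np.indices(shape, dtype=float)
        r = np.sqrt(((idx - (np.array(shape)[:, None, None, None] - 1) / 2.0) ** 2).sum(0))
        assert sphere_field72.data[r < 15.0].max() == 0.0  # fully occluded core
        assert sphere_field72.data[~gt.inside & (r > 25.0)].max() == 0.0  # vacuum
        surf = gt.inside & (r >= 19.0)
        assert (sphere_field72.data[surf] > 0).mean() > 0.5

    def test_deterministic_for_fixed_config(self, sphere64):
        vol, _ = sphere64
        tf = lv.make_test_tf("semi_transparent")
        cfg = lv.PrecomputeConfig(n_lights=6, rays_per_light=64, seed=11)
        a = lv.precompute_field(vol, tf, cfg)
        b = lv.precompute_field(vol, tf, cfg)
        np.testing.assert_array_equal(a.data, b.data)

    def test_provenance_records_config_and_tf(self, sphere_field72, opaque_tf):
        prov = sphere_field72.provenance
        assert prov["tf_hash"] == opaque_tf.content_hash()
        assert prov["config"]["n_lights"] == 72
        ledger = prov["energy"]
        assert ledger["deposited"] + ledger["exited"] + ledger["dropped"] == pytest.approx(
            1.0, abs=1e-6
        )

    def test_field_registered_with_volume(self, sphere64, sphere_field72):
        vol, _ = sphere64
        assert sphere_field72.shape == vol.shape
        assert sphere_field72.spacing == vol.spacing
        assert sphere_field72.origin == vol.origin


class TestCoverageExperiment:
    def test_unlit_material_shrinks_with_light_radius(self):
        vol, gt = lv.make_phantom(
            lv.PhantomSpec(kind="spherical_shell", radius=10.0, thickness=2.0),
            dims=(32, 32, 32),
        )
        tf = lv.make_test_tf("opaque_surface")
        cfg = lv.PrecomputeConfig(n_lights=6, rays_per_light=128, seed=3)
        fields = coverage_experiment(vol, tf, cfg, factors=(0.25, 0.5, 1.0))
        zeros = [int((f.data[gt.inside] == 0).sum()) for f in fields]
        assert zeros[0] >= zeros[1] >= zeros[2]
        assert zeros[2] < zeros[0]  # growing the source really lights more cells
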