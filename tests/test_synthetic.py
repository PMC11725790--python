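"""Generator contracts: WLC statistics, confinement, rasterization, RSA,
slab cropping and scene determinism."""

import numpy as np
import pytest
from scipy import stats

from cryomesh import (
    PointProcessParams,
    Scene,
    SceneMeta,
    WLCParams,
    fragment_filaments,
    generate_assembly,
    generate_nucleoid,
    generate_points,
    generate_scene,
    generate_wlc_filament,
    sample_isotropic_axes,
    slab_crop,
    vmf_directions,
)
from cryomesh.io import Compartment, Filament, MaskLabel, PointSet, VoxelMask
from cryomesh.synthetic import AssemblyPreset, GridSpec, Sphere, rasterize_filaments


class TestWLC:
    def test_single_segment_chain(self):
        f = generate_wlc_filament(WLCParams(5.0, 100.0, 1), 3)
        assert len(f.points) == 2
        assert f.arc_length == pytest.approx(5.0)

    def test_rigid_limit_is_straight(self):
        f = generate_wlc_filament(WLCParams(5.0, 1e15, 400), 3)
        t = np.diff(f.points, axis=0)
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        assert np.all(t @ t[0] > 1.0 - 1e-12)

    def test_fixed_step_length(self):
        f = generate_wlc_filament(WLCParams(5.0, 40.0, 200), 9)
        steps = np.linalg.norm(np.diff(f.points, axis=0), axis=1)
        assert np.allclose(steps, 5.0)

    def test_seed_reproducibility(self):
        a = generate_wlc_filament(WLCParams(5.0, 80.0, 100), 42)
        b = generate_wlc_filament(WLCParams(5.0, 80.0, 100), 42)
        assert np.array_equal(a.points, b.points)

    def test_vmf_mean_cosine_matches_langevin(self, rng):
        # <t_i . t_{i+1}> for vMF(kappa) is coth(kappa) - 1/kappa
        kappa = 10.0
        v = vmf_directions((0, 0, 1.0), kappa, 10000, rng)
        expected = 1.0 / np.tanh(kappa) - 1.0 / kappa
        se = v[:, 2].std(ddof=1) / 100.0
        assert v[:, 2].mean() == pytest.approx(expected, abs=4 * se)

    def test_isotropic_axes_pass_ks_against_one_minus_cos(self, rng):
        v = sample_isotropic_axes(10000, rng)
        theta = np.arccos(np.clip(np.abs(v[:, 2]), 0, 1))
        res = stats.kstest(theta, lambda t: 1.0 - np.cos(t))
        assert res.pvalue > 0.01

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            WLCParams(segment_length=0.0)
        with pytest.raises(ValueError):
            WLCParams(n_segments=0)


class TestAssembly:
    def test_confinement_holds_all_points(self):
        preset = AssemblyPreset(n_filaments=10, filament_length=500.0,
                                confinement=Sphere((0, 0, 0), 100.0))
        fils, mask = generate_assembly(preset, 5)
        for f in fils:
            r = np.linalg.norm(f.points, axis=1)
            assert r.max() <= 100.0 + 1e-6
        assert mask.n_foreground > 0

    def test_perfect_alignment_limit(self):
        # confinement much larger than the chains so no wall reflection
        # ever redirects a rigid chain
        preset = AssemblyPreset(
            n_filaments=5, filament_length=200.0, lp_mean=1e15,
            confinement=Sphere((0, 0, 0), 1e5),
            alignment_sigma_deg=0.0, alignment_axis=(0, 0, 1.0),
        )
        grid = GridSpec.around((-400.0,) * 3, (400.0,) * 3, 4.0)
        fils, _ = generate_assembly(preset, 5, grid=grid)
        frags = fragment_filaments(fils, 20.0)
        cos = np.abs(frags.vectors @ np.array([0, 0, 1.0]))
        assert np.all(np.degrees(np.arccos(np.clip(cos, 0, 1))) < 1e-6)

    def test_isotropic_fragment_angles_follow_sine_law(self):
        preset = AssemblyPreset(n_filaments=60, filament_length=900.0,
                                lp_mean=60.0, confinement=Sphere((0, 0, 0), 110.0))
        fils, _ = generate_assembly(preset, 11)
        frags = fragment_filaments(fils, 20.0)
        theta = np.arccos(np.clip(np.abs(frags.vectors @ sample_isotropic_axes(
            1, np.random.default_rng(1))[0]), 0, 1))
        res = stats.kstest(theta, lambda t: 1.0 - np.cos(t))
        assert res.pvalue > 0.01


class TestNucleoid:
    def test_zero_dispersion_rigid_bundle_is_parallel(self):
        fils, _ = generate_nucleoid((1.0, 0, 0), (400, 100, 100), sigma_deg=0.0,
                                    lp=1e15, n_filaments=5, rng_seed=2)
        frags = fragment_filaments(fils, 20.0)
        cos = np.abs(frags.vectors @ np.array([1.0, 0, 0]))
        assert np.all(np.degrees(np.arccos(np.clip(cos, 0, 1))) < 1e-6)

    def test_bundle_more_ordered_than_isotropic_meshwork(self):
        from cryomesh import angles_to_mean, mean_orientation

        nfils, _ = generate_nucleoid((1.0, 0, 0), (500, 150, 150), rng_seed=4,
                                     n_filaments=20)
        preset = AssemblyPreset(n_filaments=30, filament_length=600.0,
                                lp_mean=60.0, confinement=Sphere((0, 0, 0), 110.0))
        afils, _ = generate_assembly(preset, 4)
        peaks = []
        for fils in (nfils, afils):
            fr = fragment_filaments(fils, 20.0)
            peaks.append(angles_to_mean(fr, mean_orientation(fr)).peak())
        assert peaks[0] < peaks[1]

    def test_mask_extent_matches_requested_length(self):
        length = 1000.0
        _, mask = generate_nucleoid((1.0, 0, 0), (length, 300, 100), rng_seed=8,
                                    n_filaments=30)
        xs = mask.voxel_centers()[:, 0]
        assert np.ptp(xs) == pytest.approx(length, abs=mask.voxel_size)


class TestRasterization:
    def test_dilated_straight_filament_volume_matches_capsule(self):
        L, r, voxel = 400.0, 8.0, 4.0  # voxel = r/2
        f = Filament("s", [[-L / 2, 0, 0], [L / 2, 0, 0]])
        grid = GridSpec.around((-L / 2 - 3 * r,) * 3, (L / 2 + 3 * r,) * 3, voxel)
        mask = rasterize_filaments([f], grid, radius=r)
        vol = mask.n_foreground * voxel**3
        capsule = np.pi * r**2 * L + 4.0 / 3.0 * np.pi * r**3
        assert abs(vol - capsule) / capsule < 0.20


class TestPointProcess:
    def _domain(self, n=40, voxel=5.0):
        return VoxelMask(MaskLabel.cytoplasm, np.ones((n, n, n), dtype=bool), voxel)

    def test_hard_core_distance_enforced(self):
        ps = generate_points(PointProcessParams(
            intensity=2e-5, hard_core_distance=25.0, domain=self._domain()), 3)
        from scipy.spatial import cKDTree
        d, _ = cKDTree(ps.coords).query(ps.coords, k=2)
        assert d[:, 1].min() >= 25.0

    def test_exclusion_mask_respected(self):
        dom = self._domain()
        ex = np.zeros(dom.grid.shape, dtype=bool)
        ex[10:30, 10:30, 10:30] = True
        exmask = VoxelMask(MaskLabel.condensate, ex, dom.voxel_size, dom.origin)
        ps = generate_points(PointProcessParams(
            intensity=2e-5, hard_core_distance=20.0, domain=dom,
            exclusion=[exmask]), 3)
        assert not exmask.contains(ps.coords).any()

    def test_target_count_reached_in_uncrowded_domain(self):
        dom = self._domain()
        lam = 200.0 / (dom.n_foreground * dom.voxel_size**3)
        ps = generate_points(PointProcessParams(
            intensity=lam, hard_core_distance=10.0, domain=dom), 7)
        assert len(ps) == 200

    def test_underfill_warns_not_raises(self):
        dom = VoxelMask(MaskLabel.cytoplasm, np.ones((8, 8, 8), dtype=bool), 5.0)
        with pytest.warns(UserWarning, match="under-filled"):
            ps = generate_points(PointProcessParams(
                intensity=1e-2, hard_core_distance=30.0, domain=dom,
                max_attempt_factor=2), 1)
        assert len(ps) >= 1


class TestSlabCrop:
    def _scene(self):
        fils = [Filament("v", [[0, 0, -100], [0, 0, 100]]),
                Filament("in", [[0, 0, 0], [50, 0, 10]])]
        pts = [PointSet("ribosome", [[0, 0, 0], [0, 0, 90.0]])]
        return Scene(filaments=fils, points=pts, meta=SceneMeta())

    def test_identity_when_content_inside(self):
        s = Scene(filaments=[Filament("in", [[0, 0, 0], [50, 0, 10]])],
                  meta=SceneMeta())
        out = slab_crop(s, -50.0, 100.0)
        assert np.allclose(out.filaments[0].points, s.filaments[0].points)
        assert out.meta.lamella_z == (-50.0, 50.0)

    def test_clip_point_lies_exactly_on_face(self):
        out = slab_crop(self._scene(), -50.0, 100.0)
        v = next(f for f in out.filaments if f.id.startswith("v"))
        zs = v.points[:, 2]
        assert zs.min() == -50.0 and zs.max() == 50.0

    def test_arc_length_never_increases(self, rng):
        pts = np.cumsum(rng.normal(0, 10, (60, 3)), axis=0)
        f = Filament("w", pts)
        s = Scene(filaments=[f], meta=SceneMeta())
        out = slab_crop(s, -15.0, 60.0)
        assert sum(g.arc_length for g in out.filaments) <= f.arc_length + 1e-9

    def test_points_outside_slab_removed(self):
        out = slab_crop(self._scene(), -50.0, 100.0)
        assert len(out.points[0]) == 1

    def test_disjoint_slab_warns_empty(self):
        with pytest.warns(UserWarning, match="disjoint"):
            out = slab_crop(self._scene(), 5000.0, 100.0)
        assert not out.filaments


class TestScene:
    def test_determinism_under_seed(self):
        from tests.conftest import small_preset

        a = generate_scene("WT", 7, preset=small_preset())
        b = generate_scene("WT", 7, preset=small_preset())
        assert len(a.filaments) == len(b.filaments)
        for fa, fb in zip(a.filaments, b.filaments):
            assert np.array_equal(fa.points, fb.points)
        assert np.array_equal(a.points[0].coords, b.points[0].coords)
        assert np.array_equal(a.get_mask(MaskLabel.condensate).grid,
                              b.get_mask(MaskLabel.condensate).grid)

    def test_wt_ribosomes_never_touch_condensate(self, wt_scene):
        cond = wt_scene.get_mask(MaskLabel.condensate)
        ribo = wt_scene.get_points("ribosome")
        assert not cond.contains(ribo.coords).any()

    def test_unknown_genotype_rejected(self):
        with pytest.raises(ValueError):
            generate_scene("dPomX", 1)

    def test_scene_is_slab_cropped_with_metadata(self, wt_scene):
        assert wt_scene.meta.lamella_z == (-50.0, 50.0)
        z = wt_scene.get_points("ribosome").coords[:, 2]
        assert z.min() >= -50.0 and z.max() <= 50.0
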