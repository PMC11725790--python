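"""Fragmentation, orientation-tensor mean, folded angles, peaks, radial profile."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cryomesh import (
    angles_to_mean,
    distribution_peak,
    fragment_filaments,
    mean_orientation,
    radial_profile,
    sample_isotropic_axes,
)
from cryomesh.io import Filament


def _straight(length, n=11, direction=(1.0, 0, 0), start=(0, 0, 0)):
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    t = np.linspace(0, length, n)
    return Filament("s", np.asarray(start) + t[:, None] * d)


def _rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()


class TestFragmentation:
    def test_straight_polyline_gives_identical_parallel_vectors(self):
        frags = fragment_filaments([_straight(100.0)], 20.0)
        assert len(frags) == 5
        assert np.allclose(frags.vectors, [[1, 0, 0]] * 5)
        assert np.allclose(frags.midpoints[:, 0], [10, 30, 50, 70, 90])

    def test_trailing_remainder_discarded(self):
        frags = fragment_filaments([_straight(95.0)], 20.0)
        assert len(frags) == 4

    def test_too_short_filament_counted_not_fragmented(self):
        frags = fragment_filaments([_straight(15.0), _straight(40.0)], 20.0)
        assert len(frags) == 2
        assert frags.n_too_short == 1

    def test_semicircle_chord_is_diameter(self):
        # a half-circle of arc length exactly 20 has chord 2R = 40/pi
        theta = np.linspace(0.0, np.pi, 2001)
        R = 20.0 / np.pi
        pts = np.column_stack([R * np.cos(theta), R * np.sin(theta), 0 * theta])
        f = Filament("arc", pts)
        pts *= 20.0 / f.arc_length  # rescale so polyline arc length is ~exact
        # cut at the polyline's own arc length (minus float slack) so the
        # single fragment spans the whole half-circle
        L = Filament("arc", pts).arc_length * (1.0 - 1e-12)
        frags = fragment_filaments([Filament("arc", pts)], L)
        assert len(frags) == 1
        seg = np.linalg.norm(pts[-1] - pts[0])
        assert seg == pytest.approx(2 * 20.0 / np.pi, rel=1e-3)
        assert np.allclose(np.linalg.norm(frags.vectors, axis=1), 1.0)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000), st.floats(5.0, 60.0))
    def test_fragment_count_is_floor_of_arc_length_ratio(self, seed, frag_len):
        rng = np.random.default_rng(seed)
        pts = np.cumsum(rng.normal(0, 8, (30, 3)), axis=0)
        f = Filament("w", pts)
        frags = fragment_filaments([f], frag_len)
        assert len(frags) == int(f.arc_length // frag_len)


class TestMeanOrientation:
    def test_axial_invariance_sign_flips(self):
        v = np.array([[0, 0, 1.0], [0, 0, -1.0], [0, 0, 1.0]])
        m = mean_orientation(v)
        assert abs(m @ [0, 0, 1.0]) == pytest.approx(1.0)

    def test_dominant_axis_wins(self):
        v = np.array([[1.0, 0, 0]] * 10 + [[0, 1.0, 0]] + [[0, 0, 1.0]])
        assert np.allclose(mean_orientation(v), [1, 0, 0])

    def test_rotation_equivariance(self, rng):
        v = sample_isotropic_axes(500, rng)
        R = _rotation(rng)
        m1 = mean_orientation(v)
        m2 = mean_orientation(v @ R.T)
        assert min(np.linalg.norm(R @ m1 - m2), np.linalg.norm(R @ m1 + m2)) < 1e-9

    def test_exact_tie_is_an_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            mean_orientation(np.eye(3))


class TestAngles:
    def test_parallel_and_perpendicular(self):
        d = angles_to_mean(np.array([[1.0, 0, 0], [0, 1.0, 0]]), [1.0, 0, 0])
        assert np.allclose(d.angles, [0.0, 90.0])

    def test_antiparallel_folds_to_zero(self):
        d = angles_to_mean(np.array([[-1.0, 0, 0]]), [1.0, 0, 0])
        assert d.angles[0] == pytest.approx(0.0)

    def test_isotropic_sample_mean_is_one_radian(self, rng):
        v = sample_isotropic_axes(50000, rng)
        d = angles_to_mean(v, mean_orientation(v))
        assert d.angles.mean() == pytest.approx(57.30, abs=0.5)

    def test_invariance_under_global_rotation(self, rng):
        v = sample_isotropic_axes(300, rng)
        m = mean_orientation(v)
        R = _rotation(rng)
        a = angles_to_mean(v, m).angles
        b = angles_to_mean(v @ R.T, R @ m).angles
        assert np.allclose(np.sort(a), np.sort(b), atol=1e-9)

    def test_histogram_counts_sum_to_n(self, rng):
        v = sample_isotropic_axes(1000, rng)
        d = angles_to_mean(v, mean_orientation(v))
        assert d.counts.sum() == d.n


class TestDistributionPeak:
    def test_point_mass(self):
        assert distribution_peak(np.full(50, 42.0), method="kde") == 42.0
        assert distribution_peak(np.full(50, 42.0), method="hist_mode") == 42.0

    def test_sine_density_mode_bin_is_at_upper_edge(self, rng):
        v = sample_isotropic_axes(50000, rng)
        d = angles_to_mean(v, mean_orientation(v))
        peak = distribution_peak(d.angles, method="hist_mode", lo=0.0, hi=90.0,
                                 bin_width=10.0)
        assert peak == 85.0  # center of the [80, 90) bin

    def test_flat_sample_has_low_peak_confidence(self, rng):
        flat = rng.uniform(0, 90, 20000)
        _, conf_flat = distribution_peak(flat, lo=0.0, hi=90.0,
                                         return_confidence=True)
        peaked = np.clip(rng.normal(45, 4, 20000), 0, 90)
        _, conf_peak = distribution_peak(peaked, lo=0.0, hi=90.0,
                                         return_confidence=True)
        assert conf_flat < 1.3 < conf_peak

    def test_hist_mode_tie_breaks_to_lower_bin(self):
        vals = np.array([1.0, 1.5, 11.0, 11.5])  # bins [0,10) and [10,20) tie
        assert distribution_peak(vals, method="hist_mode", lo=0.0, hi=20.0,
                                 bin_width=10.0) == 5.0


class TestRadialProfile:
    def test_great_circles_on_sphere_all_at_radius(self):
        r = 80.0
        t = np.linspace(0, 2 * np.pi, 721)
        c1 = np.column_stack([r * np.cos(t), r * np.sin(t), 0 * t])
        c2 = np.column_stack([0 * t, r * np.cos(t), r * np.sin(t)])
        rp = radial_profile([Filament("a", c1), Filament("b", c2)],
                            center=(0.0, 0.0, 0.0))
        assert rp.max == pytest.approx(r, rel=1e-4)
        assert rp.peak == pytest.approx(r, abs=0.5)
        assert np.allclose(rp.distances, r, atol=r * 1e-3)

    def test_straight_filament_max_is_half_length(self):
        rp = radial_profile([_straight(200.0, n=101, start=(-100, 0, 0))])
        assert rp.max == pytest.approx(100.0, abs=0.5)

    def test_monotone_under_adding_farther_filament(self):
        base = [_straight(100.0, start=(-50, 0, 0))]
        rp1 = radial_profile(base, center=(0, 0, 0))
        far = base + [_straight(20.0, start=(300, 0, 0))]
        rp2 = radial_profile(far, center=(0, 0, 0))
        assert rp2.max >= rp1.max

    def test_confinement_bounds_radial_max(self, wt_scene):
        from cryomesh.io import Compartment

        fils = wt_scene.filaments_in(Compartment.assembly)
        rp = radial_profile(fils)
        # confinement radius + WLC step + centroid slack bounds the profile
        assert rp.max <= 110.0 + 5.0 + 5.0
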