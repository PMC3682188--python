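"""Local orientational order, segments, defects, insertion depth."""

import numpy as np
import pytest

from enthcg.order import (find_defects, fit_shell, h0_axis, local_order,
                          order_trace, segment_order)


def _random_axes(rng, n):
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1)[:, None]


class TestH0Axis:
    def test_unit_direction(self):
        sites = np.zeros((16, 3))
        sites[1] = [2.0, 0.0, 0.0]
        np.testing.assert_allclose(h0_axis(sites), [1.0, 0.0, 0.0])

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        sites = rng.normal(0, 1, (16, 3))
        shifted = sites + np.array([3.0, -2.0, 7.0])
        np.testing.assert_allclose(h0_axis(sites), h0_axis(shifted))

    def test_rotation_equivariance(self):
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(2)
        sites = rng.normal(0, 1, (16, 3))
        for rot in Rotation.random(5, rng=3):
            np.testing.assert_allclose(h0_axis(sites @ rot.as_matrix().T),
                                       rot.as_matrix() @ h0_axis(sites),
                                       atol=1e-12)

    def test_coincident_sites_rejected(self):
        with pytest.raises(ValueError):
            h0_axis(np.zeros((16, 3)))


class TestLocalOrder:
    def test_parallel_axes_give_unity(self):
        n = 10
        axes = np.tile([0.0, 0.0, 1.0], (n, 1))
        pos = np.random.default_rng(0).uniform(0, 3, (n, 3))
        field = local_order(axes, pos, cutoff=10.0)
        np.testing.assert_allclose(field.local_order, 1.0)

    def test_antiparallel_pair_unsigned(self):
        axes = np.array([[0, 0, 1.0], [0, 0, -1.0]])
        pos = np.array([[0, 0, 0.0], [1.0, 0, 0]])
        field = local_order(axes, pos, cutoff=5.0)
        np.testing.assert_allclose(field.local_order, 1.0)

    def test_isotropic_axes_converge_to_half(self):
        # E|cos theta| = 1/2 for isotropic axes; with ~2000 domains the
        # all-pairs global mean has Monte-Carlo error well below 0.01
        rng = np.random.default_rng(5)
        n = 2000
        axes = _random_axes(rng, n)
        pos = rng.uniform(0, 10, (n, 3))
        field = local_order(axes, pos, cutoff=np.inf)
        assert field.global_mean == pytest.approx(0.5, abs=0.01)

    def test_no_neighbor_sentinel_excluded(self):
        axes = np.array([[0, 0, 1.0], [0, 0, 1.0], [1.0, 0, 0]])
        pos = np.array([[0, 0, 0.0], [1.0, 0, 0], [100.0, 0, 0]])
        field = local_order(axes, pos, cutoff=5.0)
        assert np.isnan(field.local_order[2])
        assert field.global_mean == pytest.approx(1.0)

    def test_tree_equals_brute_force(self):
        rng = np.random.default_rng(7)
        n = 400
        axes = _random_axes(rng, n)
        pos = rng.uniform(0, 8, (n, 3))
        tree = local_order(axes, pos, cutoff=2.5, method="tree")
        brute = local_order(axes, pos, cutoff=2.5, method="brute")
        np.testing.assert_allclose(tree.local_order, brute.local_order,
                                   atol=1e-12, equal_nan=True)

    def test_global_rotation_and_axis_flip_invariance(self):
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(9)
        n = 60
        axes = _random_axes(rng, n)
        pos = rng.uniform(0, 5, (n, 3))
        base = local_order(axes, pos, cutoff=3.0).local_order
        rot = Rotation.random(rng=11).as_matrix()
        rotated = local_order(axes @ rot.T, pos @ rot.T,
                              cutoff=3.0).local_order
        np.testing.assert_allclose(rotated, base, atol=1e-10,
                                   equal_nan=True)
        flip = rng.choice([-1.0, 1.0], n)[:, None]
        flipped = local_order(axes * flip, pos, cutoff=3.0).local_order
        np.testing.assert_allclose(flipped, base, atol=1e-12,
                                   equal_nan=True)


class TestOrderTrace:
    def test_static_frames_constant_and_converged(self):
        rng = np.random.default_rng(3)
        axes = _random_axes(rng, 20)
        pos = rng.uniform(0, 4, (20, 3))
        series, converged = order_trace([(axes, pos)] * 8)
        assert np.allclose(series, series[0])
        assert converged

    def test_frozen_ordered_coat_is_unity(self):
        axes = np.tile([1.0, 0, 0], (12, 1))
        pos = np.random.default_rng(0).uniform(0, 3, (12, 3))
        series, _ = order_trace([(axes, pos)] * 5)
        np.testing.assert_allclose(series, 1.0)

    def test_order_to_disorder_interpolation_decreases(self):
        rng = np.random.default_rng(10)
        n = 200
        iso = _random_axes(rng, n)
        pos = rng.uniform(0, 6, (n, 3))
        frames = []
        for lam in np.linspace(0.0, 1.0, 6):
            mixed = (1 - lam) * np.tile([0, 0, 1.0], (n, 1)) + lam * iso
            mixed /= np.linalg.norm(mixed, axis=1)[:, None]
            frames.append((mixed, pos))
        series, _ = order_trace(frames, cutoff=np.inf)
        assert all(b < a for a, b in zip(series, series[1:]))


class TestSegments:
    def _field(self, s_values, z):
        n = len(s_values)
        axes = np.tile([0, 0, 1.0], (n, 1))
        pos = np.zeros((n, 3))
        pos[:, 2] = z
        from enthcg.order import OrderField
        return OrderField(axes=axes, positions=pos,
                          local_order=np.asarray(s_values, float),
                          cutoff=5.0)

    def test_homogeneous_field(self):
        z = np.linspace(0, 10, 40)
        rep = segment_order(self._field(np.full(40, 0.9), z),
                            [0, 0, 1.0], 4)
        np.testing.assert_allclose(rep.means, 0.9)

    def test_two_block_field_recovered(self):
        z = np.concatenate([np.linspace(0, 4.9, 20),
                            np.linspace(5.1, 10, 20)])
        s = np.concatenate([np.full(20, 0.95), np.full(20, 0.80)])
        rep = segment_order(self._field(s, z), [0, 0, 1.0], 2)
        np.testing.assert_allclose(rep.means, [0.95, 0.80])

    def test_offset_choice_changes_boundary_segments_only(self):
        z = np.concatenate([np.linspace(0, 4.9, 20),
                            np.linspace(5.1, 10, 20)])
        s = np.concatenate([np.full(20, 0.95), np.full(20, 0.80)])
        field = self._field(s, z)
        aligned = segment_order(field, [0, 0, 1.0], 2, choice="aligned")
        offset = segment_order(field, [0, 0, 1.0], 2, choice="offset")
        assert aligned.means[0] == pytest.approx(0.95)
        assert aligned.means[-1] == pytest.approx(0.80)
        # interior bin of the offset choice straddles the block boundary
        assert any(0.80 < m < 0.95 for m in offset.means if np.isfinite(m))

    def test_cap_domains_reported_separately(self):
        z = np.linspace(0, 10, 30)
        s = np.full(30, 0.9)
        s[:5] = 0.6
        cap = np.zeros(30, bool)
        cap[:5] = True
        rep = segment_order(self._field(s, z), [0, 0, 1.0], 3,
                            cap_mask=cap)
        assert rep.cap_mean == pytest.approx(0.6)
        np.testing.assert_allclose(rep.means, 0.9)


class TestDefects:
    def test_ordered_field_empty(self):
        rng = np.random.default_rng(0)
        axes = np.tile([0, 0, 1.0], (20, 1))
        pos = rng.uniform(0, 3, (20, 3))
        field = local_order(axes, pos, cutoff=10.0)
        assert len(find_defects(field).indices) == 0
        assert len(find_defects(field, threshold=0.0).indices) == 0

    def test_single_rotated_domain_flagged(self):
        rng = np.random.default_rng(1)
        n = 25
        axes = np.tile([0, 0, 1.0], (n, 1))
        axes[7] = [1.0, 0, 0]
        pos = np.zeros((n, 3))
        pos[:, 2] = np.arange(n) * 1.0
        field = local_order(axes, pos, cutoff=1.5)
        defects = find_defects(field, threshold=0.8)
        assert 7 in defects.indices
        assert set(defects.indices) <= {6, 7, 8}


class TestInsertionDepth:
    def test_standoff_placement_reports_negative_depth(self, topology):
        from enthcg.lattice import scatter_vesicle
        from enthcg.order import insertion_depth_profile
        from enthcg.sim import build_vesicle
        ves = build_vesicle(16.0, seed=2)
        scatter_vesicle(ves, topology, 10, standoff=0.5, seed=3)
        depths, mean = insertion_depth_profile(None, ves)
        # H0 sites 0.5 nm above the shell: depth is signed negative
        assert mean == pytest.approx(-0.5, abs=0.1)

    def test_sites_on_shell_have_zero_depth(self, topology):
        from enthcg.lattice import scatter_vesicle
        from enthcg.order import insertion_depth_profile
        from enthcg.sim import build_vesicle
        ves = build_vesicle(16.0, seed=2)
        scatter_vesicle(ves, topology, 10, standoff=0.0, seed=3)
        _, mean = insertion_depth_profile(None, ves)
        assert mean == pytest.approx(0.0, abs=0.1)


class TestShellFit:
    def test_cylinder_radius_recovered(self):
        rng = np.random.default_rng(2)
        ang = rng.uniform(0, 2 * np.pi, 500)
        z = rng.uniform(-5, 5, 500)
        pts = np.column_stack([8.0 * np.cos(ang), 8.0 * np.sin(ang), z])
        assert fit_shell(pts, "cylinder") == pytest.approx(8.0, abs=0.01)

    def test_planar_height(self):
        pts = np.column_stack([np.random.default_rng(0).uniform(0, 5, (50, 2)),
                               np.full(50, 2.4)[:, None]])
        assert fit_shell(pts, "planar") == pytest.approx(2.4)
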