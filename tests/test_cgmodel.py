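"""Coarse-graining: EDCG partitioning, mapping, heteroENM, PMF inversion."""

import numpy as np
import pytest

from enthcg.cgmodel import (ENTHTopology, SpringNetwork, build_enth16,
                            default_spring_network, edcg_partition,
                            heteroenm_fit, map_to_sites,
                            model_distance_variances, pmf_from_rdf)
from enthcg.constants import kt
from enthcg.synthetic import chain_spec, gen_enm_trajectory


class TestEDCG:
    def test_finest_partition_zero_residual(self, hinged_block_frames):
        n = hinged_block_frames.shape[1]
        part = edcg_partition(hinged_block_frames, n)
        assert part.n_sites == n
        assert part.boundaries == list(range(1, n + 1))
        assert abs(part.residual) < 1e-10

    def test_single_site_residual_is_total_essential_variance(
            self, hinged_block_frames):
        from enthcg.cgmodel import essential_projection
        part = edcg_partition(hinged_block_frames, 1)
        ess, _ = essential_projection(hinged_block_frames)
        mean = ess.mean(axis=1, keepdims=True)
        total = ((ess - mean) ** 2).sum(axis=(1, 2)).mean()
        assert part.residual == pytest.approx(total, rel=1e-9)

    def test_hinge_boundary_matches_exhaustive_search(
            self, hinged_block_frames):
        from enthcg.cgmodel import _segment_costs, essential_projection
        part = edcg_partition(hinged_block_frames, 2)
        ess, _ = essential_projection(hinged_block_frames)
        cost = _segment_costs(ess)
        n = hinged_block_frames.shape[1]
        totals = [cost[0, b] + cost[b, n] for b in range(1, n)]
        best = int(np.argmin(totals)) + 1
        assert part.boundaries == [1, best + 1]
        # the hinge bead itself may fall on either side of the cut
        assert best in (10, 11)

    def test_residual_nonincreasing_in_n_sites(self, hinged_block_frames):
        residuals = [edcg_partition(hinged_block_frames, k).residual
                     for k in (1, 2, 4, 8, 20)]
        assert all(b <= a + 1e-12 for a, b in zip(residuals, residuals[1:]))

    def test_too_many_sites_rejected(self, hinged_block_frames):
        with pytest.raises(ValueError, match="n_sites"):
            edcg_partition(hinged_block_frames, 21)

    def test_degenerate_trajectory_rejected(self):
        frames = np.zeros((2, 5, 3))
        with pytest.raises(ValueError):
            edcg_partition(frames, 2)


class TestMapping:
    def test_singleton_identity(self, hinged_block_frames):
        n = hinged_block_frames.shape[1]
        part = edcg_partition(hinged_block_frames, n)
        mapped = map_to_sites(hinged_block_frames, part)
        np.testing.assert_allclose(mapped, hinged_block_frames)

    def test_two_bead_midpoint(self):
        from enthcg.cgmodel import SitePartition
        frames = np.array([[[0.0, 0, 0], [2.0, 0, 0]]])
        part = SitePartition(boundaries=[1], n_sites=1, residual=0.0)
        np.testing.assert_allclose(map_to_sites(frames, part),
                                   [[[1.0, 0, 0]]])

    def test_mapped_variance_bounded_by_residue_variance(
            self, hinged_block_frames):
        part = edcg_partition(hinged_block_frames, 2)
        mapped = map_to_sites(hinged_block_frames, part)
        segs = part.segments(hinged_block_frames.shape[1])
        for k, (a, b) in enumerate(segs):
            vm = mapped[:, k].var(axis=0).sum()
            va = hinged_block_frames[:, a:b].var(axis=0).sum(axis=1).mean()
            assert vm <= va + 1e-12


class TestHeteroENM:
    def _grid(self):
        pts = np.array([[i * 0.5, j * 0.5, 0.3 * ((i + j) % 2)]
                        for i in range(3) for j in range(3)])
        return pts

    def test_homogeneous_recovery_within_5pct(self):
        pts = self._grid()
        springs = [(i, j, 10.0, float(np.linalg.norm(pts[j] - pts[i])))
                   for i in range(9) for j in range(i + 1, 9)
                   if np.linalg.norm(pts[j] - pts[i]) <= 0.9]
        targets = model_distance_variances(pts, springs, 300.0)
        net = heteroenm_fit(coords=pts, target_variances=targets,
                            cutoff=0.9, tolerance=0.01)
        ks = np.array([s[2] for s in net.springs])
        assert net.converged
        assert np.all(np.abs(ks / 10.0 - 1.0) < 0.05)

    def test_two_block_stiffness_ratio_within_10pct(self):
        pts = self._grid()
        springs = []
        for i in range(9):
            for j in range(i + 1, 9):
                r0 = float(np.linalg.norm(pts[j] - pts[i]))
                if r0 <= 0.9:
                    k = 5.0 if (i < 5 and j < 5) else 50.0
                    springs.append((i, j, k, r0))
        targets = model_distance_variances(pts, springs, 300.0)
        net = heteroenm_fit(coords=pts, target_variances=targets,
                            cutoff=0.9, tolerance=0.005, max_iter=500)
        soft = [s[2] for s in net.springs if s[0] < 5 and s[1] < 5]
        stiff = [s[2] for s in net.springs if not (s[0] < 5 and s[1] < 5)]
        ratio = np.mean(stiff) / np.mean(soft)
        assert abs(ratio / 10.0 - 1.0) < 0.10

    def test_mismatch_decreases_monotonically(self):
        pts = self._grid()
        springs = [(i, j, 20.0, float(np.linalg.norm(pts[j] - pts[i])))
                   for i in range(9) for j in range(i + 1, 9)
                   if np.linalg.norm(pts[j] - pts[i]) <= 0.9]
        targets = model_distance_variances(pts, springs, 300.0)
        net = heteroenm_fit(coords=pts, target_variances=targets,
                            cutoff=0.9, tolerance=1e-4, max_iter=100)
        h = net.mismatch_history
        assert all(b <= a + 1e-12 for a, b in zip(h, h[1:]))

    def _n_pairs(self, pts, cutoff=0.9):
        return sum(1 for i in range(len(pts)) for j in range(i + 1, len(pts))
                   if np.linalg.norm(pts[j] - pts[i]) <= cutoff)

    def test_infinite_tolerance_returns_initial_guess(self):
        pts = self._grid()
        n = self._n_pairs(pts)
        net = heteroenm_fit(coords=pts,
                            target_variances=np.full(n, 0.01),
                            cutoff=0.9, tolerance=np.inf, k_init=7.0)
        assert net.n_iterations == 0
        assert all(s[2] == 7.0 for s in net.springs)

    def test_trajectory_route_recovers_stiffness(self):
        spec = chain_spec(5, spacing=0.5, stiffness=50.0)
        frames = gen_enm_trajectory(spec, 30_000, seed=3)
        net = heteroenm_fit(frames, cutoff=0.6, tolerance=0.02)
        ks = np.array([s[2] for s in net.springs])
        assert np.all(np.abs(ks / 50.0 - 1.0) < 0.15)

    def test_nonpositive_target_variance_rejected(self):
        pts = self._grid()
        n = self._n_pairs(pts)
        with pytest.raises(ValueError, match="non-positive"):
            heteroenm_fit(coords=pts, target_variances=np.zeros(n),
                          cutoff=0.9)


class TestPMF:
    def test_uniform_g_gives_zero_pmf(self):
        r = np.linspace(0.2, 2.0, 30)
        _, pmf = pmf_from_rdf(r, np.ones_like(r))
        np.testing.assert_allclose(pmf, 0.0, atol=1e-12)

    def test_boltzmann_inversion_identity(self):
        r = np.linspace(0.3, 2.0, 60)
        u = 1.2 * np.exp(-((r - 0.8) / 0.2) ** 2) \
            - 0.9 * np.exp(-((r - 1.2) / 0.3) ** 2)
        g = np.exp(-u / kt(300.0))
        _, pmf = pmf_from_rdf(r, g, 300.0)
        np.testing.assert_allclose(pmf, u - u[-1], atol=1e-10)

    def test_r114_well_depth_magnitude(self):
        # g built so the PMF well depth is the R114 parameter, 1.2 kcal/mol
        r = np.linspace(0.3, 2.0, 69)   # grid hits the well minimum at 0.6
        u = -1.2 * np.exp(-((r - 0.6) / 0.15) ** 2)
        g = np.exp(-u / kt(300.0))
        _, pmf = pmf_from_rdf(r, g, 300.0)
        assert np.nanmin(pmf) == pytest.approx(-1.2, abs=1e-6)

    def test_zero_bins_masked_and_all_zero_rejected(self):
        r = np.linspace(0.2, 1.0, 10)
        g = np.ones_like(r)
        g[:3] = 0.0
        _, pmf = pmf_from_rdf(r, g)
        assert np.isnan(pmf[:3]).all() and np.isfinite(pmf[3:]).all()
        with pytest.raises(ValueError):
            pmf_from_rdf(r, np.zeros_like(r))


class TestENTH16:
    def test_site_count_enforced(self):
        with pytest.raises(ValueError, match="16"):
            build_enth16(reference_coords=np.zeros((15, 3)))

    def test_roles(self, topology):
        assert topology.role_of(1) == "H0_A"
        assert topology.role_of(2) == "H0_B"
        assert topology.role_of(10) == "R114_loop"
        assert topology.role_of(5) == "hydrophobic_patch"
        roles = [topology.role_of(s) for s in range(1, 17)]
        assert roles.count("PIP2_pocket") == 1

    def test_out_of_range_spring_rejected(self, topology):
        bad = SpringNetwork(springs=[(1, 17, 10.0, 1.0)], cutoff=1.3)
        with pytest.raises(ValueError, match="outside"):
            ENTHTopology(site_coords=topology.site_coords,
                         roles=topology.roles, springs=bad,
                         label_anchors=topology.label_anchors)

    def test_spring_network_connected(self, topology):
        # constructor validates connectivity; spot-check the default net
        net = default_spring_network()
        sites = {s for spr in net.springs for s in spr[:2]}
        assert sites == set(range(1, 17))

    def test_json_round_trip(self, topology):
        text = topology.to_json()
        back = ENTHTopology.from_json(text)
        np.testing.assert_allclose(back.site_coords, topology.site_coords)
        assert back.roles == topology.roles
        assert len(back.springs.springs) == len(topology.springs.springs)
        for res, (site, local) in topology.label_anchors.items():
            s2, l2 = back.label_anchors[res]
            assert s2 == site
            np.testing.assert_allclose(l2, local)
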