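"""EPR-restrained construction: dimer, tetramer, coats, scattering."""

import numpy as np
import pytest

from enthcg.geometry import anchor_distance, h0_axis_of_sites
from enthcg.lattice import (CoatSpec, RestraintSet, build_h0_dimer,
                            build_tetramer, coat_tube,
                            dimer_scatter_vesicle, scatter_vesicle)
from enthcg.order import domain_axes_positions, local_order
from enthcg.sim import build_tube, build_vesicle


@pytest.fixture(scope="module")
def dimer(topology):
    return build_h0_dimer(topology)


@pytest.fixture(scope="module")
def tetramer(topology, dimer):
    return build_tetramer(dimer, topology)


class TestDimer:
    def test_h0_axes_antiparallel(self, topology, dimer):
        a = h0_axis_of_sites(dimer[0].apply(topology.site_coords))
        b = h0_axis_of_sites(dimer[1].apply(topology.site_coords))
        assert np.dot(a, b) == pytest.approx(-1.0, abs=1e-6)

    def test_restraint_centers_reproduced(self, topology, dimer):
        a = dimer[0].apply(topology.site_coords)
        b = dimer[1].apply(topology.site_coords)
        expected = {6: 13.0, 10: 13.0, 5: 9.0, 4: 21.0}
        for res, center in expected.items():
            assert anchor_distance(topology, a, b, res) == pytest.approx(
                center, abs=1.0)

    def test_residue_5_is_shortest(self, topology, dimer):
        a = dimer[0].apply(topology.site_coords)
        b = dimer[1].apply(topology.site_coords)
        dists = {res: anchor_distance(topology, a, b, res)
                 for res in (4, 5, 6, 10)}
        assert min(dists, key=dists.get) == 5

    def test_infeasible_restraints_error_with_residuals(self, topology):
        bad = RestraintSet(entries={
            6: (13.0, 2.0, "intra_dimer"),
            10: (13.0, 2.0, "intra_dimer"),
            5: (40.0, 2.0, "intra_dimer"),   # geometrically impossible
            4: (2.0, 2.0, "intra_dimer"),
        })
        with pytest.raises(ValueError, match="residuals"):
            build_h0_dimer(topology, bad)

    def test_missing_required_restraint_rejected(self, topology):
        with pytest.raises(ValueError, match="residue 10"):
            build_h0_dimer(topology, RestraintSet(
                entries={6: (13.0, 2.0, "intra_dimer")}))


class TestTetramer:
    def test_cross_dimer_restraints(self, topology, tetramer):
        a1 = tetramer[0].apply(topology.site_coords)
        b2 = tetramer[3].apply(topology.site_coords)
        assert anchor_distance(topology, a1, b2, 13) == pytest.approx(
            15.0, abs=1.5)
        assert anchor_distance(topology, a1, b2, 14) == pytest.approx(
            10.0, abs=1.5)

    def test_patch_contact(self, topology, tetramer):
        a1 = tetramer[0].apply(topology.site_coords)
        b2 = tetramer[3].apply(topology.site_coords)
        sep = np.linalg.norm(b2[4] - a1[4])
        assert sep <= 1.2 * 0.535  # within LJ contact of the patch pair

    def test_second_dimer_is_pure_translation(self, tetramer):
        np.testing.assert_allclose(tetramer[0].rotation,
                                   tetramer[2].rotation, atol=1e-12)
        np.testing.assert_allclose(tetramer[1].rotation,
                                   tetramer[3].rotation, atol=1e-12)
        t1 = tetramer[2].translation - tetramer[0].translation
        t2 = tetramer[3].translation - tetramer[1].translation
        np.testing.assert_allclose(t1, t2, atol=1e-12)


class TestCoat:
    @pytest.fixture(scope="class")
    def coated(self, topology):
        tube = build_tube(16.0, 8 * 3.024, periodic=True, seed=1)
        return coat_tube(tube, topology,
                         spec=CoatSpec(dimers_per_turn=3, n_rows=8))

    def test_domain_and_site_counts(self, coated):
        assert coated.geometry["n_domains"] == 48
        assert coated.geometry["n_protein_sites"] == 48 * 16
        # at the full experimental scale: 192 domains -> 3072 sites
        assert 192 * 16 == 3072

    def test_initial_global_order_near_unity(self, coated):
        axes, pos = domain_axes_positions(coated)
        field = local_order(axes, pos, cutoff=5.0)
        assert field.global_mean >= 0.98

    def test_h0_axes_along_tube_axis(self, coated):
        axes, _ = domain_axes_positions(coated)
        cosang = np.abs(axes @ np.array([0.0, 0.0, 1.0]))
        assert np.all(cosang > np.cos(np.radians(5.0)))

    def test_no_lipid_protein_overlaps(self, coated):
        coated.check_overlaps(factor=0.5)

    def test_coat_rotation_equivariance(self, topology):
        from scipy.spatial.transform import Rotation
        spec = CoatSpec(dimers_per_turn=3, n_rows=4)
        rot = Rotation.from_euler("xyz", [0.3, -0.2, 0.9]).as_matrix()
        t1 = build_tube(16.0, 4 * 3.024, periodic=True, seed=2)
        coat_tube(t1, topology, spec=spec)
        t1.rotate(rot)
        t2 = build_tube(16.0, 4 * 3.024, periodic=True, seed=2)
        t2.rotate(rot)
        coat_tube(t2, topology, spec=spec)
        for c1, c2 in zip(t1.protein_coords, t2.protein_coords):
            np.testing.assert_allclose(c1, c2, atol=1e-9)


class TestVesicleScatter:
    @pytest.fixture(scope="class")
    def vesicle(self):
        return build_vesicle(20.0, seed=3)

    def test_seeded_placement_reproducible(self, topology):
        a = scatter_vesicle(build_vesicle(20.0, seed=3), topology, 20,
                            seed=9)
        b = scatter_vesicle(build_vesicle(20.0, seed=3), topology, 20,
                            seed=9)
        for c1, c2 in zip(a.protein_coords, b.protein_coords):
            np.testing.assert_array_equal(c1, c2)

    def test_standoff_above_outer_shell(self, topology, vesicle):
        import copy
        v = copy.deepcopy(vesicle)
        scatter_vesicle(v, topology, 15, standoff=0.5, seed=4)
        shell = v.outer_head_shell()
        for coords in v.protein_coords:
            h0_radius = np.linalg.norm(coords[:2], axis=1)
            # H0 sites lie in the tangent plane touching the standoff
            # shell, so their radius exceeds it only by the sagitta
            assert np.all(h0_radius - (shell + 0.5) > -1e-9)
            assert np.all(h0_radius - (shell + 0.5) < 0.05)

    def test_retry_cap_error_when_overcrowded(self, topology, vesicle):
        import copy
        v = copy.deepcopy(vesicle)
        with pytest.raises(RuntimeError, match="lower n_domains"):
            scatter_vesicle(v, topology, 5000, seed=5, max_retries=2000)

    def test_dimer_scatter_preserves_restraints(self, topology):
        v = build_vesicle(24.0, seed=6)
        dimer_scatter_vesicle(v, topology, 8, seed=7)
        assert v.n_proteins == 16
        for k in range(0, 16, 2):
            a, b = v.protein_coords[k], v.protein_coords[k + 1]
            assert anchor_distance(topology, a, b, 10) == pytest.approx(
                13.0, abs=1.0)

    def test_paper_scale_compatibility(self, topology):
        # 441 monomers on the 50-nm vesicle: feasible at default spacing
        v = build_vesicle(50.0, seed=8)
        scatter_vesicle(v, topology, 441, seed=8)
        assert v.n_proteins == 441
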