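import dataclasses
from itertools import product

import numpy as np
import pytest

import halbachmri as hm
from halbachmri import magnetdesign as md


def central_field(elements):
    grid = hm.PointGrid(points=[[0.0, 0.0, 0.0]])
    return hm.dipole_field(elements, grid).B[0]


class TestHalbachConstruction:
    def test_single_ring_count_and_field_direction(self, single_ring_elements):
        els = single_ring_elements
        assert len(els) == 32
        B = central_field(els)
        assert B[2] > 0
        assert abs(B[0]) < 1e-4 * np.linalg.norm(B)
        assert abs(B[1]) < 1e-4 * np.linalg.norm(B)

    def test_flipping_all_moments_negates_field(self, single_ring_elements):
        flipped = [
            dataclasses.replace(e, moment_dir=-e.moment_dir)
            for e in single_ring_elements
        ]
        np.testing.assert_allclose(
            central_field(flipped), -central_field(single_ring_elements), rtol=1e-12
        )

    def test_ring_rotation_symmetry(self):
        """Rotating the ring pattern by the inter-magnet angle leaves the
        central field unchanged (discrete k = 1 symmetry)."""
        kw = dict(axial_position=0.0, layer_radii=(0.18, 0.193),
                  magnets_per_layer=(16, 16))
        ring0 = hm.RingSpec(**kw)
        ring1 = hm.RingSpec(**kw, phi0=2 * np.pi / 16)
        B0 = central_field(md._ring_elements(ring0))
        B1 = central_field(md._ring_elements(ring1))
        assert np.linalg.norm(B1 - B0) < 1e-6 * np.linalg.norm(B0)

    def test_element_count_full_design(self):
        design = hm.HalbachMagnetDesign.reference(n_rings=5)
        expect = sum(sum(r.magnets_per_layer) for r in design.rings)
        assert len(hm.build_halbach_elements(design)) == expect

    def test_overlap_rejected(self):
        with pytest.raises(md.GeometryError, match="overlap"):
            hm.RingSpec(
                axial_position=0.0,
                layer_radii=(0.14, 0.153),
                magnets_per_layer=(80, 80),
            )

    def test_mirror_symmetric_design_gives_symmetric_field(self):
        design = hm.HalbachMagnetDesign.reference(n_rings=5)
        els = hm.build_halbach_elements(design)
        pts = np.array([[0.08, 0.01, 0.02], [-0.08, 0.01, 0.02]])
        f = hm.dipole_field(els, hm.PointGrid(points=pts))
        assert abs(f.b0_component[0] - f.b0_component[1]) < 1e-9 * abs(
            f.b0_component[0]
        )

    def test_design_json_roundtrip(self, tmp_path):
        design = hm.HalbachMagnetDesign.reference(n_rings=5)
        design.to_json(tmp_path / "d.json")
        back = hm.HalbachMagnetDesign.from_json(tmp_path / "d.json")
        assert back.rings == design.rings


class TestShimGrid:
    def test_all_absent_empty(self):
        grid = hm.ShimGrid()
        assert hm.build_shim_elements(grid) == []

    def test_all_aligned_has_900_elements(self):
        grid = hm.ShimGrid(state=np.full(900, hm.ALIGNED))
        assert len(hm.build_shim_elements(grid)) == 900

    def test_flipped_field_is_exact_negation(self):
        state_a = np.zeros(900, dtype=np.int8)
        state_a[123] = hm.ALIGNED
        state_f = np.zeros(900, dtype=np.int8)
        state_f[123] = hm.FLIPPED
        grid_a = hm.ShimGrid(state=state_a)
        grid_f = hm.ShimGrid(state=state_f)
        pts = hm.PointGrid(points=np.random.default_rng(0).normal(0, 0.04, (10, 3)))
        fa = hm.dipole_field(hm.build_shim_elements(grid_a), pts)
        ff = hm.dipole_field(hm.build_shim_elements(grid_f), pts)
        np.testing.assert_allclose(ff.B, -fa.B, rtol=1e-12)

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError, match="ABSENT/ALIGNED/FLIPPED"):
            hm.ShimGrid(state=np.full(900, 7))

    def test_shim_superposition(self, dsv20):
        """Field of a random state = sum of its individual magnet fields."""
        rng = np.random.default_rng(4)
        grid = hm.ShimGrid(n_rings=3, positions_per_ring=8)
        pts = dsv20.sample_points
        for _ in range(3):
            state = rng.integers(0, 3, grid.n_positions).astype(np.int8)
            g = dataclasses.replace(grid, state=state)
            total = hm.dipole_field(hm.build_shim_elements(g), pts).B
            parts = np.zeros_like(total)
            for i in range(grid.n_positions):
                s1 = np.zeros(grid.n_positions, dtype=np.int8)
                s1[i] = state[i]
                els = hm.build_shim_elements(dataclasses.replace(grid, state=s1))
                if els:
                    parts += hm.dipole_field(els, pts).B
            np.testing.assert_allclose(total, parts, rtol=1e-10, atol=1e-18)

    def test_json_roundtrip(self, tmp_path):
        state = np.random.default_rng(1).integers(0, 3, 900).astype(np.int8)
        grid = hm.ShimGrid(state=state)
        grid.to_json(tmp_path / "g.json")
        back = hm.ShimGrid.from_json(tmp_path / "g.json")
        np.testing.assert_array_equal(back.state, grid.state)


class TestRingDiameterGA:
    def test_toy_problem_matches_exhaustive_search(self, dsv20):
        """3-ring magnet, 5 candidate radii per free ring: the GA with an
        exhaustive-scale budget finds the grid-search optimum."""
        tmpl = hm.HalbachMagnetDesign.reference(n_rings=3, length=0.2)
        cands = [np.linspace(0.185, 0.215, 5), np.linspace(0.185, 0.215, 5)]

        def ppm_of(radii_half):
            radii = [radii_half[0], radii_half[1], radii_half[0]]
            design = md._design_with_radii(tmpl, np.asarray(radii))
            f = hm.dipole_field(hm.build_halbach_elements(design), dsv20.sample_points)
            return hm.homogeneity_ppm(f, dsv20)

        best_exhaustive = min(
            ppm_of((a, b)) for a, b in product(cands[0], cands[1])
        )
        ga = hm.GAConfig(population_size=30, generations=20, seed=7)
        _, res = hm.optimize_ring_diameters(tmpl, ga, dsv20, candidates=cands)
        assert res.fitness == pytest.approx(best_exhaustive, rel=1e-9)

    def test_best_fitness_monotone(self, dsv20):
        tmpl = hm.HalbachMagnetDesign.reference(n_rings=5)
        ga = hm.GAConfig(population_size=12, generations=8, seed=3)
        _, res = hm.optimize_ring_diameters(tmpl, ga, dsv20)
        assert np.all(np.diff(res.history) <= 0)

    def test_seed_determinism(self, dsv20):
        tmpl = hm.HalbachMagnetDesign.reference(n_rings=5)
        ga = hm.GAConfig(population_size=10, generations=6, seed=11)
        d1, r1 = hm.optimize_ring_diameters(tmpl, ga, dsv20)
        d2, r2 = hm.optimize_ring_diameters(tmpl, ga, dsv20)
        assert d1.rings == d2.rings
        np.testing.assert_array_equal(r1.history, r2.history)

    def test_infeasible_bounds_rejected_before_ga(self, dsv20):
        tmpl = hm.HalbachMagnetDesign.reference(n_rings=3, length=0.2)
        ga = hm.GAConfig(population_size=4, generations=2, seed=0)
        with pytest.raises(md.GeometryError, match="bore"):
            hm.optimize_ring_diameters(tmpl, ga, dsv20, bounds=(0.10, 0.12))


class TestShimGA:
    @staticmethod
    def tiny_grid():
        return hm.ShimGrid(n_rings=1, positions_per_ring=6, radius=0.15, length=0.02)

    @staticmethod
    def perturbed_base_field(dsv, seed=5):
        rng = np.random.default_rng(seed)
        design = hm.HalbachMagnetDesign.reference(n_rings=7, length=0.3)
        els = [
            dataclasses.replace(e, remanence=e.remanence * (1 + rng.normal(0, 0.01)))
            for e in hm.build_halbach_elements(design)
        ]
        return hm.dipole_field(els, dsv.sample_points)

    def test_matches_exhaustive_on_729_states(self, dsv20):
        grid = self.tiny_grid()
        base = self.perturbed_base_field(dsv20)
        basis = md._shim_basis(grid, dsv20.sample_points.points, base.b0_axis)
        signs = np.array([0.0, 1.0, -1.0])

        def ppm_of(state):
            vals = base.b0_component + signs[np.asarray(state)] @ basis
            return (vals.max() - vals.min()) / vals.mean() * 1e6

        best_exhaustive = min(
            ppm_of(state) for state in product((0, 1, 2), repeat=6)
        )
        ga = hm.GAConfig(population_size=60, generations=60, seed=2)
        _, res = hm.optimize_shim(base, grid, ga, dsv20)
        assert res.fitness == pytest.approx(best_exhaustive, rel=1e-9)

    def test_uniform_base_field_keeps_all_absent_optimal(self, dsv20):
        B = np.zeros((len(dsv20.sample_points), 3))
        B[:, 2] = 0.05
        base = hm.FieldMap(grid=dsv20.sample_points, B=B)
        ga = hm.GAConfig(population_size=20, generations=10, seed=0)
        best, res = hm.optimize_shim(base, self.tiny_grid(), ga, dsv20)
        assert res.fitness <= 0.0 + 1e-12  # cannot beat a perfectly uniform field
        assert np.all(best.state == hm.ABSENT)

    def test_never_worse_than_all_absent(self, dsv20):
        base = self.perturbed_base_field(dsv20, seed=8)
        baseline = hm.homogeneity_ppm(base, dsv20)
        ga = hm.GAConfig(population_size=30, generations=15, seed=1)
        _, res = hm.optimize_shim(base, self.tiny_grid(), ga, dsv20)
        assert res.fitness <= baseline

    def test_strictly_reduces_perturbed_field_ppm(self, dsv20):
        """Full 15 x 60 grid on a jittered-magnet field: ppm strictly drops."""
        base = self.perturbed_base_field(dsv20)
        baseline = hm.homogeneity_ppm(base, dsv20)
        ga = hm.GAConfig(population_size=40, generations=40, seed=6)
        best, res = hm.optimize_shim(base, hm.ShimGrid(), ga, dsv20)
        assert res.fitness < baseline
        # and the returned state reproduces the reported fitness
        shim_els = hm.build_shim_elements(best)
        total = base + hm.dipole_field(shim_els, dsv20.sample_points)
        assert hm.homogeneity_ppm(total, dsv20) == pytest.approx(
            res.fitness, rel=1e-9
        )
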