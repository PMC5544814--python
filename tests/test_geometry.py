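"""Scenario geometry: region maps, crescent lesions, mirror symmetry, meshing."""

import numpy as np
import pytest
from dataclasses import replace

from subwave.geometry import (
    REGIONS,
    HeadModelConfig,
    ScenarioGeometry,
    ScenarioParams,
    build_head_scenario,
    crescent_region,
    ellipse_distance,
)
from subwave.mesh import generate_mesh, structured_rectangle_mesh

CFG = HeadModelConfig()


def random_points(n, radius, seed=0):
    rng = np.random.default_rng(seed)
    r = radius * np.sqrt(rng.uniform(0, 1, n))
    t = rng.uniform(0, 2 * np.pi, n)
    return np.column_stack([r * np.cos(t), r * np.sin(t)])


class TestEllipseDistance:
    def test_matches_brute_force_minimum(self):
        rng = np.random.default_rng(1)
        a, b = 0.084, 0.067
        t_dense = np.linspace(0, 2 * np.pi, 400_000)
        boundary = np.column_stack([a * np.cos(t_dense), b * np.sin(t_dense)])
        pts = random_points(30, 0.08, seed=2)
        d = ellipse_distance(pts, a, b)
        for p, di in zip(pts, d):
            brute = np.hypot(*(boundary - p).T).min()
            assert di == pytest.approx(brute, abs=2e-7)


class TestScenarioGeometry:
    def test_head_scale_sweep_gives_seven_distinct_geometries(self):
        axes = set()
        for s in CFG.head_scales:
            g = build_head_scenario(ScenarioParams(head_scale=s), CFG)
            axes.add((round(g.a_outer, 6), round(g.b_outer, 6)))
        assert len(CFG.head_scales) == 7
        assert len(axes) == 7

    def test_null_lesion_has_no_bleeding_region(self):
        g = build_head_scenario(ScenarioParams(bleeding_thickness=0.0), CFG)
        pts = random_points(20_000, CFG.boundary_radius, seed=3)
        labels = g.classify(pts)
        assert not np.any(labels == REGIONS.index("bleeding"))

    def test_brain_area_unchanged_by_null_lesion(self):
        # Monte-Carlo area of the brain region equals the no-lesion case exactly
        # (identical classifier outputs point-by-point)
        g0 = build_head_scenario(ScenarioParams(), CFG)
        g1 = build_head_scenario(
            ScenarioParams(bleeding_thickness=0.0, position_index=5), CFG
        )
        pts = random_points(20_000, CFG.boundary_radius, seed=4)
        assert np.array_equal(g0.classify(pts), g1.classify(pts))

    def test_left_right_mirror_at_zero_rotation(self):
        pr = ScenarioParams(
            bleeding_thickness=0.01, position_index=3, rotation_deg=0.0, side="right"
        )
        pl = replace(pr, side="left")
        gr = build_head_scenario(pr, CFG)
        gl = build_head_scenario(pl, CFG)
        pts = random_points(1000, CFG.boundary_radius, seed=5)
        mirrored = pts.copy()
        mirrored[:, 0] = -mirrored[:, 0]
        assert np.array_equal(gl.classify(mirrored), gr.classify(pts))

    def test_mirror_with_rotation_negates_angle(self):
        pr = ScenarioParams(
            bleeding_thickness=0.02, position_index=2, rotation_deg=4.5, side="right"
        )
        gr = build_head_scenario(pr, CFG)
        gl = gr.mirrored()
        assert gl.params.side == "left"
        assert gl.params.rotation_deg == -4.5
        pts = random_points(1000, CFG.boundary_radius, seed=6)
        mirrored = pts.copy()
        mirrored[:, 0] = -mirrored[:, 0]
        assert np.array_equal(gl.classify(mirrored), gr.classify(pts))

    def test_region_partition_unique_and_total(self):
        g = build_head_scenario(
            ScenarioParams(bleeding_thickness=0.02, position_index=1, rotation_deg=3.0),
            CFG,
        )
        pts = random_points(10_000, CFG.boundary_radius, seed=7)
        labels = g.classify(pts)
        assert labels.min() >= 0 and labels.max() < len(REGIONS)
        # every tissue plus helmet structure is realized somewhere
        present = {REGIONS[i] for i in np.unique(labels)}
        for must in ("skull", "csf", "brain", "bleeding", "water_bag", "port", "air"):
            assert must in present

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ScenarioParams(bleeding_thickness=0.003).validate(CFG)  # not a class value
        with pytest.raises(ValueError):
            ScenarioParams(bleeding_thickness=0.01, position_index=11).validate(CFG)
        with pytest.raises(ValueError):
            ScenarioParams(csf_thickness=0.009).validate(CFG)
        with pytest.raises(ValueError):
            ScenarioParams(rotation_deg=9.0).validate(CFG)
        with pytest.raises(ValueError):
            ScenarioParams(side="up").validate(CFG)


class TestCrescent:
    def grid_inside_brain(self, g, n=400):
        xs = np.linspace(-g.a_inner, g.a_inner, n)
        ys = np.linspace(-g.b_inner, g.b_inner, n)
        X, Y = np.meshgrid(xs, ys)
        return np.column_stack([X.ravel(), Y.ravel()])

    def test_adjacent_positions_disjoint_at_half_cm(self):
        g = build_head_scenario(ScenarioParams(), CFG)
        r1 = crescent_region(0.005, 1, "right", g)
        r2 = crescent_region(0.005, 2, "right", g)
        pts = self.grid_inside_brain(g)
        assert not np.any(r1(pts) & r2(pts))

    def test_adjacent_positions_overlap_at_one_cm(self):
        g = build_head_scenario(ScenarioParams(), CFG)
        r1 = crescent_region(0.01, 1, "right", g)
        r2 = crescent_region(0.01, 2, "right", g)
        pts = self.grid_inside_brain(g)
        assert np.any(r1(pts) & r2(pts))

    @pytest.mark.parametrize("thickness", [0.01, 0.02, 0.025])
    def test_max_depth_matches_thickness(self, thickness):
        g = build_head_scenario(
            ScenarioParams(bleeding_thickness=thickness, position_index=1), CFG
        )
        pts = self.grid_inside_brain(g, n=900)
        member = crescent_region(thickness, 1, "right", g)
        inside = pts[member(pts)]
        depth = ellipse_distance(inside, g.a_inner, g.b_inner).max()
        assert depth == pytest.approx(thickness, rel=0.02)

    def test_bleeding_touches_inner_skull(self):
        g = build_head_scenario(
            ScenarioParams(bleeding_thickness=0.02, position_index=1), CFG
        )
        pts = self.grid_inside_brain(g, n=900)
        inside = pts[g.classify(pts) == REGIONS.index("bleeding")]
        # some lesion points lie within a hair of the inner skull boundary
        assert ellipse_distance(inside, g.a_inner, g.b_inner).min() < 5e-4

    def test_invalid_crescent_arguments(self):
        g = build_head_scenario(ScenarioParams(), CFG)
        with pytest.raises(ValueError):
            crescent_region(0.0, 1, "right", g)
        with pytest.raises(ValueError):
            crescent_region(0.01, 0, "right", g)


class TestMesh:
    def test_centroid_labels_match_classifier(self):
        g = build_head_scenario(
            ScenarioParams(bleeding_thickness=0.02, position_index=1), CFG
        )
        m = generate_mesh(g, 1.2e9, 6)
        np.testing.assert_array_equal(m.labels, g.classify(m.centroids()))

    def test_no_bleeding_mesh_has_no_bleeding_triangles(self):
        m = generate_mesh(build_head_scenario(ScenarioParams(), CFG), 1.2e9, 6)
        assert not np.any(m.label_name(m.labels) == "bleeding")

    def test_total_area_matches_disk(self):
        m = generate_mesh(build_head_scenario(ScenarioParams(), CFG), 1.2e9, 6)
        disk = np.pi * CFG.boundary_radius**2
        assert m.triangle_areas().sum() == pytest.approx(disk, rel=5e-3)

    def test_refinement_scaling(self):
        g = build_head_scenario(ScenarioParams(), CFG)
        coarse = generate_mesh(g, 2.5e9, 6)
        fine = generate_mesh(g, 2.5e9, 12)  # halves the target element size
        ratio = fine.n_triangles / coarse.n_triangles
        assert 3.0 <= ratio <= 5.0

    def test_minimum_elements_per_wavelength_enforced(self):
        g = build_head_scenario(ScenarioParams(), CFG)
        with pytest.raises(ValueError):
            generate_mesh(g, 1e9, 4)

    def test_boundary_edges_cover_all_ports(self):
        m = generate_mesh(build_head_scenario(ScenarioParams(), CFG), 1.2e9, 6)
        for k in range(CFG.n_ports):
            assert f"port:{k}" in m.boundary_edges
            assert len(m.boundary_edges[f"port:{k}"]) >= 3
        assert "absorbing" in m.boundary_edges

    def test_gmsh_export(self, tmp_path):
        m = structured_rectangle_mesh(0.02, 0.01, 0.002)
        out = tmp_path / "guide.msh"
        m.export_gmsh(out)
        text = out.read_text()
        assert "$Nodes" in text and "$Elements" in text
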