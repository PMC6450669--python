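"""Morphometry against analytic phantoms."""

import math

import numpy as np
import pytest

from mesotrack.model import FilopodiumTrace, LabeledCellMask, ValidationError
from mesotrack.morphometry import (
    axis_ratio_2d,
    cell_surface_area,
    cell_volume,
    filopodia_lengths,
    filopodia_per_cell,
    filopodium_length,
    summarize_shapes,
)
from mesotrack.synthetic import generate_filopodia, rasterize_ellipsoid


def cube_mask(n, voxel=(1.0, 1.0, 1.0)):
    return LabeledCellMask(np.ones((n, n, n), bool), voxel, "cube")


class TestVolume:
    def test_unit_cube(self):
        assert cell_volume(cube_mask(10)) == 1000.0

    def test_anisotropic_voxels(self):
        m = LabeledCellMask(np.ones((4, 20, 20), bool), (3.0, 0.5, 0.5), "c")
        assert cell_volume(m) == pytest.approx(1200.0)

    def test_ellipsoid_within_2pct_of_analytic(self):
        m = rasterize_ellipsoid((10, 5, 5), voxel_size=(0.5, 0.5, 0.5))
        analytic = 4.0 / 3.0 * math.pi * 250.0
        assert cell_volume(m) == pytest.approx(analytic, rel=0.02)

    def test_translation_invariant_and_voxel_proportional(self):
        occ = np.zeros((6, 6, 6), bool)
        occ[1:4, 1:4, 1:4] = True
        base = cell_volume(LabeledCellMask(occ, (1, 1, 1), "c"))
        shifted = np.roll(occ, (1, 1, 1), axis=(0, 1, 2))
        assert cell_volume(LabeledCellMask(shifted, (1, 1, 1), "c")) == base
        assert cell_volume(LabeledCellMask(occ, (2, 1, 1), "c")) == 2 * base


class TestSurface:
    def test_sphere_within_3pct_of_analytic(self):
        m = rasterize_ellipsoid((10, 10, 10), voxel_size=(0.5, 0.5, 0.5))
        assert cell_surface_area(m) == pytest.approx(4 * math.pi * 100.0, rel=0.03)

    def test_cube_approaches_6L2_within_mesh_tolerance(self):
        # 20 µm cube at 0.5 µm voxels; smoothed-mesh convention documented
        # to shave corners by < 5%
        m = cube_mask(40, voxel=(0.5, 0.5, 0.5))
        assert cell_surface_area(m) == pytest.approx(6 * 400.0, rel=0.05)

    def test_single_voxel_face_convention(self):
        m = LabeledCellMask(np.ones((1, 1, 1), bool), (1, 1, 1), "v")
        assert cell_surface_area(m) == 6.0

    def test_translation_invariant(self):
        occ = np.zeros((12, 12, 12), bool)
        occ[2:7, 2:7, 2:7] = True
        a = cell_surface_area(LabeledCellMask(occ, (1, 1, 1), "c"))
        b = cell_surface_area(
            LabeledCellMask(np.roll(occ, 3, axis=2), (1, 1, 1), "c"))
        assert a == pytest.approx(b, rel=1e-9)


class TestAxisRatio:
    def test_disc_projection_is_isotropic(self):
        m = rasterize_ellipsoid((8, 8, 2), voxel_size=(0.5, 0.5, 0.5))
        assert axis_ratio_2d(m) == pytest.approx(1.0, rel=0.01)

    def test_rectangle_20x10_gives_exactly_2(self):
        m = LabeledCellMask(np.ones((1, 10, 20), bool), (1.0, 1.0, 1.0), "r")
        assert axis_ratio_2d(m) == pytest.approx(2.0, rel=1e-12)

    def test_ellipsoid_projection_within_2pct(self):
        m = rasterize_ellipsoid((10, 5, 5), voxel_size=(0.5, 0.5, 0.5))
        assert axis_ratio_2d(m) == pytest.approx(2.0, rel=0.02)

    def test_in_plane_rotation_invariant_within_2pct(self):
        theta = math.radians(37.0)
        R = np.array([[math.cos(theta), -math.sin(theta), 0],
                      [math.sin(theta), math.cos(theta), 0],
                      [0, 0, 1]])
        a = axis_ratio_2d(rasterize_ellipsoid((10, 5, 5), (0.5, 0.5, 0.5)))
        b = axis_ratio_2d(rasterize_ellipsoid((10, 5, 5), (0.5, 0.5, 0.5),
                                              rotation=R))
        assert b == pytest.approx(a, rel=0.02)

    def test_monotone_in_true_elongation(self):
        ratios = [
            axis_ratio_2d(rasterize_ellipsoid((5 * f, 5, 5), (0.5, 0.5, 0.5)))
            for f in (1.0, 1.5, 2.0, 3.0)
        ]
        assert all(b > a for a, b in zip(ratios, ratios[1:]))

    def test_collinear_projection_rejected(self):
        m = LabeledCellMask(np.ones((1, 1, 5), bool), (1, 1, 1), "line")
        with pytest.raises(ValidationError, match="degenerate|collinear|fewer"):
            axis_ratio_2d(m)


class TestFilopodia:
    def test_three_four_five(self):
        tr = FilopodiumTrace("c", 0.0, [[0, 0], [3, 4]])
        assert filopodium_length(tr) == 5.0

    def test_l_path(self):
        tr = FilopodiumTrace("c", 0.0, [[0, 0], [3, 0], [3, 4]])
        assert filopodium_length(tr) == 7.0

    def test_random_polyline_matches_segment_sum(self, rng):
        verts = rng.normal(size=(10, 2))
        expected = sum(
            math.dist(verts[i], verts[i + 1]) for i in range(9)
        )
        tr = FilopodiumTrace("c", 0.0, verts)
        assert filopodium_length(tr) == pytest.approx(expected, rel=1e-12)

    def test_length_additive_under_concatenation(self, rng):
        v1 = rng.normal(size=(5, 2))
        v2 = rng.normal(size=(4, 2)) + 10.0
        joined = np.vstack([v1, v2])
        total = filopodium_length(FilopodiumTrace("c", 0.0, joined))
        part1 = filopodium_length(FilopodiumTrace("c", 0.0, v1))
        bridge = math.dist(v1[-1], v2[0])
        part2 = filopodium_length(FilopodiumTrace("c", 0.0, v2))
        assert total == pytest.approx(part1 + bridge + part2, rel=1e-12)

    def test_counts_mean_over_timepoints(self):
        traces = []
        for t, k in zip((0.0, 20.0, 40.0), (3, 4, 5)):
            for f in range(k):
                traces.append(FilopodiumTrace("c1", t, [[0, 0], [1, 1]],
                                              filopodium_id=f"f{f}"))
        out = filopodia_per_cell(traces)
        assert out.mean_count_per_timepoint.iloc[0] == pytest.approx(4.0)
        assert out.n_timepoints.iloc[0] == 3

    def test_zero_traces_at_annotated_timepoint(self):
        out = filopodia_per_cell([], annotated_timepoints={"c1": [0.0]})
        assert out.mean_count_per_timepoint.iloc[0] == 0.0

    def test_by_target_split(self):
        traces = [
            FilopodiumTrace("c1", 0.0, [[0, 0], [1, 0]], target="epiblast",
                            filopodium_id="f0"),
            FilopodiumTrace("c1", 0.0, [[0, 0], [0, 1]],
                            target="visceral_endoderm", filopodium_id="f1"),
            FilopodiumTrace("c1", 0.0, [[0, 0], [0, 2]],
                            target="visceral_endoderm", filopodium_id="f2"),
        ]
        out = filopodia_per_cell(traces, by_target=True).set_index("target")
        assert out.loc["epiblast", "mean_count_per_timepoint"] == 1.0
        assert out.loc["visceral_endoderm", "mean_count_per_timepoint"] == 2.0

    def test_poisson_counts_recovered_within_3_se(self):
        lam = 6.86
        traces, truth = generate_filopodia(500, count_mean=lam, length_mean=8.0,
                                           seed=5)
        out = filopodia_per_cell(
            traces, annotated_timepoints={c: [0.0] for c in truth.cell_id})
        mean = out.mean_count_per_timepoint.mean()
        se = math.sqrt(lam / 500)
        assert abs(mean - lam) < 3 * se


class TestShapeSummaries:
    def test_one_row_per_mask_with_oracle_values(self):
        masks = [
            rasterize_ellipsoid((6, 4, 4), (1, 1, 1), cell_id="2"),
            cube_mask(8),
        ]
        out = summarize_shapes(masks).set_index("cell_id")
        assert len(out) == 2
        assert out.loc["cube", "volume_um3"] == cell_volume(masks[1])
        assert out.loc["2", "surface_um2"] == pytest.approx(
            cell_surface_area(masks[0]))
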