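"""Cell extraction, PCA frames, median plane, tilt and gravity recovery."""

import numpy as np
import pytest

from combscan import cell_analysis as ca
from combscan import synthetic_comb as syn
from combscan import volume_io as vio

from conftest import comb_only_sdf


def rotation_matrix(axis, deg):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    a = np.radians(deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def make_cellset_from_points(pts_list, spacing=0.5):
    """Synthetic CellSet with explicit voxel index groups (one per cell)."""
    all_pts = np.vstack(pts_list)
    lo = all_pts.min(axis=0) - 2
    hi = all_pts.max(axis=0) + 3
    dims = tuple(((hi - lo)).astype(int) + 1)
    labels = np.zeros(dims, dtype=np.int32)
    for cid, pts in enumerate(pts_list, start=1):
        idx = (pts - lo).astype(int)
        labels[idx[:, 0], idx[:, 1], idx[:, 2]] = cid
    cs = ca.CellSet(
        labels=labels,
        spacing_mm=(spacing,) * 3,
        origin_mm=tuple(lo * spacing),
        n_cells=len(pts_list),
    )
    ca._basic_metrics(cs)
    return cs


class TestExtractCells:
    def test_planted_cell_count_recovered(self, small_phantom_cells, small_phantom):
        cells, _, gt = small_phantom_cells
        assert cells.n_cells == gt.cell_count

    def test_solid_slab_has_no_negative_space(self):
        mask = np.zeros((40, 40, 20), dtype=bool)
        mask[4:36, 4:36, 4:16] = True
        sdf = vio.signed_distance_from_mask(mask, (0.5,) * 3)
        with pytest.raises(ValueError, match="no negative space"):
            ca.extract_cells(sdf, closure_radius_mm=5.0)

    def test_breached_pair_severed_by_opening(self):
        """Two wells connected by a slit thinner than the opening ball are
        separated into two cells."""
        h = 0.5
        mask = np.ones((60, 36, 30), dtype=bool)  # solid block
        # two open-top wells 8x8 mm, 8 mm deep
        for x0 in (8, 36):
            mask[x0 : x0 + 16, 10:26, 14:30] = False
        # 1 mm wide breach between them
        mask[24:36, 17:19, 20:28] = False
        sdf = vio.signed_distance_from_mask(mask, (h,) * 3)
        cells = ca.extract_cells(sdf, closure_radius_mm=8.0)
        assert cells.n_cells == 2

    def test_sum_of_cell_volumes_bounded_by_negative_space(
        self, small_phantom_cells, small_phantom_sdf
    ):
        from combscan import morphology as mo

        cells, _, _ = small_phantom_cells
        h = small_phantom_sdf.spacing_mm[0]
        closed = mo.close_mask(small_phantom_sdf.solid_mask, 10.0, h)
        neg = closed & ~small_phantom_sdf.solid_mask
        assert cells.volumes_mm3.sum() <= neg.sum() * h**3 + 1e-9


class TestCellFrames:
    def test_box_principal_axis(self):
        i, j, k = np.indices((20, 6, 6))
        pts = np.argwhere(np.ones((20, 6, 6), dtype=bool))
        cs = make_cellset_from_points([pts])
        ca.cell_frames(cs)
        axis = cs.frames[0, 0]
        assert abs(axis @ np.array([1.0, 0, 0])) > 0.999
        # orthonormal frame
        np.testing.assert_allclose(cs.frames[0] @ cs.frames[0].T, np.eye(3), atol=1e-8)

    def test_rotated_box_axis_recovered_within_one_degree(self):
        R = rotation_matrix([1, 0, 0], 13.0)
        base = np.argwhere(np.ones((40, 10, 10), dtype=bool)).astype(float)
        base -= base.mean(axis=0)
        rot = base @ R.T
        cs = make_cellset_from_points([np.round(rot + 30).astype(int)])
        ca.cell_frames(cs)
        axis = cs.frames[0, 0]
        expected = R @ np.array([1.0, 0, 0])
        ang = np.degrees(np.arccos(np.clip(abs(axis @ expected), 0, 1)))
        assert ang < 1.0

    def test_spherical_cell_flagged_degenerate(self):
        i, j, k = np.indices((21, 21, 21))
        ball = np.argwhere((i - 10) ** 2 + (j - 10) ** 2 + (k - 10) ** 2 <= 81)
        cs = make_cellset_from_points([ball])
        ca.cell_frames(cs)
        assert cs.degenerate[0]


class TestMedianPlane:
    def test_symmetric_phantom_interface_recovered(self, small_phantom_cells):
        _, plane, gt = small_phantom_cells
        # distance of the fitted plane to the planted interface point
        d = abs(plane.signed_distance(gt.interface_point_mm[None])[0])
        assert d < 0.5
        ang = np.degrees(
            np.arccos(np.clip(abs(plane.normal @ gt.interface_normal), 0, 1))
        )
        assert ang < 3.0

    def test_rotation_equivariance(self):
        R = rotation_matrix([1, 1, 0], 30.0)
        spec = syn.CombPhantomSpec(
            rows=3, cols=3, spacing_mm=0.35, rotation=tuple(map(tuple, R)), rng_seed=4
        )
        vol, gt = syn.generate(spec)
        cells = ca.extract_cells(comb_only_sdf(vol, gt))
        ca.cell_frames(cells)
        plane = ca.median_plane(cells)
        ang = np.degrees(
            np.arccos(np.clip(abs(plane.normal @ gt.interface_normal), 0, 1))
        )
        assert ang < 3.0

    def test_single_sheet_plane_parallel_to_backing(self):
        spec = syn.CombPhantomSpec(rows=3, cols=3, sides=1, spacing_mm=0.35, rng_seed=5)
        vol, gt = syn.generate(spec)
        cells = ca.extract_cells(comb_only_sdf(vol, gt))
        ca.cell_frames(cells)
        plane = ca.median_plane(cells)
        ang = np.degrees(
            np.arccos(np.clip(abs(plane.normal @ gt.interface_normal), 0, 1))
        )
        assert ang < 5.0


class TestTiltAndGravity:
    def test_planted_tilt_and_gravity_recovered(self, small_phantom_cells):
        cells, plane, gt = small_phantom_cells
        tilt, gravity = ca.tilt_and_gravity(cells, plane)
        valid = ~cells.degenerate & ~cells.boundary_touch
        assert abs(np.mean(tilt[valid]) - 13.0) <= 2.0
        assert gravity @ gt.gravity > 0.97

    def test_zero_tilt_unresolvable(self):
        spec = syn.CombPhantomSpec(rows=3, cols=3, tilt_deg=0.0, spacing_mm=0.35, rng_seed=6)
        vol, gt = syn.generate(spec)
        cells = ca.extract_cells(comb_only_sdf(vol, gt))
        ca.cell_frames(cells)
        plane = ca.median_plane(cells)
        with pytest.raises(ValueError, match="unresolvable"):
            ca.tilt_and_gravity(cells, plane)

    def test_gravity_equivariant_under_rotation(self):
        R = rotation_matrix([0, 1, 1], 40.0)
        spec = syn.CombPhantomSpec(
            rows=3, cols=3, spacing_mm=0.35, rotation=tuple(map(tuple, R)), rng_seed=8
        )
        vol, gt = syn.generate(spec)
        cells = ca.extract_cells(comb_only_sdf(vol, gt))
        ca.cell_frames(cells)
        plane = ca.median_plane(cells)
        _, gravity = ca.tilt_and_gravity(cells, plane)
        assert gravity @ gt.gravity > 0.97  # gt.gravity is already rotated


class TestCellMetrics:
    def test_planted_depth_width_volume(self, small_phantom_cells):
        cells, plane, gt = small_phantom_cells
        table = ca.cell_metrics(cells, plane)
        h = cells.spacing_mm[0]
        assert abs(np.median(table["depth_mm"]) - gt.interior_depth_mm) <= 2 * h
        assert abs(np.median(table["width_mm"]) - gt.interior_width_mm) <= 2 * h
        # opening rounds hex corners: voxel volume below the analytic prism
        assert np.median(table["volume_mm3"]) <= gt.cell_volume_mm3 * 1.05

    def test_planted_prism_volume_formula(self, small_phantom):
        """Voxel-counted interior of a planted cell matches the hexagonal
        prism formula (3*sqrt(3)/2) e^2 d within 5%."""
        vol, gt = small_phantom
        h = vol.spacing_mm[0]
        # count open-cell voxels straight from the generator's label volume
        label = gt.extra["label_volume"]
        n_air_cells = gt.cell_count
        # air voxels inside the comb slab = cell interiors
        interior = (label == 0) & (gt.segment_labels > 0)
        per_cell = interior.sum() * h**3 / n_air_cells
        assert abs(per_cell - gt.cell_volume_mm3) / gt.cell_volume_mm3 < 0.05

    def test_width_error_halves_with_resolution(self):
        errs = []
        for h in (0.5, 0.25):
            spec = syn.CombPhantomSpec(rows=2, cols=3, spacing_mm=h, wall_thickness_mm=1.0, rng_seed=9)
            vol, gt = syn.generate(spec)
            cells = ca.extract_cells(comb_only_sdf(vol, gt))
            ca.cell_frames(cells)
            plane = ca.median_plane(cells)
            table = ca.cell_metrics(cells, plane)
            errs.append(abs(np.median(table["width_mm"]) - gt.interior_width_mm))
        assert errs[1] < errs[0]

    def test_cell_count_invariant_under_rotation(self, small_phantom):
        _, gt = small_phantom
        R = rotation_matrix([0, 0, 1], 25.0)
        spec = syn.CombPhantomSpec(
            rows=3, cols=4, spacing_mm=0.3, rotation=tuple(map(tuple, R)), rng_seed=11
        )
        vol2, gt2 = syn.generate(spec)
        cells2 = ca.extract_cells(comb_only_sdf(vol2, gt2))
        assert abs(cells2.n_cells - gt.cell_count) <= 1
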