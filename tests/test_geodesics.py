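"""Eikonal solver: analytic limits, Dijkstra oracles, build direction."""

import numpy as np
import pytest
from scipy import sparse
from scipy.sparse.csgraph import dijkstra

from combscan import geodesics as geo
from combscan import volume_io as vio
from combscan.synthetic_comb import analytic_shapes


def point_source(sdf, pos_mm):
    src = np.zeros(sdf.dims, dtype=bool)
    idx = tuple(
        np.round((np.asarray(pos_mm) - np.asarray(sdf.origin_mm)) / sdf.spacing_mm[0]).astype(int)
    )
    src[idx] = True
    return src, idx


def voxel_index(sdf, pos_mm):
    return tuple(
        np.round((np.asarray(pos_mm) - np.asarray(sdf.origin_mm)) / sdf.spacing_mm[0]).astype(int)
    )


def dijkstra_grid(mask, spacing, src_idx):
    """26-connected Dijkstra oracle on the voxel graph (unit speed)."""
    n = mask.size
    idx_map = -np.ones(mask.shape, dtype=int)
    coords = np.argwhere(mask)
    idx_map[tuple(coords.T)] = np.arange(len(coords))
    rows, cols, data = [], [], []
    offs = [
        (di, dj, dk)
        for di in (-1, 0, 1)
        for dj in (-1, 0, 1)
        for dk in (-1, 0, 1)
        if (di, dj, dk) != (0, 0, 0)
    ]
    for di, dj, dk in offs:
        shifted = np.roll(mask, (-di, -dj, -dk), axis=(0, 1, 2))
        for ax, d in zip((0, 1, 2), (di, dj, dk)):
            if d == 1:
                sl = [slice(None)] * 3
                sl[ax] = -1
                shifted[tuple(sl)] = False
            elif d == -1:
                sl = [slice(None)] * 3
                sl[ax] = 0
                shifted[tuple(sl)] = False
        both = mask & shifted
        a = idx_map[both]
        cc = np.argwhere(both) + np.array([di, dj, dk])
        b = idx_map[tuple(cc.T)]
        w = spacing * np.sqrt(di * di + dj * dj + dk * dk)
        rows.append(a)
        cols.append(b)
        data.append(np.full(len(a), w))
    g = sparse.csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(len(coords), len(coords)),
    )
    d = dijkstra(g, indices=idx_map[src_idx])
    out = np.full(mask.shape, np.inf)
    out[tuple(coords.T)] = d
    _ = n
    return out


@pytest.fixture(scope="module")
def slab_field():
    slab = analytic_shapes("slab", thickness=1.0, half_extent=20.0, spacing_mm=0.5)
    src, _ = point_source(slab, (-15.0, 0.0, 0.0))
    return slab, geo.solve_eikonal(slab, src, 1.0)


class TestEikonal:
    def test_slab_euclidean_limit(self, slab_field):
        slab, field = slab_field
        tgt = voxel_index(slab, (15.0, 0.0, 0.0))
        assert abs(field.u[tgt] - 30.0) / 30.0 < 0.05
        assert field.u[field.source_mask].max() == 0.0

    def test_inverse_speed_scaling_exact(self, slab_field):
        slab, field = slab_field
        src, _ = point_source(slab, (-15.0, 0.0, 0.0))
        half = geo.solve_eikonal(slab, src, 0.5)
        fin = np.isfinite(field.u)
        np.testing.assert_allclose(half.u[fin], 2.0 * field.u[fin], rtol=1e-12)

    def test_cylinder_shell_closed_form(self):
        cyl = analytic_shapes(
            "cylinder_shell", radius=10.0, thickness=1.0, length=50.0, spacing_mm=0.3
        )
        src, _ = point_source(cyl, (10.0, 0.0, -10.0))
        field = geo.solve_eikonal(cyl, src, 1.0)
        tgt = voxel_index(cyl, (0.0, 10.0, 10.0))
        # quarter turn (R*pi/2) plus 20 mm axial, unrolled
        expected = np.sqrt((5 * np.pi) ** 2 + 20.0**2)
        assert abs(field.u[tgt] - expected) / expected < 0.05

    def test_empty_source_raises(self, slab_field):
        slab, _ = slab_field
        with pytest.raises(ValueError, match="empty source"):
            geo.solve_eikonal(slab, np.zeros(slab.dims, dtype=bool), 1.0)

    def test_unreachable_voxels_counted(self):
        # two disjoint balls; source in one only
        db = analytic_shapes("dumbbell", ball_radius=4.0, separation=20.0, neck_radius=0.0)
        mask = db.solid_mask.copy()
        mid = mask.shape[0] // 2
        mask[mid - 2 : mid + 2] = False  # sever any residual neck
        sdf = vio.signed_distance_from_mask(mask, db.spacing_mm, db.origin_mm)
        src, _ = point_source(sdf, (-10.0, 0.0, 0.0))
        field = geo.solve_eikonal(sdf, src, 1.0)
        assert field.n_unreached > 0

    def test_metric_monotonicity(self, slab_field):
        slab, field = slab_field
        src, _ = point_source(slab, (-15.0, 0.0, 0.0))
        faster = geo.solve_eikonal(slab, src, 2.0)
        fin = np.isfinite(field.u)
        assert np.all(faster.u[fin] <= field.u[fin] + 1e-9)

    def test_first_order_convergence_on_slab(self):
        errs = []
        for h in (1.0, 0.5):
            slab = analytic_shapes("slab", thickness=2 * h, half_extent=20.0, spacing_mm=h)
            src, _ = point_source(slab, (-15.0, -15.0, 0.0))
            field = geo.solve_eikonal(slab, src, 1.0)
            tgt = voxel_index(slab, (15.0, 15.0, 0.0))
            errs.append(abs(field.u[tgt] - np.sqrt(2) * 30.0))
        assert errs[1] < 0.75 * errs[0]

    def test_triangle_inequality_against_dijkstra(self):
        rng = np.random.default_rng(7)
        slab = analytic_shapes("slab", thickness=1.0, half_extent=10.0, spacing_mm=0.5)
        mask = slab.solid_mask
        src, src_idx = point_source(slab, (-5.0, -5.0, 0.0))
        field = geo.solve_eikonal(slab, src, 1.0)
        coords = np.argwhere(mask & np.isfinite(field.u))
        bs = coords[rng.integers(0, len(coords), size=4)]
        for b in bs:
            d_b = dijkstra_grid(mask, 0.5, tuple(b))
            sel = coords[rng.integers(0, len(coords), size=250)]
            ua = field.u[tuple(sel.T)]
            ub = field.u[tuple(b)]
            dba = d_b[tuple(sel.T)]
            assert np.all(ua <= ub + dba + 0.5 * np.sqrt(3))


class TestGradient:
    def test_point_source_gives_radial_field(self):
        ball = analytic_shapes("ball", radius=10.0, spacing_mm=0.5)
        src, src_idx = point_source(ball, (0.0, 0.0, 0.0))
        field = geo.solve_eikonal(ball, src, 1.0)
        g = geo.gradient_field(field)
        coords = np.argwhere(np.isfinite(field.u))
        pos = np.asarray(ball.origin_mm) + coords * 0.5
        r = np.linalg.norm(pos, axis=1)
        sel = (r > 2.5) & (r < 8.0)
        radial = pos[sel] / r[sel, None]
        gv = g[tuple(coords[sel].T)]
        cosang = np.sum(radial * gv, axis=1)
        ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
        assert np.mean(ang) < 5.0

    def test_planar_source_gives_constant_direction(self):
        ball = analytic_shapes("ball", radius=10.0, spacing_mm=0.5)
        src = np.zeros(ball.dims, dtype=bool)
        plane_k = voxel_index(ball, (0, 0, -8.0))[2]
        src[:, :, plane_k] = True
        field = geo.solve_eikonal(ball, src, 1.0)
        g = geo.gradient_field(field)
        sel = np.isfinite(field.u) & ~field.source_mask
        k = np.argwhere(sel)
        pos = np.asarray(ball.origin_mm) + 0.5 * k
        # the source is the z = -8 disk (radius 6): the wave is planar only
        # within the cylinder above it, away from the curved ball boundary
        above = (k[:, 2] > plane_k + 4) & (np.linalg.norm(pos[:, :2], axis=1) < 4.0)
        gv = g[tuple(k[above].T)]
        assert np.mean(gv[:, 2]) > 0.97

    def test_gradient_matches_dijkstra_directions(self):
        slab = analytic_shapes("slab", thickness=1.0, half_extent=8.0, spacing_mm=0.5)
        src, src_idx = point_source(slab, (-4.0, -4.0, 0.0))
        field = geo.solve_eikonal(slab, src, 1.0)
        d = dijkstra_grid(slab.solid_mask, 0.5, src_idx)
        fd = geo.GeodesicField(
            u=d,
            spacing_mm=field.spacing_mm,
            origin_mm=field.origin_mm,
            source_mask=field.source_mask,
            metric_s=field.metric_s,
            domain_mask=field.domain_mask,
        )
        g1 = geo.gradient_field(field)
        g2 = geo.gradient_field(fd)
        sel = np.isfinite(field.u) & slab.solid_mask & ~field.source_mask
        cos = np.sum(g1[sel] * g2[sel], axis=1)
        assert np.median(cos) > 0.9


class TestTracePath:
    def test_straight_descent_on_slab(self, slab_field):
        slab, field = slab_field
        start = voxel_index(slab, (15.0, 0.0, 0.0))
        path = geo.trace_path(field, start)
        length = geo.path_length_mm(path)
        assert abs(length - 30.0) / 30.0 < 0.10
        # terminates on the source
        end_idx = voxel_index(slab, path[-1])
        assert field.source_mask[end_idx]

    def test_start_on_source_single_point(self, slab_field):
        slab, field = slab_field
        start = voxel_index(slab, (-15.0, 0.0, 0.0))
        path = geo.trace_path(field, start)
        assert path.shape == (1, 3)

    def test_path_around_obstacle_matches_dijkstra(self):
        slab = analytic_shapes("slab", thickness=1.0, half_extent=10.0, spacing_mm=0.5)
        mask = slab.solid_mask.copy()
        # wall with a slot: block x=0 plane except a gap at y > 5
        wall_i = voxel_index(slab, (0.0, 0.0, 0.0))[0]
        ys = np.asarray(slab.origin_mm)[1] + 0.5 * np.arange(mask.shape[1])
        mask[wall_i, ys < 5.0, :] = False
        sdf = vio.signed_distance_from_mask(mask, slab.spacing_mm, slab.origin_mm)
        src, src_idx = point_source(sdf, (-8.0, 0.0, 0.0))
        field = geo.solve_eikonal(sdf, src, 1.0, domain_mask=mask)
        start = voxel_index(sdf, (8.0, 0.0, 0.0))
        path = geo.trace_path(field, start)
        d = dijkstra_grid(mask, 0.5, src_idx)
        assert abs(geo.path_length_mm(path) - d[start]) / d[start] < 0.10


class TestBuildDirection:
    def test_lobe_growth_axis_recovered(self, small_phantom):
        vol, gt = small_phantom
        field = geo.solve_eikonal(
            vol, gt.substrate_mask, metric=vol.values, iso_threshold=0.2
        )
        rep = geo.build_direction(field, gt.segment_labels == 1)
        assert rep.mean_gradient @ gt.growth_axes[0] > 0.95
        assert 0.0 <= rep.dispersion <= 1.0

    def test_isotropic_growth_high_dispersion(self):
        ball = analytic_shapes("ball", radius=10.0, spacing_mm=0.5)
        src, _ = point_source(ball, (0.0, 0.0, 0.0))
        field = geo.solve_eikonal(ball, src, 1.0)
        rep = geo.build_direction(field, np.isfinite(field.u))
        assert rep.dispersion > 0.5

    def test_mirrored_regions_cancel_in_plane(self, small_phantom):
        vol, gt = small_phantom
        field = geo.solve_eikonal(
            vol, gt.substrate_mask, metric=vol.values, iso_threshold=0.2
        )
        region = gt.segment_labels == 1
        xs = np.asarray(vol.origin_mm)[0] + vol.spacing_mm[0] * np.arange(vol.dims[0])
        left = region & (xs[:, None, None] < -3.0)
        right = region & (xs[:, None, None] > 3.0)
        rl = geo.build_direction(field, left)
        rr = geo.build_direction(field, right)
        assert abs(rl.mean_gradient[0] + rr.mean_gradient[0]) < 0.05

    def test_small_region_rejected(self, small_phantom):
        vol, gt = small_phantom
        field = geo.solve_eikonal(
            vol, gt.substrate_mask, metric=vol.values, iso_threshold=0.2
        )
        tiny = np.zeros(vol.dims, dtype=bool)
        idx = np.argwhere(gt.segment_labels == 1)[:10]
        tiny[tuple(idx.T)] = True
        with pytest.raises(ValueError, match="too small"):
            geo.build_direction(field, tiny)
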