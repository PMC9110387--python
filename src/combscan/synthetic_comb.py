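"""Deterministic comb phantoms with full ground truth.

The generator voxelizes an idealized *A. mellifera* comb at scan-like
resolution: one or more double-sided sheets of tessellated hexagonal
cells meeting at a median interface, hexagons point-up with one vertex
toward the substrate, cell axes tilted toward the opposite of a planted
gravity direction (canonically 13 degrees), walls of beeswax density,
an attachment substrate slab, and optional honey filling a contiguous
run of cells up to a volume budget.  Default dimensions follow reported
comb morphometrics: cell edge 2.5 mm (interior hexagon), wall 0.75 mm,
depth 10.5 mm, lobe spacing 8.5 mm.

Every geometric fact the analysis modules are meant to recover — cell
count, centers, axes, interface plane, gravity per growth segment,
per-material voxel counts, growth order — is recorded exactly in the
returned :class:`GroundTruth`, making phantoms a complete oracle for the
pipeline.  The same spec and seed always produce a bitwise-identical
volume.

Normalized-value encoding: ``value = density / 2`` g/cm^3, i.e. the
phantom's true attenuation calibration line has slope 2 and intercept 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .volume_io import DensityVolume, SignedDistanceVolume, SurfaceMesh

__all__ = [
    "CombPhantomSpec",
    "GroundTruth",
    "generate",
    "analytic_shapes",
    "DENSITY_TO_VALUE",
]

#: normalized attenuation value per g/cm^3
DENSITY_TO_VALUE = 0.5

_SQRT3 = math.sqrt(3.0)


@dataclass(frozen=True)
class CombPhantomSpec:
    """Full parameterization of a synthetic comb phantom."""

    cell_edge_mm: float = 2.5
    wall_thickness_mm: float = 0.75
    cell_depth_mm: float = 10.5
    tilt_deg: float = 13.0
    lobe_spacing_mm: float = 8.5
    rows: int = 4
    cols: int = 5
    n_cells: int | None = None  # optional row-major truncation of rows*cols
    sides: int = 2  # 1 = cells on one sheet face, 2 = mirrored double-sided
    n_lobes: int = 1
    warp: str = "none"  # none | cylinder_bend | saddle | l_bend | y_branch
    warp_amplitude: float = 0.0  # saddle coeff (1/mm), bend radius (mm) or angle (deg)
    branch_rows: tuple | None = None  # per-branch row counts for y_branch
    # (unequal branch lengths keep the Fiedler field monotone trunk-to-tip)
    gravity_switch_deg: float | None = None  # second growth segment, rotated gravity
    wax_density: float = 0.95
    honey_density: float = 1.4
    substrate_density: float = 1.19
    honey_volume_mm3: float = 0.0
    substrate_thickness_mm: float = 2.0
    spacing_mm: float = 0.2
    margin_mm: float = 1.0
    rotation: tuple | None = None  # optional 3x3 world rotation (rows)
    rng_seed: int = 0

    def validate(self) -> None:
        for name in (
            "cell_edge_mm",
            "wall_thickness_mm",
            "cell_depth_mm",
            "lobe_spacing_mm",
            "spacing_mm",
            "substrate_thickness_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.wall_thickness_mm < 2 * self.spacing_mm:
            raise ValueError(
                "insufficient resolution: wall thinner than 2 voxels "
                f"({self.wall_thickness_mm} mm at {self.spacing_mm} mm spacing)"
            )
        if self.sides not in (1, 2):
            raise ValueError("sides must be 1 or 2")
        if self.warp not in ("none", "cylinder_bend", "saddle", "l_bend", "y_branch"):
            raise ValueError(f"unknown warp {self.warp!r}")
        for d in (self.wax_density, self.honey_density, self.substrate_density):
            if not 0 < d * DENSITY_TO_VALUE <= 1:
                raise ValueError("material densities must map into (0, 1] normalized values")


@dataclass
class _Panel:
    """One flat sheet of cells in its own in-plane frame."""

    origin: np.ndarray  # world (pre-rotation) position of (u=0, v=0, w=0)
    e_u: np.ndarray
    e_v: np.ndarray
    e_w: np.ndarray
    rows: int
    cols: int
    n_cells: int
    gravity_uv: np.ndarray  # unit (u, v)
    order: int
    parent: int | None
    warp: str = "none"
    warp_amplitude: float = 0.0
    # derived lattice geometry (filled by _finalize)
    pitch: float = 0.0
    u_off: float = 0.0
    v0: float = 0.0
    width_u: float = 0.0
    length_v: float = 0.0
    placed: np.ndarray = None  # (rows, cols) bool


@dataclass
class GroundTruth:
    """Everything the phantom planted, for closing the analysis loop."""

    spec: CombPhantomSpec
    cell_count: int
    cell_centers_mm: np.ndarray  # (N, 3) world
    cell_axes: np.ndarray  # (N, 3) unit, pointing away from the interface
    cell_panel: np.ndarray  # (N,) panel index
    cell_side: np.ndarray  # (N,) +1 / -1
    interface_point_mm: np.ndarray
    interface_normal: np.ndarray
    gravity: np.ndarray  # world gravity of the first growth segment
    segment_gravity: list  # per-panel world gravity vectors
    segment_order: list  # per-panel growth order indices
    segment_parent: list
    growth_axes: list  # per-panel world growth (+v) directions
    segment_labels: np.ndarray  # per-voxel panel id + 1 (0 outside any panel)
    substrate_mask: np.ndarray
    material_counts: dict
    honey_planted_mm3: float
    interior_width_mm: float  # hexagon flat-to-flat
    interior_depth_mm: float
    cell_volume_mm3: float  # analytic hexagonal prism volume
    calibration_slope: float = 1.0 / DENSITY_TO_VALUE
    calibration_intercept: float = 0.0
    extra: dict = field(default_factory=dict)


def _hex_dist(du: np.ndarray, dv: np.ndarray) -> np.ndarray:
    """Point-up hexagon gauge: <= e inside a hexagon of edge (circumradius) e."""
    adu = np.abs(du)
    return np.maximum(2.0 * adu / _SQRT3, adu / _SQRT3 + np.abs(dv))


def _rot2(deg: float) -> np.ndarray:
    a = math.radians(deg)
    return np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])


def _finalize_panel(p: _Panel, spec: CombPhantomSpec) -> None:
    e_int = spec.cell_edge_mm
    pitch_e = e_int + spec.wall_thickness_mm / _SQRT3
    p.pitch = pitch_e
    tanphi = math.tan(math.radians(spec.tilt_deg))
    # cells shift in-plane with depth (the tilt); margins must cover the
    # shifted interiors so every planted cell is fully walled
    shift = spec.cell_depth_mm * tanphi * (-p.gravity_uv)
    base = pitch_e + spec.wall_thickness_mm + 0.5
    margin_u = base + abs(shift[0])
    lattice_u = (p.cols - 1 + 0.5) * _SQRT3 * pitch_e
    p.u_off = -lattice_u / 2.0
    p.v0 = base + max(0.0, -shift[1])
    p.width_u = lattice_u + 2.0 * margin_u
    p.length_v = p.v0 + (p.rows - 1) * 1.5 * pitch_e + base + max(0.0, shift[1])
    placed = np.zeros((p.rows, p.cols), dtype=bool)
    n = p.n_cells if p.n_cells is not None else p.rows * p.cols
    n = min(n, p.rows * p.cols)
    flat = 0
    for j in range(p.rows):
        for i in range(p.cols):
            if flat < n:
                placed[j, i] = True
            flat += 1
    p.placed = placed


def _build_panels(spec: CombPhantomSpec) -> list[_Panel]:
    ex = np.array([1.0, 0.0, 0.0])
    ey = np.array([0.0, 1.0, 0.0])
    ez = np.array([0.0, 0.0, 1.0])
    g0 = np.array([0.0, 1.0])  # gravity along growth (+v): comb builds downward

    def panel(origin, e_u, e_v, grav_uv, order, parent, warp="none", amp=0.0, rows=None, cols=None):
        return _Panel(
            origin=np.asarray(origin, float),
            e_u=np.asarray(e_u, float),
            e_v=np.asarray(e_v, float),
            e_w=np.cross(e_u, e_v),
            rows=spec.rows if rows is None else rows,
            cols=spec.cols if cols is None else cols,
            n_cells=spec.n_cells,
            gravity_uv=np.asarray(grav_uv, float),
            order=order,
            parent=parent,
            warp=warp,
            warp_amplitude=amp,
        )

    panels: list[_Panel] = []
    if spec.warp in ("none", "cylinder_bend", "saddle") and spec.gravity_switch_deg is None:
        panels.append(panel([0, 0, 0], ex, ey, g0, 0, None, spec.warp, spec.warp_amplitude))
    elif spec.gravity_switch_deg is not None:
        p0 = panel([0, 0, 0], ex, ey, g0, 0, None)
        _finalize_panel(p0, spec)
        g1 = _rot2(spec.gravity_switch_deg) @ g0
        p1 = panel([0, p0.length_v, 0], ex, ey, g1, 1, 0)
        panels.extend([p0, p1])
    elif spec.warp == "l_bend":
        angle = spec.warp_amplitude or 90.0
        p0 = panel([0, 0, 0], ex, ey, g0, 0, None)
        _finalize_panel(p0, spec)
        R = _rot2(angle)
        e_v1 = R[0, 0] * ey + R[1, 0] * ez  # rotate growth axis out of plane about e_u
        p1 = _Panel(
            origin=np.array([0.0, p0.length_v, 0.0]),
            e_u=ex,
            e_v=e_v1 / np.linalg.norm(e_v1),
            e_w=np.cross(ex, e_v1 / np.linalg.norm(e_v1)),
            rows=spec.rows,
            cols=spec.cols,
            n_cells=spec.n_cells,
            gravity_uv=g0,
            order=1,
            parent=0,
        )
        panels.extend([p0, p1])
    elif spec.warp == "y_branch":
        angle = spec.warp_amplitude or 40.0
        p0 = panel([0, 0, 0], ex, ey, g0, 0, None)
        _finalize_panel(p0, spec)
        tip = np.array([0.0, p0.length_v, 0.0])
        panels.append(p0)
        brows = spec.branch_rows or (spec.rows + 2, max(2, spec.rows - 1))
        for k, sgn in enumerate((-1.0, 1.0)):
            Rb = _rot2(sgn * angle)
            e_v1 = Rb[0, 0] * ey + Rb[1, 0] * ex
            e_u1 = np.cross(e_v1, ez)
            panels.append(panel(tip, e_u1, e_v1, g0, 1 + k, 0, rows=int(brows[k])))
    for p in panels:
        if p.placed is None:
            _finalize_panel(p, spec)
    return panels


def _panel_flat_coords(p: _Panel, pts: np.ndarray):
    """World (pre-rotation) points -> flattened panel coords (u, v, w)."""
    rel = pts - p.origin
    u = rel @ p.e_u
    v = rel @ p.e_v
    w = rel @ p.e_w
    if p.warp == "saddle" and p.warp_amplitude != 0.0:
        w = w - p.warp_amplitude * (u * u - (v - p.length_v / 2.0) ** 2)
    elif p.warp == "cylinder_bend" and p.warp_amplitude != 0.0:
        R = p.warp_amplitude
        rho = np.sqrt(v * v + (R - w) ** 2)
        v = R * np.arctan2(v, R - w)
        w = rho - R
    return u, v, w


def _panel_forward(p: _Panel, u, v, w) -> np.ndarray:
    """Flattened panel coords -> world (pre-rotation) point."""
    u = float(u)
    v = float(v)
    w = float(w)
    if p.warp == "saddle" and p.warp_amplitude != 0.0:
        w = w + p.warp_amplitude * (u * u - (v - p.length_v / 2.0) ** 2)
    elif p.warp == "cylinder_bend" and p.warp_amplitude != 0.0:
        R = p.warp_amplitude
        q = (R + w) * np.sin(v / R)
        r = R - (R + w) * np.cos(v / R)
        v, w = q, r
    return p.origin + u * p.e_u + v * p.e_v + w * p.e_w


def _panel_cell_query(p: _Panel, spec: CombPhantomSpec, u, v, w, lobe_offset: float):
    """Cell-interior test for all points at once.

    Cells are hexagonal prisms rotated by the tilt angle about their base
    centers (axis = interface normal tilted toward minus gravity).
    Returns (in_slab, in_cell, cell_row, cell_col, s) where s is the depth
    coordinate along the cell axis measured from the base.
    """
    w = w - lobe_offset
    w0 = spec.wall_thickness_mm / 2.0
    W_half = w0 + spec.cell_depth_mm
    in_domain = (np.abs(u) <= p.width_u / 2.0) & (v >= 0.0) & (v <= p.length_v)
    if spec.sides == 2:
        wa = np.abs(w)
        in_slab = in_domain & (wa <= W_half)
    else:
        wa = w
        in_slab = in_domain & (w >= -w0) & (w <= W_half)

    phi = math.radians(spec.tilt_deg)
    sinp, cosp = math.sin(phi), math.cos(phi)
    tanphi = math.tan(phi)
    t = -p.gravity_uv  # in-plane tilt direction (cells lean against gravity)
    t_perp = np.array([-t[1], t[0]])
    qw = wa - w0
    # shear estimate only to locate candidate lattice centers
    uu = u - np.maximum(qw, 0.0) * tanphi * t[0]
    vv = v - np.maximum(qw, 0.0) * tanphi * t[1]

    pitch = p.pitch
    jf = (vv - p.v0) / (1.5 * pitch)
    j_base = np.rint(jf).astype(np.int64)
    best = np.full(u.shape, np.inf)
    best_i = np.zeros(u.shape, dtype=np.int64)
    best_j = np.zeros(u.shape, dtype=np.int64)
    best_s = np.zeros(u.shape)
    for dj in (-1, 0, 1):
        j = j_base + dj
        v_c = p.v0 + j * 1.5 * pitch
        if_ = (uu - p.u_off) / (_SQRT3 * pitch) - 0.5 * (j % 2)
        i_base = np.rint(if_).astype(np.int64)
        for di in (-1, 0, 1):
            i = i_base + di
            u_c = p.u_off + (i + 0.5 * (j % 2)) * _SQRT3 * pitch
            qu = u - u_c
            qv = v - v_c
            qt = qu * t[0] + qv * t[1]
            s = qt * sinp + qw * cosp  # depth along the rotated axis
            d1 = qt * cosp - qw * sinp  # in-plane offset in the tilt plane
            d2 = qu * t_perp[0] + qv * t_perp[1]
            hd = _hex_dist(d2, d1)
            better = hd < best
            best = np.where(better, hd, best)
            best_i = np.where(better, i, best_i)
            best_j = np.where(better, j, best_j)
            best_s = np.where(better, s, best_s)

    valid = (
        (best_j >= 0)
        & (best_j < p.rows)
        & (best_i >= 0)
        & (best_i < p.cols)
    )
    placed = np.zeros(u.shape, dtype=bool)
    placed[valid] = p.placed[best_j[valid], best_i[valid]]
    in_cell = (
        in_domain
        & placed
        & (best <= spec.cell_edge_mm)
        & (best_s >= 0.0)
        & (best_s < spec.cell_depth_mm)
        & (qw >= 0.0)  # the base wall (septum) clips the rotated prism
    )
    return in_slab, in_cell, best_j, best_i, best_s


def _honey_levels(spec: CombPhantomSpec, panels: list[_Panel]) -> dict:
    """Per (panel, side, row, col) fill fraction of depth, seeded, contiguous."""
    if spec.honey_volume_mm3 <= 0:
        return {}
    cell_vol = 1.5 * _SQRT3 * spec.cell_edge_mm**2 * spec.cell_depth_mm
    slots = []
    for pi, p in enumerate(panels):
        for s in ((1,) if spec.sides == 1 else (1, -1)):
            for j in range(p.rows):
                for i in range(p.cols):
                    if p.placed[j, i]:
                        slots.append((pi, s, j, i))
    need = spec.honey_volume_mm3 / cell_vol
    n_slots = len(slots)
    if need > n_slots:
        raise ValueError(
            f"honey budget {spec.honey_volume_mm3} mm^3 exceeds total cell volume"
        )
    rng = np.random.default_rng(spec.rng_seed)
    n_full = int(math.floor(need))
    start_max = n_slots - int(math.ceil(need))
    start = int(rng.integers(0, start_max + 1)) if start_max > 0 else 0
    levels = {}
    for k in range(n_full):
        levels[slots[start + k]] = 1.0
    frac = need - n_full
    if frac > 1e-12 and start + n_full < n_slots:
        levels[slots[start + n_full]] = frac
    return levels


def generate(spec: CombPhantomSpec) -> tuple[DensityVolume, GroundTruth]:
    """Voxelize the phantom and return it with its complete ground truth."""
    spec.validate()
    panels = _build_panels(spec)
    h = spec.spacing_mm
    w0 = spec.wall_thickness_mm / 2.0
    W_half = w0 + spec.cell_depth_mm
    lobe_offsets = [k * spec.lobe_spacing_mm for k in range(spec.n_lobes)]

    R = np.eye(3) if spec.rotation is None else np.asarray(spec.rotation, float)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
        raise ValueError("rotation must be a 3x3 orthonormal matrix")

    # bounding box of all panels + substrate, in pre-rotation coordinates
    corners = []
    slab_lo = -W_half if spec.sides == 2 else -w0
    for p in panels:
        for su in (-p.width_u / 2, p.width_u / 2):
            for sv in (0.0, p.length_v):
                for sw in (slab_lo, W_half):
                    for lo in lobe_offsets:
                        bulge = 0.0
                        if p.warp == "saddle":
                            bulge = abs(p.warp_amplitude) * max(
                                (p.width_u / 2) ** 2, (p.length_v / 2) ** 2
                            )
                        corners.append(
                            _panel_forward(p, su, sv, sw + lo)
                            + np.array([0, 0, np.sign(sw) * bulge])
                        )
    p0 = panels[0]
    sub_half_w = (
        W_half + 2.0 + (lobe_offsets[-1] if lobe_offsets else 0.0)
    )
    for su in (-p0.width_u / 2 - 2, p0.width_u / 2 + 2):
        for sv in (-spec.substrate_thickness_mm, 0.0):
            for sw in (slab_lo - 2, sub_half_w):
                corners.append(p0.origin + su * p0.e_u + sv * p0.e_v + sw * p0.e_w)
    corners = np.asarray(corners) @ R.T
    lo = corners.min(axis=0) - spec.margin_mm
    hi = corners.max(axis=0) + spec.margin_mm
    dims = np.maximum(np.ceil((hi - lo) / h).astype(int) + 1, 2)
    origin = lo

    levels = _honey_levels(spec, panels)
    level_tables: dict[int, np.ndarray] = {}
    for (pi, s, j, i), lv in levels.items():
        tab = level_tables.setdefault(pi, np.zeros((2, panels[pi].rows, panels[pi].cols)))
        tab[0 if s == 1 else 1, j, i] = lv
    label = np.zeros(tuple(dims), dtype=np.uint8)  # 0 air 1 wax 2 honey 3 substrate
    seg = np.zeros(tuple(dims), dtype=np.uint8)

    ys = origin[1] + h * np.arange(dims[1])
    zs = origin[2] + h * np.arange(dims[2])
    Y, Z = np.meshgrid(ys, zs, indexing="ij")
    chunk = max(1, int(4e6 // (dims[1] * dims[2])))
    for i0 in range(0, dims[0], chunk):
        i1 = min(i0 + chunk, dims[0])
        xs = origin[0] + h * np.arange(i0, i1)
        pts = np.empty((i1 - i0, dims[1], dims[2], 3))
        pts[..., 0] = xs[:, None, None]
        pts[..., 1] = Y[None, :, :]
        pts[..., 2] = Z[None, :, :]
        flat = pts.reshape(-1, 3) @ R  # R.T applied from the right = inverse rotation
        shape = (i1 - i0, dims[1], dims[2])

        wax_any = np.zeros(flat.shape[0], dtype=bool)
        cell_any = np.zeros(flat.shape[0], dtype=bool)
        honey_any = np.zeros(flat.shape[0], dtype=bool)
        seg_chunk = np.zeros(flat.shape[0], dtype=np.uint8)
        for pi, p in enumerate(panels):
            u, v, w = _panel_flat_coords(p, flat)
            for lobe in lobe_offsets:
                in_slab, in_cell, bj, bi, wrel = _panel_cell_query(p, spec, u, v, w, lobe)
                wax_any |= in_slab
                cell_any |= in_cell
                if pi in level_tables:
                    # fill-height test, vectorized via the per-panel level table
                    table = level_tables[pi]  # (2, rows, cols)
                    side_idx = ((w - lobe) < 0).astype(np.int64)  # 0: +w, 1: -w
                    lv = np.zeros(flat.shape[0])
                    sel = in_cell
                    if sel.any():
                        lv[sel] = table[side_idx[sel], bj[sel], bi[sel]]
                    honey_any |= in_cell & (wrel < lv * spec.cell_depth_mm)
                new_seg = in_slab & (seg_chunk == 0)
                seg_chunk[new_seg] = pi + 1

        # substrate slab in panel-0 frame
        rel = flat - p0.origin
        su = rel @ p0.e_u
        sv = rel @ p0.e_v
        sw = rel @ p0.e_w
        substrate = (
            (np.abs(su) <= p0.width_u / 2 + 2)
            & (sv >= -spec.substrate_thickness_mm)
            & (sv < 0)
            & (sw >= slab_lo - 2)
            & (sw <= sub_half_w)
        )

        lab = np.zeros(flat.shape[0], dtype=np.uint8)
        lab[wax_any & ~cell_any] = 1
        lab[cell_any & honey_any] = 2
        lab[substrate] = 3
        label[i0:i1] = lab.reshape(shape)
        seg_chunk[~(wax_any | cell_any)] = 0
        seg[i0:i1] = seg_chunk.reshape(shape)

    densities = np.array(
        [0.0, spec.wax_density, spec.honey_density, spec.substrate_density]
    )
    values = densities[label] * DENSITY_TO_VALUE
    vol = DensityVolume(spacing_mm=(h, h, h), origin_mm=tuple(origin), values=values)

    counts = np.bincount(label.ravel(), minlength=4)
    material_counts = {
        "air": int(counts[0]),
        "wax": int(counts[1]),
        "honey": int(counts[2]),
        "substrate": int(counts[3]),
    }

    # ------------------------------------------------------------------
    # ground truth
    phi = math.radians(spec.tilt_deg)
    sinp, cosp = math.sin(phi), math.cos(phi)
    centers = []
    axes = []
    cpanel = []
    cside = []
    delta = 1e-3
    for pi, p in enumerate(panels):
        t_uv = -p.gravity_uv
        for lobe in lobe_offsets:
            for s in ((1,) if spec.sides == 1 else (1, -1)):
                for j in range(p.rows):
                    for i in range(p.cols):
                        if not p.placed[j, i]:
                            continue
                        u_c = p.u_off + (i + 0.5 * (j % 2)) * _SQRT3 * p.pitch
                        v_c = p.v0 + j * 1.5 * p.pitch
                        mid = spec.cell_depth_mm / 2.0
                        # cell axis: interface normal rotated by the tilt
                        uu = u_c + mid * sinp * t_uv[0]
                        vv = v_c + mid * sinp * t_uv[1]
                        ww = s * (w0 + mid * cosp) + lobe
                        c = _panel_forward(p, uu, vv, ww)
                        c2 = _panel_forward(
                            p,
                            uu + delta * sinp * t_uv[0],
                            vv + delta * sinp * t_uv[1],
                            ww + s * delta * cosp,
                        )
                        ax = (c2 - c) / np.linalg.norm(c2 - c)
                        centers.append(R @ c)
                        axes.append(R @ ax)
                        cpanel.append(pi)
                        cside.append(s)
    centers = np.asarray(centers).reshape(-1, 3)
    axes = np.asarray(axes).reshape(-1, 3)

    def world_vec(p: _Panel, uv: np.ndarray) -> np.ndarray:
        v3 = uv[0] * p.e_u + uv[1] * p.e_v
        return R @ v3

    seg_gravity = [world_vec(p, p.gravity_uv) for p in panels]
    growth_axes = [R @ p.e_v for p in panels]
    interface_point = R @ panels[0].origin
    interface_normal = R @ panels[0].e_w

    gt = GroundTruth(
        spec=spec,
        cell_count=len(centers),
        cell_centers_mm=centers,
        cell_axes=axes,
        cell_panel=np.asarray(cpanel, dtype=int),
        cell_side=np.asarray(cside, dtype=int),
        interface_point_mm=interface_point,
        interface_normal=interface_normal,
        gravity=seg_gravity[0],
        segment_gravity=seg_gravity,
        segment_order=[p.order for p in panels],
        segment_parent=[p.parent for p in panels],
        growth_axes=growth_axes,
        segment_labels=seg,
        substrate_mask=label == 3,
        material_counts=material_counts,
        honey_planted_mm3=material_counts["honey"] * h**3,
        interior_width_mm=_SQRT3 * spec.cell_edge_mm,
        interior_depth_mm=spec.cell_depth_mm,
        cell_volume_mm3=1.5 * _SQRT3 * spec.cell_edge_mm**2 * spec.cell_depth_mm,
    )
    gt.extra["label_volume"] = label
    return vol, gt


# ---------------------------------------------------------------------------
# analytic shapes (exact SDFs / meshes for oracle tests)
# ---------------------------------------------------------------------------


def _grid(extent_mm, spacing: float):
    ext = np.asarray(extent_mm, float).reshape(3, 2)
    axes = [np.arange(ext[a, 0], ext[a, 1] + spacing / 2, spacing) for a in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    origin = (axes[0][0], axes[1][0], axes[2][0])
    return X, Y, Z, origin


def analytic_shapes(kind: str, spacing_mm: float = 0.5, **params):
    """Analytically exact signed distance volumes (or meshes) for oracles.

    Kinds: ``ball`` (radius, center), ``slab`` (thickness, z0, half_extent),
    ``cylinder_shell`` (radius, thickness, length), ``dumbbell``
    (ball_radius, separation, neck_radius), ``saddle`` (coeff, half_extent;
    returns a mesh z = coeff*(x^2 - y^2)).
    """
    if kind == "ball":
        r = params.get("radius", 10.0)
        c = np.asarray(params.get("center", (0.0, 0.0, 0.0)))
        m = params.get("margin", 3.0)
        ext = [(c[a] - r - m, c[a] + r + m) for a in range(3)]
        X, Y, Z, origin = _grid(ext, spacing_mm)
        d = np.sqrt((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2) - r
        return SignedDistanceVolume(
            spacing_mm=(spacing_mm,) * 3, origin_mm=origin, distances=d
        )
    if kind == "slab":
        t = params.get("thickness", 1.0)
        z0 = params.get("z0", 0.0)
        hx = params.get("half_extent", 20.0)
        m = params.get("margin", 2.0)
        ext = [(-hx, hx), (-hx, hx), (z0 - t / 2 - m, z0 + t / 2 + m)]
        X, Y, Z, origin = _grid(ext, spacing_mm)
        d = np.abs(Z - z0) - t / 2
        return SignedDistanceVolume(
            spacing_mm=(spacing_mm,) * 3, origin_mm=origin, distances=d
        )
    if kind == "cylinder_shell":
        r = params.get("radius", 10.0)
        t = params.get("thickness", 1.0)
        length = params.get("length", 30.0)
        m = params.get("margin", 2.0)
        ext = [
            (-r - t - m, r + t + m),
            (-r - t - m, r + t + m),
            (-length / 2 - m, length / 2 + m),
        ]
        X, Y, Z, origin = _grid(ext, spacing_mm)
        radial = np.abs(np.sqrt(X**2 + Y**2) - r) - t / 2
        axial = np.abs(Z) - length / 2
        d = np.maximum(radial, axial)
        return SignedDistanceVolume(
            spacing_mm=(spacing_mm,) * 3, origin_mm=origin, distances=d
        )
    if kind == "dumbbell":
        rb = params.get("ball_radius", 6.0)
        sep = params.get("separation", 20.0)
        rn = params.get("neck_radius", 1.5)
        m = params.get("margin", 2.0)
        ext = [
            (-sep / 2 - rb - m, sep / 2 + rb + m),
            (-rb - m, rb + m),
            (-rb - m, rb + m),
        ]
        X, Y, Z, origin = _grid(ext, spacing_mm)
        d1 = np.sqrt((X + sep / 2) ** 2 + Y**2 + Z**2) - rb
        d2 = np.sqrt((X - sep / 2) ** 2 + Y**2 + Z**2) - rb
        radial = np.sqrt(Y**2 + Z**2) - rn
        neck = np.maximum(radial, np.abs(X) - sep / 2)
        d = np.minimum(np.minimum(d1, d2), neck)
        return SignedDistanceVolume(
            spacing_mm=(spacing_mm,) * 3, origin_mm=origin, distances=d
        )
    if kind == "saddle":
        coeff = params.get("coeff", 0.05)
        hx = params.get("half_extent", 10.0)
        n = params.get("n", 41)
        xs = np.linspace(-hx, hx, n)
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        Z = coeff * (X**2 - Y**2)
        verts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        faces = []
        for i in range(n - 1):
            for j in range(n - 1):
                a = i * n + j
                b = a + 1
                c = a + n
                d = c + 1
                faces.append((a, b, c))
                faces.append((b, d, c))
        return SurfaceMesh(vertices=verts, faces=np.asarray(faces))
    raise ValueError(f"unknown analytic shape {kind!r}")
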