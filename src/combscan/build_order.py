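"""Heuristic reconstruction of comb construction order.

Starting from the endpoints of the comb's medial tree (the Fiedler curve
skeleton), the walk moves back along decreasing geodesic distance from
the substrate until a branch node; there the segment's build direction
(mean geodesic gradient) and gravity (from its cells' tilt) are
re-estimated, and the walk continues toward the root.  Reversing the
walk yields a plausible construction timeline: the substrate-adjacent
trunk first, then each branch in order of increasing distance.

Sibling branches of the same parent cannot be ordered by this heuristic;
they are ordered by ascending mean geodesic value and flagged as ties.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cell_analysis import CellSet, MedianPlane, cell_frames, tilt_and_gravity
from .geodesics import GeodesicField, build_direction
from .spectral_skeleton import CurveSkeleton

__all__ = [
    "BuildSegment",
    "BuildTimeline",
    "medial_skeleton",
    "reconstruct_build_order",
    "timeline_report",
]


def medial_skeleton(
    section,
    substrate_mask: np.ndarray,
    closure_radius_mm: float = 4.0,
    n_contours: int = 20,
    downsample_factor: int = 2,
    min_branch_nodes: int = 3,
) -> CurveSkeleton:
    """Medial tree of a comb: distance-front isocontours on its closure.

    The comb is morphologically closed (cells filled) so the skeleton
    tracks the lobe, not individual walls; geodesic distance from the
    substrate is solved over the closed solid, sampled at the closure
    surface, and its isocontour centroids are linked into a tree.
    Distance fronts split wherever the lobe branches, which is exactly
    the branch structure the construction walk needs.
    """
    from . import morphology as mo
    from . import spectral_skeleton as sk
    from . import volume_io as vio
    from .geodesics import solve_eikonal
    from scipy.ndimage import map_coordinates

    h = section.require_isotropic("medial_skeleton")
    comb_only = section.solid_mask & ~np.asarray(substrate_mask, bool)
    closed = mo.close_mask(comb_only, closure_radius_mm, h)
    csdf = vio.signed_distance_from_mask(
        closed, section.spacing_mm, section.origin_mm, getattr(section, "iso_threshold", 0.5)
    )
    f = max(1, int(downsample_factor))
    if f > 1:
        vals = np.clip(0.5 - 0.5 * np.tanh(csdf.distances), 0.0, 1.0)  # smooth indicator
        dv = vio.DensityVolume(
            spacing_mm=csdf.spacing_mm, origin_mm=csdf.origin_mm, values=vals
        )
        dv = vio.downsample(dv, f)
        mask = dv.values >= 0.5
        sub = np.asarray(substrate_mask, bool)
        nx, ny, nz = (s // f for s in sub.shape)
        subc = sub[: nx * f, : ny * f, : nz * f]
        sub_ds = subc.reshape(nx, f, ny, f, nz, f).any(axis=(1, 3, 5))
        sub_ds = sub_ds[: mask.shape[0], : mask.shape[1], : mask.shape[2]]
        csdf = vio.signed_distance_from_mask(mask, dv.spacing_mm, dv.origin_mm)
        substrate_mask = sub_ds
    grown = csdf.distances < csdf.spacing_mm[0] * 1.5  # one-voxel shell for surface sampling
    dom = grown | substrate_mask
    field = solve_eikonal(csdf, np.asarray(substrate_mask, bool), metric=1.0, domain_mask=dom)
    mesh = vio.extract_mesh(csdf)
    idx = (mesh.vertices - np.asarray(csdf.origin_mm)) / np.asarray(csdf.spacing_mm)
    u = field.u.copy()
    bad = ~np.isfinite(u)
    if bad.any():
        u[bad] = np.nanmax(np.where(np.isfinite(u), u, np.nan))
    vert_u = map_coordinates(u, [idx[:, 0], idx[:, 1], idx[:, 2]], order=1, mode="nearest")
    basis = sk.SpectralBasis(
        mesh=mesh, eigenvalues=np.array([0.0, 1.0]), eigenvectors=np.zeros((mesh.n_vertices, 2))
    )
    skel = sk.curve_skeleton(basis, n_contours=n_contours, scalar_field=vert_u)
    return sk.prune_skeleton(skel, min_branch_nodes=min_branch_nodes)


@dataclass
class BuildSegment:
    """A chain of skeleton nodes between branch points, with its vectors."""

    order: int
    nodes: list[int]
    build_direction: np.ndarray
    gravity: np.ndarray | None
    parent: int | None
    n_cells: int
    gravity_inherited: bool = False
    sibling_tie: bool = False
    mean_geodesic_mm: float = 0.0


@dataclass
class BuildTimeline:
    segments: list[BuildSegment] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.segments)


def _segment_tree(skeleton: CurveSkeleton, root: int) -> list[dict]:
    """Decompose the skeleton tree into chains between branch/leaf nodes."""
    adj = skeleton.adjacency()
    n = skeleton.n_nodes
    parent = np.full(n, -1, dtype=int)
    order = []
    seen = np.zeros(n, dtype=bool)
    stack = [root]
    seen[root] = True
    while stack:
        v = stack.pop()
        order.append(v)
        for w in adj[v]:
            if not seen[w]:
                seen[w] = True
                parent[w] = v
                stack.append(w)
    if not seen.all():
        raise ValueError("skeleton is not connected")

    def is_junction(v: int) -> bool:
        return v == root or len(adj[v]) >= 3

    segments = []
    for v in order:
        if v == root:
            continue
        p = parent[v]
        if is_junction(p):
            # start a new chain at p -> v, follow until next junction/leaf
            chain = [int(p), int(v)]
            cur = v
            while not is_junction(cur) and len(adj[cur]) == 2:
                nxt = [w for w in adj[cur] if w != chain[-2]][0]
                chain.append(int(nxt))
                cur = nxt
            segments.append({"nodes": chain, "parent_node": int(p)})
    return segments


def _subdivide_chains(chains: list[dict], skeleton: CurveSkeleton, max_len: float) -> list[dict]:
    out = []
    for ch in chains:
        owned = [v for v in ch["nodes"] if v != ch.get("parent_node")]
        prev_parent = ch.get("parent_node")
        run: list[int] = []
        run_len = 0.0
        last = prev_parent
        for v in owned:
            if last is not None:
                run_len += float(np.linalg.norm(skeleton.nodes[v] - skeleton.nodes[last]))
            run.append(v)
            last = v
            if run_len >= max_len:
                nodes = ([prev_parent] if prev_parent is not None else []) + run
                out.append({"nodes": nodes, "parent_node": prev_parent})
                prev_parent = run[-1]
                run = []
                run_len = 0.0
        if run:
            nodes = ([prev_parent] if prev_parent is not None else []) + run
            out.append({"nodes": nodes, "parent_node": prev_parent})
    return out


def reconstruct_build_order(
    skeleton: CurveSkeleton,
    geo: GeodesicField,
    cells: CellSet | None = None,
    plane: MedianPlane | None = None,
    min_cells_per_segment: int = 5,
    max_segment_length_mm: float | None = None,
) -> BuildTimeline:
    """Order skeleton segments from the substrate outward.

    The root is the skeleton node of smallest geodesic value (it should
    sit adjacent to the substrate source; a warning is issued otherwise).
    Comb voxels are assigned to their nearest skeleton node; each
    segment's build direction is the mean unit gradient over its voxels,
    and its gravity comes from the tilt of its member cells (inherited
    from the parent, flagged, when a segment has too few cells).
    """
    n = skeleton.n_nodes
    if n == 0:
        raise ValueError("empty skeleton")

    node_idx = np.asarray(
        [
            np.clip(
                np.round((skeleton.nodes[i] - np.asarray(geo.origin_mm)) / np.asarray(geo.spacing_mm)),
                0,
                np.asarray(geo.u.shape) - 1,
            )
            for i in range(n)
        ],
        dtype=int,
    )
    node_u = np.array([geo.u[tuple(node_idx[i])] for i in range(n)])
    # a node can sit in a cell cavity; fall back to nearest finite voxel value
    if not np.isfinite(node_u).all():
        finite_idx = np.argwhere(np.isfinite(geo.u) & geo.domain_mask)
        finite_pos = np.asarray(geo.origin_mm) + finite_idx * np.asarray(geo.spacing_mm)
        for i in np.flatnonzero(~np.isfinite(node_u)):
            d2 = ((finite_pos - skeleton.nodes[i]) ** 2).sum(axis=1)
            node_u[i] = geo.u[tuple(finite_idx[np.argmin(d2)])]
    root = int(np.argmin(node_u))
    src_pos = np.argwhere(geo.source_mask)
    if len(src_pos):
        src_mm = np.asarray(geo.origin_mm) + src_pos * np.asarray(geo.spacing_mm)
        d_root = np.min(np.linalg.norm(src_mm - skeleton.nodes[root], axis=1))
        others = np.linalg.norm(skeleton.nodes - skeleton.nodes[root], axis=1)
        scale = others.max() if n > 1 else 1.0
        if d_root > 0.5 * scale:
            warnings.warn("geodesic field does not appear rooted at the substrate")

    if n == 1:
        chains = [{"nodes": [0], "parent_node": None}]
    else:
        chains = _segment_tree(skeleton, root)
    if max_segment_length_mm is not None and n > 1:
        # a long unbranched lobe built under changing conditions (e.g. a
        # hive rotation) carries no branch point; optional subdivision
        # re-estimates gravity over shorter spans of the walk
        chains = _subdivide_chains(chains, skeleton, max_segment_length_mm)
    # assign comb voxels to nearest node
    dom = np.argwhere(geo.domain_mask & np.isfinite(geo.u))
    dom_mm = np.asarray(geo.origin_mm) + dom * np.asarray(geo.spacing_mm)
    from scipy.spatial import cKDTree

    tree = cKDTree(skeleton.nodes)
    _, nearest = tree.query(dom_mm)
    node_of_voxel = np.asarray(nearest)

    seg_of_node = np.full(n, -1, dtype=int)
    for si, ch in enumerate(chains):
        for v in ch["nodes"]:
            if v == ch.get("parent_node"):
                continue
            seg_of_node[v] = si
    seg_of_node[root] = 0 if chains else -1

    # per-chain mean geodesic value (for sibling ordering)
    seg_mean_u = []
    for ch in chains:
        vals = [node_u[v] for v in ch["nodes"] if v != ch.get("parent_node")]
        seg_mean_u.append(float(np.mean(vals)) if vals else float("inf"))

    # chain parent relations: chain whose parent_node lies inside another chain
    chain_parent = []
    for ch in chains:
        pn = ch.get("parent_node")
        if pn is None or pn == root:
            chain_parent.append(None)
        else:
            chain_parent.append(int(seg_of_node[pn]))
    # order chains topologically, siblings by ascending mean u
    idx_sorted = sorted(range(len(chains)), key=lambda s: seg_mean_u[s])
    order_of_chain = {}
    assigned = []
    while len(assigned) < len(chains):
        progressed = False
        for s in idx_sorted:
            if s in order_of_chain:
                continue
            p = chain_parent[s]
            if p is None or p in order_of_chain:
                order_of_chain[s] = len(assigned)
                assigned.append(s)
                progressed = True
        if not progressed:
            raise ValueError("cycle detected in skeleton segments")

    # sibling tie flags
    ties = set()
    by_parent: dict = {}
    for s, p in enumerate(chain_parent):
        by_parent.setdefault(p, []).append(s)
    for p, group in by_parent.items():
        if len(group) > 1:
            ties.update(group)

    plane_for_gravity = plane
    cell_seg = None
    if cells is not None and cells.n_cells > 0:
        if cells.frames is None:
            cell_frames(cells)
        _, cell_node = tree.query(cells.centroids_mm)
        cell_seg = seg_of_node[np.asarray(cell_node)]

    segments: list[BuildSegment] = []
    gravity_by_chain: dict[int, np.ndarray | None] = {}
    for s in assigned:
        ch = chains[s]
        members = [v for v in ch["nodes"] if seg_of_node[v] == s]
        vox_sel = np.isin(node_of_voxel, members)
        region = np.zeros(geo.u.shape, dtype=bool)
        region[tuple(dom[vox_sel].T)] = True
        try:
            bd = build_direction(geo, region, region_id=s, min_voxels=10)
            direction = bd.mean_gradient
        except ValueError:
            direction = np.zeros(3)

        gravity = None
        inherited = False
        n_seg_cells = 0
        if cell_seg is not None:
            member_cells = np.flatnonzero(cell_seg == s) + 1
            n_seg_cells = len(member_cells)
            if n_seg_cells >= min_cells_per_segment and plane_for_gravity is not None:
                sub = _subset_cells(cells, member_cells)
                try:
                    _, gravity = tilt_and_gravity(
                        sub, plane_for_gravity, min_cells=min_cells_per_segment
                    )
                except ValueError:
                    gravity = None
            if gravity is None:
                p = chain_parent[s]
                gravity = gravity_by_chain.get(p) if p is not None else None
                inherited = gravity is not None
        gravity_by_chain[s] = gravity

        segments.append(
            BuildSegment(
                order=order_of_chain[s],
                nodes=[int(v) for v in ch["nodes"]],
                build_direction=np.asarray(direction, float),
                gravity=None if gravity is None else np.asarray(gravity, float),
                parent=None if chain_parent[s] is None else order_of_chain[chain_parent[s]],
                n_cells=n_seg_cells,
                gravity_inherited=inherited,
                sibling_tie=s in ties,
                mean_geodesic_mm=seg_mean_u[s],
            )
        )
    segments.sort(key=lambda sg: sg.order)
    return BuildTimeline(segments=segments)


def _subset_cells(cells: CellSet, ids: np.ndarray) -> CellSet:
    """Shallow view of a CellSet restricted to the given 1-based cell ids."""
    import copy

    sub = copy.copy(cells)
    sel = np.asarray(ids, dtype=int) - 1
    sub.n_cells = len(sel)
    sub.centroids_mm = cells.centroids_mm[sel]
    sub.volumes_mm3 = cells.volumes_mm3[sel]
    sub.frames = None if cells.frames is None else cells.frames[sel].copy()
    sub.eigenvalues = None if cells.eigenvalues is None else cells.eigenvalues[sel]
    sub.degenerate = None if cells.degenerate is None else cells.degenerate[sel]
    sub.boundary_touch = (
        None if cells.boundary_touch is None else cells.boundary_touch[sel]
    )
    sub.tilt_deg = None
    lut = np.zeros(cells.n_cells + 1, dtype=np.int32)
    for new_id, old in enumerate(sel + 1, start=1):
        lut[old] = new_id
    sub.labels = lut[cells.labels]
    sub.extra = dict(cells.extra)
    sub.extra.pop("_index_groups", None)
    return sub


def timeline_report(timeline: BuildTimeline) -> tuple[pd.DataFrame, str]:
    """Tabular and JSON serializations of a timeline (JSON round-trips)."""
    if len(timeline) == 0:
        raise ValueError("empty timeline")
    rows = []
    for sg in timeline.segments:
        rows.append(
            {
                "order": sg.order,
                "node_span": sg.nodes,
                "build_direction": None
                if sg.build_direction is None
                else [float(x) for x in sg.build_direction],
                "gravity": None if sg.gravity is None else [float(x) for x in sg.gravity],
                "parent": sg.parent,
                "n_cells": sg.n_cells,
                "gravity_inherited": bool(sg.gravity_inherited),
                "sibling_tie": bool(sg.sibling_tie),
                "mean_geodesic_mm": float(sg.mean_geodesic_mm),
            }
        )
    df = pd.DataFrame(rows)
    return df, json.dumps({"segments": rows}, indent=2)
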