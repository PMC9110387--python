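"""Spectral shape analysis: Laplacian eigenbasis, Fiedler segmentation,
isocontour curve skeletons and oriented cross-sections.

The Laplace operator of the comb surface provides a manifold harmonic
basis; its eigenvector with the smallest nonzero eigenvalue — the Fiedler
vector — varies monotonically along the shape's dominant extent and its
level sets slice the comb into approximately planar lobes.  Linking the
centroids of Fiedler isocontours with a minimum spanning tree gives a
curve skeleton of the lobe structure, whose tangents orient cross-section
planes through the comb interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.ndimage import map_coordinates
from scipy.sparse.linalg import eigsh

from .volume_io import DensityVolume, SurfaceMesh

__all__ = [
    "LaplacianOperator",
    "SpectralBasis",
    "CurveSkeleton",
    "SegmentSet",
    "build_laplacian",
    "graph_laplacian_from_edges",
    "eigenbasis",
    "fiedler_segment",
    "curve_skeleton",
    "prune_skeleton",
    "cross_section",
    "prim_mst",
]


@dataclass
class LaplacianOperator:
    """Sparse symmetric PSD Laplacian ``L`` with mass matrix ``M``."""

    L: sparse.csr_matrix
    M: sparse.csr_matrix
    kind: str
    mesh: SurfaceMesh | None = None


@dataclass
class SpectralBasis:
    """The k smallest eigenpairs of a Laplacian, M-orthonormal, ascending."""

    mesh: SurfaceMesh | None
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # (n_vertices, k)

    @property
    def k(self) -> int:
        return len(self.eigenvalues)

    @property
    def fiedler(self) -> np.ndarray:
        """Eigenvector of the smallest nonzero eigenvalue."""
        nonzero = np.flatnonzero(self.eigenvalues > 1e-8 * max(self.eigenvalues[-1], 1.0))
        if len(nonzero) == 0:
            raise ValueError("no nonzero eigenvalue in the basis")
        return self.eigenvectors[:, nonzero[0]]


@dataclass
class CurveSkeleton:
    """Tree of isocontour centroids (mm) with per-node tangents."""

    nodes: np.ndarray  # (n, 3) positions
    fiedler_values: np.ndarray
    edges: np.ndarray  # (n-1, 2) tree edges
    tangents: np.ndarray  # (n, 3) unit

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for a, b in self.edges:
            adj[int(a)].append(int(b))
            adj[int(b)].append(int(a))
        return adj

    def total_length(self) -> float:
        if len(self.edges) == 0:
            return 0.0
        d = self.nodes[self.edges[:, 0]] - self.nodes[self.edges[:, 1]]
        return float(np.linalg.norm(d, axis=1).sum())


@dataclass
class SegmentSet:
    """Vertex partition by Fiedler-value bins with per-segment planes."""

    labels: np.ndarray
    value_ranges: list[tuple[float, float]]
    centroids: np.ndarray  # (n_segments, 3)
    plane_axes: np.ndarray  # (n_segments, 2, 3) orthonormal in-plane vectors
    plane_normals: np.ndarray = field(default=None)

    @property
    def n_segments(self) -> int:
        return len(self.value_ranges)


def _check_manifold_edges(mesh: SurfaceMesh) -> None:
    e = np.vstack(
        [mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]]
    )
    e = np.sort(e, axis=1)
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    bad = uniq[counts > 2]
    if len(bad):
        raise ValueError(f"non-manifold edges (shared by >2 faces): {bad[:10].tolist()}")


def build_laplacian(mesh: SurfaceMesh, kind: str = "cotangent") -> LaplacianOperator:
    """Assemble the mesh Laplacian.

    ``cotangent``: standard cotan weights with a lumped (barycentric)
    mass matrix — the geometric discretization used for harmonic analysis.
    ``graph``: uniform weights ``L = D - A`` with identity mass, retained
    because its spectra have closed forms on simple graphs.
    """
    _check_manifold_edges(mesh)
    n = mesh.n_vertices
    if kind == "graph":
        e = mesh.edges
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        data = -np.ones(len(rows))
        A = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
        deg = -np.asarray(A.sum(axis=1)).ravel()
        L = sparse.diags(deg) + A
        M = sparse.identity(n, format="csr")
        return LaplacianOperator(L=L.tocsr(), M=M, kind=kind, mesh=mesh)
    if kind != "cotangent":
        raise ValueError(f"unknown Laplacian kind {kind!r}")

    v = mesh.vertices
    f = mesh.faces
    iiv = [(0, 1, 2), (1, 2, 0), (2, 0, 1)]
    rows, cols, data = [], [], []
    for a, b, c in iiv:
        # cotangent at corner a weights edge (b, c)
        e1 = v[f[:, b]] - v[f[:, a]]
        e2 = v[f[:, c]] - v[f[:, a]]
        cross = np.linalg.norm(np.cross(e1, e2), axis=1)
        cross = np.maximum(cross, 1e-300)
        cot = (e1 * e2).sum(axis=1) / cross
        w = 0.5 * cot
        rows.extend([f[:, b], f[:, c]])
        cols.extend([f[:, c], f[:, b]])
        data.extend([-w, -w])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    data = np.concatenate(data)
    W = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
    W = 0.5 * (W + W.T)  # exact symmetry despite accumulation order
    diag = -np.asarray(W.sum(axis=1)).ravel()
    L = W + sparse.diags(diag)
    M = sparse.diags(np.maximum(mesh.vertex_areas(), 1e-12)).tocsr()
    return LaplacianOperator(L=L.tocsr(), M=M, kind="cotangent", mesh=mesh)


def graph_laplacian_from_edges(n: int, edges) -> LaplacianOperator:
    """Uniform-weight graph Laplacian ``L = D - A`` for an explicit edge list.

    Useful for graphs that are not triangle meshes (paths, trees), whose
    spectra have closed forms and serve as oracles.
    """
    e = np.asarray(edges, dtype=int).reshape(-1, 2)
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    A = sparse.csr_matrix((-np.ones(len(rows)), (rows, cols)), shape=(n, n))
    deg = -np.asarray(A.sum(axis=1)).ravel()
    L = sparse.diags(deg) + A
    return LaplacianOperator(L=L.tocsr(), M=sparse.identity(n, format="csr"), kind="graph")


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Deterministic sign: first component exceeding tolerance is positive."""
    out = vecs.copy()
    for c in range(out.shape[1]):
        col = out[:, c]
        nz = np.flatnonzero(np.abs(col) > 1e-8 * max(np.abs(col).max(), 1e-30))
        if len(nz) and col[nz[0]] < 0:
            out[:, c] = -col
    return out


def eigenbasis(op: LaplacianOperator, k: int) -> SpectralBasis:
    """k smallest eigenpairs of ``L x = lambda M x``, M-orthonormal.

    Uses dense LAPACK below ~1500 vertices, otherwise shift-invert
    Lanczos anchored slightly below zero (L is PSD, so the factorized
    matrix is definite).
    """
    n = op.L.shape[0]
    if k < 2 or k > n:
        raise ValueError("k must satisfy 2 <= k <= n_vertices")
    if n <= 1500:
        from scipy.linalg import eigh

        Ld = op.L.toarray()
        Md = op.M.toarray()
        vals, vecs = eigh(Ld, Md)
        vals, vecs = vals[:k], vecs[:, :k]
    else:
        try:
            vals, vecs = eigsh(op.L, k=k, M=op.M, sigma=-1e-3, which="LM")
        except Exception as exc:  # pragma: no cover - diagnostic path
            raise RuntimeError(f"sparse eigensolver failed: {exc}") from exc
    order = np.argsort(vals)
    vals = np.maximum(vals[order], 0.0)
    vecs = vecs[:, order]
    vecs = _fix_signs(vecs)
    return SpectralBasis(mesh=op.mesh, eigenvalues=vals, eigenvectors=vecs)


def _segment_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    centroid = points.mean(axis=0)
    centered = points - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axes = vt[:2]
    normal = np.cross(axes[0], axes[1])
    normal /= max(np.linalg.norm(normal), 1e-30)
    return centroid, axes, normal


def fiedler_segment(basis: SpectralBasis, n_segments: int) -> SegmentSet:
    """Partition vertices into equal-mass quantile bins of the Fiedler vector.

    Each bin is a contiguous Fiedler-value range — the "values within a
    small range" selection — and gets a principal plane from the first two
    principal components of its member vertex positions.
    """
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    if basis.k < 2:
        raise ValueError("basis must contain at least 2 eigenvectors")
    fied = basis.fiedler
    qs = np.quantile(fied, np.linspace(0, 1, n_segments + 1))
    labels = np.clip(np.searchsorted(qs, fied, side="right") - 1, 0, n_segments - 1)
    verts = basis.mesh.vertices
    ranges, cents, axes_all, normals = [], [], [], []
    for s in range(n_segments):
        sel = labels == s
        pts = verts[sel]
        if len(pts) == 0:
            ranges.append((float(qs[s]), float(qs[s + 1])))
            cents.append(np.zeros(3))
            axes_all.append(np.zeros((2, 3)))
            normals.append(np.zeros(3))
            continue
        c, ax, nrm = _segment_plane(pts)
        ranges.append((float(qs[s]), float(qs[s + 1])))
        cents.append(c)
        axes_all.append(ax)
        normals.append(nrm)
    return SegmentSet(
        labels=labels,
        value_ranges=ranges,
        centroids=np.asarray(cents),
        plane_axes=np.asarray(axes_all),
        plane_normals=np.asarray(normals),
    )


def prim_mst(points: np.ndarray) -> np.ndarray:
    """Prim's minimum spanning tree on Euclidean distances.

    Ties broken by lowest node index (scan order). Returns (n-1, 2) edges.
    """
    n = len(points)
    if n <= 1:
        return np.zeros((0, 2), dtype=int)
    in_tree = np.zeros(n, dtype=bool)
    best_dist = np.full(n, np.inf)
    best_from = np.full(n, -1, dtype=int)
    in_tree[0] = True
    d0 = np.linalg.norm(points - points[0], axis=1)
    upd = d0 < best_dist
    best_dist[upd] = d0[upd]
    best_from[upd] = 0
    edges = []
    for _ in range(n - 1):
        cand = np.where(~in_tree, best_dist, np.inf)
        j = int(np.argmin(cand))  # argmin takes the lowest index on ties
        edges.append((int(best_from[j]), j))
        in_tree[j] = True
        dj = np.linalg.norm(points - points[j], axis=1)
        upd = (~in_tree) & (dj < best_dist)
        best_dist[upd] = dj[upd]
        best_from[upd] = j
    return np.asarray(edges, dtype=int)


def _isocontour_components(
    mesh: SurfaceMesh, fied: np.ndarray, level: float, min_vertices: int = 3
) -> list[np.ndarray]:
    """Connected components of the Fiedler level set, as crossing points.

    An edge crosses the level when its endpoint values straddle it; two
    crossing edges are connected when they share a triangle. Returns a
    list of (m, 3) arrays of linearly interpolated crossing points.
    """
    f = mesh.faces
    vals = fied
    crossing_edges: dict[tuple[int, int], int] = {}
    pts: list[np.ndarray] = []
    comp_graph_edges: list[tuple[int, int]] = []

    def edge_id(u: int, v: int) -> int | None:
        a, b = (u, v) if u < v else (v, u)
        fa, fb = vals[a], vals[b]
        if not ((fa < level <= fb) or (fb < level <= fa)):
            return None
        key = (a, b)
        if key not in crossing_edges:
            t = (level - fa) / (fb - fa)
            crossing_edges[key] = len(pts)
            pts.append(mesh.vertices[a] + t * (mesh.vertices[b] - mesh.vertices[a]))
        return crossing_edges[key]

    for tri in f:
        ids = []
        for u, v in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            eid = edge_id(int(u), int(v))
            if eid is not None:
                ids.append(eid)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                comp_graph_edges.append((ids[i], ids[j]))

    m = len(pts)
    if m == 0:
        return []
    rows = [e[0] for e in comp_graph_edges] + [e[1] for e in comp_graph_edges]
    cols = [e[1] for e in comp_graph_edges] + [e[0] for e in comp_graph_edges]
    g = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(m, m))
    n_comp, lab = sparse.csgraph.connected_components(g, directed=False)
    P = np.asarray(pts)
    out = []
    for c in range(n_comp):
        comp_pts = P[lab == c]
        if len(comp_pts) >= min_vertices:
            out.append(comp_pts)
    return out


def curve_skeleton(
    basis: SpectralBasis, n_contours: int = 25, scalar_field: np.ndarray | None = None
) -> CurveSkeleton:
    """Curve skeleton from scalar isocontours linked by Prim's MST.

    The driving field defaults to the Fiedler vector, which orders the
    comb along its dominant extent; any per-vertex scalar whose level
    sets sweep the shape (e.g. geodesic distance from the substrate,
    whose fronts split at branch points) can be supplied instead.

    Levels are uniform quantiles of the field; each connected contour
    component contributes one node at its centroid (components with
    fewer than 3 crossing points are dropped). Tangents point along the
    tree: leaves toward their neighbor, path nodes between their two
    neighbors, branch nodes along the principal direction of incident
    edges.
    """
    fied = basis.fiedler if scalar_field is None else np.asarray(scalar_field, float)
    if len(fied) != basis.mesh.n_vertices:
        raise ValueError("scalar field length must match the vertex count")
    levels = np.quantile(fied, np.linspace(0, 1, n_contours + 2)[1:-1])
    nodes = []
    node_vals = []
    for lv in np.unique(levels):
        for comp in _isocontour_components(basis.mesh, fied, float(lv)):
            nodes.append(comp.mean(axis=0))
            node_vals.append(float(lv))
    if not nodes:
        raise ValueError("no isocontour produced any component")
    nodes = np.asarray(nodes)
    node_vals = np.asarray(node_vals)
    edges = prim_mst(nodes)
    tangents = _node_tangents(nodes, edges)
    return CurveSkeleton(nodes=nodes, fiedler_values=node_vals, edges=edges, tangents=tangents)


def _node_tangents(nodes: np.ndarray, edges: np.ndarray) -> np.ndarray:
    n = len(nodes)
    tangents = np.zeros((n, 3))
    adj: list[list[int]] = [[] for _ in range(n)]
    for a, b in edges:
        adj[int(a)].append(int(b))
        adj[int(b)].append(int(a))
    for v in range(n):
        nb = adj[v]
        if len(nb) == 0:
            tangents[v] = np.array([1.0, 0.0, 0.0])
        elif len(nb) == 1:
            d = nodes[nb[0]] - nodes[v]
            tangents[v] = d / max(np.linalg.norm(d), 1e-30)
        elif len(nb) == 2:
            d = nodes[nb[1]] - nodes[nb[0]]
            tangents[v] = d / max(np.linalg.norm(d), 1e-30)
        else:
            dirs = np.array(
                [
                    (nodes[w] - nodes[v]) / max(np.linalg.norm(nodes[w] - nodes[v]), 1e-30)
                    for w in nb
                ]
            )
            _, _, vt = np.linalg.svd(dirs, full_matrices=False)
            tangents[v] = vt[0]
    return tangents


def prune_skeleton(skel: CurveSkeleton, min_branch_nodes: int = 3) -> CurveSkeleton:
    """Remove twig branches shorter than ``min_branch_nodes``.

    A twig is the chain from a leaf up to (not including) the nearest
    node of degree >= 3; twigs with fewer nodes than the threshold are
    contour-noise offshoots and are deleted, iterating until stable.
    """
    nodes = skel.nodes
    vals = skel.fiedler_values
    edges = skel.edges
    while True:
        n = len(nodes)
        adj: list[list[int]] = [[] for _ in range(n)]
        for a, b in edges:
            adj[int(a)].append(int(b))
            adj[int(b)].append(int(a))
        remove = np.zeros(n, dtype=bool)
        for leaf in range(n):
            if len(adj[leaf]) != 1:
                continue
            chain = [leaf]
            prev, cur = leaf, adj[leaf][0]
            while len(adj[cur]) == 2:
                nxt = adj[cur][0] if adj[cur][0] != prev else adj[cur][1]
                chain.append(cur)
                prev, cur = cur, nxt
            if len(adj[cur]) >= 3 and len(chain) < min_branch_nodes:
                remove[chain] = True
        if not remove.any() or remove.all():
            break
        keep = ~remove
        remap = -np.ones(n, dtype=int)
        remap[keep] = np.arange(keep.sum())
        nodes = nodes[keep]
        vals = vals[keep]
        edges = np.asarray(
            [(remap[a], remap[b]) for a, b in edges if keep[a] and keep[b]], dtype=int
        )
    return CurveSkeleton(
        nodes=nodes, fiedler_values=vals, edges=edges, tangents=_node_tangents(nodes, edges)
    )


def cross_section(
    vol: DensityVolume,
    skeleton: CurveSkeleton,
    node: int,
    size_mm: float,
) -> tuple[np.ndarray, bool]:
    """Planar resample of the volume at a skeleton node.

    The plane passes through the node with normal along the node tangent;
    pixel spacing equals the volume spacing (isotropic required). In-plane
    axes are chosen deterministically from the world axis least aligned
    with the normal. Out-of-volume pixels are 0 and flagged by the second
    return value.
    """
    h = vol.require_isotropic("cross_section")
    normal = skeleton.tangents[node]
    if np.linalg.norm(normal) == 0:
        raise ValueError("node has no defined tangent")
    normal = normal / np.linalg.norm(normal)
    axis = int(np.argmin(np.abs(normal)))
    e = np.zeros(3)
    e[axis] = 1.0
    b1 = e - (e @ normal) * normal
    b1 /= np.linalg.norm(b1)
    b2 = np.cross(normal, b1)
    half = size_mm / 2.0
    coords_1d = np.arange(-half, half + 1e-9, h)
    U, V = np.meshgrid(coords_1d, coords_1d, indexing="ij")
    pts = (
        skeleton.nodes[node][None, None, :]
        + U[..., None] * b1[None, None, :]
        + V[..., None] * b2[None, None, :]
    )
    idx = (pts - np.asarray(vol.origin_mm)) / np.asarray(vol.spacing_mm)
    dims = np.asarray(vol.values.shape)
    inside = np.all((idx >= 0) & (idx <= dims - 1), axis=-1)
    sample = map_coordinates(
        vol.values, [idx[..., 0], idx[..., 1], idx[..., 2]], order=1, mode="constant", cval=0.0
    )
    sample[~inside] = 0.0
    return sample, bool((~inside).any())
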