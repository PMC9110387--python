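"""Bee-scale curvature estimation by local quadric fitting.

At every mesh vertex the surrounding surface patch — the geodesic ball of
a given radius, by default 15 mm, roughly the reach of a worker bee
sensing her surroundings — is expressed in a local tangent frame and fit
with the quadric ``z = a x^2 + b y^2 + c xy + d x + e y`` (no constant
term: the patch passes through the vertex).  Principal curvatures are the
eigenvalues of the shape operator of this Monge patch at the origin;
Gaussian curvature is their product, mean curvature their average.

The local frame's z axis points along the *inward* surface normal, so a
convex solid (e.g. a ball) has positive principal curvatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .volume_io import SurfaceMesh

__all__ = [
    "CurvatureField",
    "DegenerateFitError",
    "fit_local_quadric",
    "curvature_from_quadric",
    "compute_curvature_field",
    "curvature_histogram",
]

#: Condition-number threshold above which a neighborhood is degenerate.
DEGENERATE_COND = 1e8


class DegenerateFitError(ValueError):
    """Raised when a vertex neighborhood cannot support a quadric fit."""


@dataclass
class CurvatureField:
    """Per-vertex principal/Gaussian/mean curvature channels (1/mm)."""

    mesh: SurfaceMesh
    kappa1: np.ndarray
    kappa2: np.ndarray
    gaussian_K: np.ndarray
    mean_H: np.ndarray
    sample_radius_mm: float
    qc_degenerate: np.ndarray = field(default=None)

    def channel(self, name: str) -> np.ndarray:
        return {
            "kappa1": self.kappa1,
            "kappa2": self.kappa2,
            "K": self.gaussian_K,
            "H": self.mean_H,
        }[name]


def _edge_length_graph(mesh: SurfaceMesh) -> csr_matrix:
    e = mesh.edges
    lengths = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    n = mesh.n_vertices
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    data = np.concatenate([lengths, lengths])
    return csr_matrix((data, (rows, cols)), shape=(n, n))


def _tangent_frame(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal tangent pair for a unit normal.

    The first tangent is the world axis least aligned with the normal,
    projected into the tangent plane, so near-planar patches get frames
    aligned with world coordinates.
    """
    ref = np.zeros(3)
    ref[int(np.argmin(np.abs(normal)))] = 1.0
    t1 = ref - (ref @ normal) * normal
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(normal, t1)
    return t1, t2


def _fit_quadric_local(xy: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Least-squares (a, b, c, d, e) for z = ax^2+by^2+cxy+dx+ey."""
    x, y = xy[:, 0], xy[:, 1]
    A = np.column_stack([x * x, y * y, x * y, x, y])
    if len(z) < 6:
        raise DegenerateFitError("need at least 6 neighbors within the sampling radius")
    # normal equations with explicit conditioning check
    s = np.linalg.svd(A, compute_uv=False)
    if s[0] <= 0 or s[-1] == 0 or s[0] / max(s[-1], 1e-300) > DEGENERATE_COND:
        raise DegenerateFitError("rank-deficient neighborhood (collinear samples)")
    coef, *_ = np.linalg.lstsq(A, z, rcond=None)
    return coef


def fit_local_quadric(
    mesh: SurfaceMesh,
    vertex: int,
    radius_mm: float,
    normal: np.ndarray | None = None,
    graph: csr_matrix | None = None,
) -> tuple[float, float, float, float, float]:
    """Fit the local quadric at one vertex over its mesh-geodesic ball.

    The neighborhood is gathered by shortest edge paths (breadth-first
    with accumulated edge length), not a Euclidean ball, so the opposite
    comb sheet a few millimetres away through air is never captured.
    """
    if graph is None:
        graph = _edge_length_graph(mesh)
    dist = dijkstra(graph, indices=vertex, limit=radius_mm)
    nbrs = np.flatnonzero(np.isfinite(dist))
    nbrs = nbrs[nbrs != vertex]
    if len(nbrs) < 6:
        raise DegenerateFitError("need at least 6 neighbors within the sampling radius")
    if normal is None:
        normal = mesh.vertex_normals()[vertex]
    n_in = -np.asarray(normal, dtype=float)  # frame z along inward normal
    n_in = n_in / np.linalg.norm(n_in)
    t1, t2 = _tangent_frame(n_in)
    rel = mesh.vertices[nbrs] - mesh.vertices[vertex]
    xy = np.column_stack([rel @ t1, rel @ t2])
    z = rel @ n_in
    a, b, c, d, e = _fit_quadric_local(xy, z)
    return float(a), float(b), float(c), float(d), float(e)


def curvature_from_quadric(
    a: float, b: float, c: float, d: float, e: float
) -> tuple[float, float, float, float]:
    """Principal, Gaussian and mean curvature of the Monge patch at the origin.

    First fundamental form from the gradient (d, e); second fundamental
    form from the Hessian (2a, c; c, 2b) divided by sqrt(1+d^2+e^2).
    Returns ``(kappa1, kappa2, K, H)`` with ``kappa1 >= kappa2``,
    ``K = kappa1*kappa2`` and ``H = (kappa1+kappa2)/2`` exactly.
    """
    E = 1.0 + d * d
    F = d * e
    G = 1.0 + e * e
    w = np.sqrt(1.0 + d * d + e * e)
    L = 2.0 * a / w
    M = c / w
    N = 2.0 * b / w
    det_I = E * G - F * F
    K = (L * N - M * M) / det_I
    H = (E * N - 2.0 * F * M + G * L) / (2.0 * det_I)
    disc = max(H * H - K, 0.0)
    root = np.sqrt(disc)
    k1 = H + root
    k2 = H - root
    return float(k1), float(k2), float(k1 * k2), float(0.5 * (k1 + k2))


def _neighbor_lists(mesh: SurfaceMesh) -> list[np.ndarray]:
    n = mesh.n_vertices
    e = mesh.edges
    adj: list[list[int]] = [[] for _ in range(n)]
    for u, v in e:
        adj[u].append(v)
        adj[v].append(u)
    return [np.asarray(a, dtype=np.int64) for a in adj]


def compute_curvature_field(
    mesh: SurfaceMesh,
    radius_mm: float = 15.0,
    smoothing_rounds: int = 2,
    batch_size: int = 256,
) -> CurvatureField:
    """Quadric-fit curvatures at every vertex, then locally average.

    Smoothing replaces each vertex value by the mean over itself and its
    one-ring, repeated ``smoothing_rounds`` times. Vertices whose fit is
    degenerate inherit the nearest valid value and are flagged in the
    ``qc_degenerate`` channel. Channels are also written onto
    ``mesh.attributes``.
    """
    n = mesh.n_vertices
    graph = _edge_length_graph(mesh)
    mean_edge = graph.data.mean() if graph.nnz else 0.0
    if radius_mm < 3.0 * mean_edge:
        raise ValueError(
            f"sampling radius {radius_mm} mm must be at least 3x the mean edge "
            f"length ({mean_edge:.3f} mm)"
        )
    normals = mesh.vertex_normals()
    k1 = np.zeros(n)
    k2 = np.zeros(n)
    degen = np.zeros(n, dtype=bool)
    verts = mesh.vertices
    for start in range(0, n, batch_size):
        idx = np.arange(start, min(start + batch_size, n))
        dist = dijkstra(graph, indices=idx, limit=radius_mm)
        for row, v in enumerate(idx):
            nbrs = np.flatnonzero(np.isfinite(dist[row]))
            nbrs = nbrs[nbrs != v]
            if len(nbrs) < 6:
                degen[v] = True
                continue
            n_in = -normals[v]
            t1, t2 = _tangent_frame(n_in)
            rel = verts[nbrs] - verts[v]
            xy = np.column_stack([rel @ t1, rel @ t2])
            z = rel @ n_in
            try:
                a, b, c, d, e = _fit_quadric_local(xy, z)
            except DegenerateFitError:
                degen[v] = True
                continue
            k1[v], k2[v], _, _ = curvature_from_quadric(a, b, c, d, e)

    if degen.any():
        if degen.all():
            raise DegenerateFitError("every vertex neighborhood is degenerate")
        # inherit the nearest valid value, filling outward from valid vertices
        valid = ~degen
        dist_to_valid = dijkstra(graph, indices=np.flatnonzero(valid), min_only=True)
        adj = _neighbor_lists(mesh)
        filled = valid.copy()
        for v in np.argsort(dist_to_valid):
            if filled[v]:
                continue
            nb = adj[v]
            good = nb[filled[nb]] if len(nb) else np.array([], dtype=int)
            if len(good):
                k1[v] = k1[good].mean()
                k2[v] = k2[good].mean()
                filled[v] = True

    adj = _neighbor_lists(mesh)
    for _ in range(max(0, int(smoothing_rounds))):
        k1_new = k1.copy()
        k2_new = k2.copy()
        for v in range(n):
            nb = adj[v]
            if len(nb):
                k1_new[v] = (k1[v] + k1[nb].sum()) / (1 + len(nb))
                k2_new[v] = (k2[v] + k2[nb].sum()) / (1 + len(nb))
        k1, k2 = k1_new, k2_new

    hi = np.maximum(k1, k2)
    lo = np.minimum(k1, k2)
    K = hi * lo
    H = 0.5 * (hi + lo)
    field = CurvatureField(
        mesh=mesh,
        kappa1=hi,
        kappa2=lo,
        gaussian_K=K,
        mean_H=H,
        sample_radius_mm=radius_mm,
        qc_degenerate=degen,
    )
    mesh.attributes["kappa1"] = hi
    mesh.attributes["kappa2"] = lo
    mesh.attributes["gaussian_K"] = K
    mesh.attributes["mean_H"] = H
    mesh.attributes["curvature_qc"] = degen.astype(float)
    return field


def curvature_histogram(
    field: CurvatureField, channel: str = "kappa1", bins: int = 50
) -> pd.DataFrame:
    """Area-weighted histogram of a curvature channel.

    Each vertex is weighted by one third of its incident triangle area, so
    ``area_fraction`` sums to 1 and reflects surface coverage rather than
    tessellation density. Columns: bin_lo, bin_hi, count, area_fraction.
    """
    values = field.channel(channel)
    if values.size == 0:
        raise ValueError("empty curvature field")
    weights = field.mesh.vertex_areas()
    lo, hi = float(values.min()), float(values.max())
    if hi - lo <= 0:
        edges = np.array([lo - 0.5, lo + 0.5]) if bins == 1 else np.linspace(
            lo - 0.5, lo + 0.5, bins + 1
        )
    else:
        edges = np.linspace(lo, hi, bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    wsum, _ = np.histogram(values, bins=edges, weights=weights)
    total = weights.sum()
    return pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "count": counts,
            "area_fraction": wsum / total if total > 0 else wsum,
        }
    )
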