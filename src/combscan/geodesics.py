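"""Density-weighted geodesic distance on voxel grids.

Travel cost ``u`` away from a source set solves the eikonal equation
``|grad u(x)| = 1 / s(x)`` where ``s`` is a local speed field.  Following
how a bee experiences the hive — movement restricted to comb material —
the speed is the normalized density value, so distances accumulate only
through built material and ``u`` is the weighted geodesic distance from
the source (in mm when ``s == 1``).

The solver is a fast-marching method on the 6-neighborhood with the
upwind quadratic update, promoted to second-order differences where two
upwind values are available; voxels outside the domain mask never become
finite.  The gradient of ``u`` yields shortest paths back to
the source, and the average *direction* of the gradient over a comb
region is the region's build direction (construction proceeds along
increasing distance from the founding substrate).
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass

import numpy as np

from .volume_io import DensityVolume, SignedDistanceVolume

__all__ = [
    "GeodesicField",
    "BuildDirectionReport",
    "solve_eikonal",
    "gradient_field",
    "trace_path",
    "path_length_mm",
    "build_direction",
]

#: Lower clamp for the speed metric: density can vanish in pores, but the
#: eikonal speed must stay positive for the solve to terminate.
SPEED_FLOOR = 1e-3


@dataclass
class GeodesicField:
    """Solved travel-cost field ``u`` with its domain, metric and sources."""

    u: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]
    source_mask: np.ndarray
    metric_s: np.ndarray
    domain_mask: np.ndarray

    @property
    def n_unreached(self) -> int:
        """Domain voxels the front never reached (u = +inf)."""
        return int((~np.isfinite(self.u) & self.domain_mask).sum())

    def index_to_world(self, idx) -> np.ndarray:
        return np.asarray(self.origin_mm) + np.asarray(idx, dtype=float) * np.asarray(
            self.spacing_mm
        )


@dataclass
class BuildDirectionReport:
    """Mean growth direction of a comb region with its angular dispersion."""

    region_id: object
    mean_gradient: np.ndarray
    dispersion: float

    def to_dict(self) -> dict:
        return {
            "region": self.region_id,
            "mean_gradient": [float(x) for x in self.mean_gradient],
            "dispersion": float(self.dispersion),
        }


def _eikonal_update(ax_terms: list[tuple[float, float]], rhs: float) -> float:
    """Upwind quadratic solve for one voxel.

    Each axis contributes a term ``c * (u - t)^2``; first-order axes have
    ``(t, c) = (u1, 1)`` and second-order axes ``((4 u1 - u2)/3, 9/4)``.
    Solves ``sum c_i (u - t_i)^2 = rhs^2`` over the causal subset.
    """
    terms = sorted(ax_terms)
    m = len(terms)
    while m > 0:
        A = 0.0
        B = 0.0
        C = -rhs * rhs
        for t, c in terms[:m]:
            A += c
            B += c * t
            C += c * t * t
        disc = B * B - A * C
        if disc >= 0.0:
            u = (B + disc ** 0.5) / A
            if m == 1 or u >= terms[m - 1][0]:
                return u
        m -= 1
    return terms[0][0] + rhs  # unreachable in practice


def solve_eikonal(
    domain: SignedDistanceVolume | DensityVolume,
    source: np.ndarray,
    metric: np.ndarray | float = 1.0,
    domain_mask: np.ndarray | None = None,
    iso_threshold: float | None = None,
) -> GeodesicField:
    """Fast marching of ``|grad u| = 1/s`` from a source set.

    Parameters
    ----------
    domain
        A signed distance volume (domain = inside voxels) or a density
        volume (domain = values >= ``iso_threshold``, default the volume's
        0.5); overridden by an explicit ``domain_mask``.
    source
        Boolean mask of source voxels; must be non-empty and intersect
        the domain. ``u`` is exactly 0 there.
    metric
        Per-voxel speed field or a constant. Values are clamped to
        ``[1e-3, inf)``; pass the density volume's values for the
        density-weighted distance.

    Voxels the front cannot reach keep ``u = +inf`` and are counted in
    :attr:`GeodesicField.n_unreached`.
    """
    if isinstance(domain, SignedDistanceVolume):
        h = domain.require_isotropic("solve_eikonal")
        mask = domain.solid_mask if domain_mask is None else np.asarray(domain_mask, bool)
    else:
        h = domain.require_isotropic("solve_eikonal")
        if domain_mask is None:
            thr = 0.5 if iso_threshold is None else iso_threshold
            mask = domain.values >= thr
        else:
            mask = np.asarray(domain_mask, bool)
    shape = mask.shape
    source = np.asarray(source, dtype=bool)
    if source.shape != shape:
        raise ValueError("source mask shape mismatch")
    src_in = source & mask
    if not src_in.any():
        raise ValueError("empty source: no source voxel lies inside the domain")

    if np.isscalar(metric):
        s = np.full(shape, float(metric))
    else:
        s = np.asarray(metric, dtype=float)
        if s.shape != shape:
            raise ValueError("metric shape mismatch")
    s = np.clip(s, SPEED_FLOOR, None)

    u = np.full(shape, np.inf)
    state = np.zeros(shape, dtype=np.int8)  # 0 far, 1 trial, 2 frozen
    u[src_in] = 0.0

    nx, ny, nz = shape
    syz = ny * nz
    u_flat = u.ravel()
    mask_flat = mask.ravel()
    state_flat = state.ravel()
    rhs_flat = (h / s).ravel()

    heap: list[tuple[float, int]] = [(0.0, int(i)) for i in np.flatnonzero(src_in.ravel())]
    heapq.heapify(heap)

    axis_off = (syz, nz, 1)
    axis_dim = (nx, ny, nz)

    def axis_term(flat: int, pos: tuple, axis: int):
        """Best upwind (t, c) term along one axis, second-order when the
        next voxel out is also frozen with a smaller value."""
        off = axis_off[axis]
        p = pos[axis]
        dim = axis_dim[axis]
        best = np.inf
        side = 0
        if p > 0 and state_flat[flat - off] == 2:
            best = u_flat[flat - off]
            side = -1
        if p < dim - 1 and state_flat[flat + off] == 2 and u_flat[flat + off] < best:
            best = u_flat[flat + off]
            side = 1
        if side == 0:
            return None
        p2 = p + 2 * side
        if 0 <= p2 < dim:
            f2 = flat + 2 * side * off
            if state_flat[f2] == 2 and u_flat[f2] <= best:
                return ((4.0 * best - u_flat[f2]) / 3.0, 2.25)
        return (best, 1.0)

    offsets = (syz, -syz, nz, -nz, 1, -1)
    while heap:
        uv, flat = heapq.heappop(heap)
        if state_flat[flat] == 2 or uv > u_flat[flat]:
            continue
        state_flat[flat] = 2
        i, rem = divmod(flat, syz)
        j, k = divmod(rem, nz)
        for off in offsets:
            if off == syz and i == nx - 1:
                continue
            if off == -syz and i == 0:
                continue
            if off == nz and j == ny - 1:
                continue
            if off == -nz and j == 0:
                continue
            if off == 1 and k == nz - 1:
                continue
            if off == -1 and k == 0:
                continue
            nb = flat + off
            if not mask_flat[nb] or state_flat[nb] == 2:
                continue
            ni, nrem = divmod(nb, syz)
            nj, nk = divmod(nrem, nz)
            npos = (ni, nj, nk)
            terms = []
            for ax in range(3):
                t = axis_term(nb, npos, ax)
                if t is not None:
                    terms.append(t)
            if not terms:
                continue
            new_u = _eikonal_update(terms, rhs_flat[nb])
            if new_u < u_flat[nb]:
                u_flat[nb] = new_u
                state_flat[nb] = 1
                heapq.heappush(heap, (new_u, int(nb)))

    u = u_flat.reshape(shape)
    spacing = (
        domain.spacing_mm if isinstance(domain.spacing_mm, tuple) else tuple(domain.spacing_mm)
    )
    return GeodesicField(
        u=u,
        spacing_mm=spacing,
        origin_mm=tuple(domain.origin_mm),
        source_mask=src_in,
        metric_s=s,
        domain_mask=mask,
    )


def gradient_field(field: GeodesicField, normalize: bool = True) -> np.ndarray:
    """Finite-difference gradient of ``u``: central where both neighbors are
    finite, one-sided at the domain boundary, unit-normalized by default.

    Isolated finite voxels with no finite neighbor along any axis get the
    zero vector (they are also flagged by a zero norm).
    """
    u = field.u
    g = np.zeros(u.shape + (3,))
    finite = np.isfinite(u)
    for ax in range(3):
        h = field.spacing_mm[ax]
        fwd = np.roll(u, -1, axis=ax)
        bwd = np.roll(u, 1, axis=ax)
        f_ok = np.roll(finite, -1, axis=ax)
        b_ok = np.roll(finite, 1, axis=ax)
        # forbid wrap-around
        edge_hi = [slice(None)] * 3
        edge_hi[ax] = -1
        edge_lo = [slice(None)] * 3
        edge_lo[ax] = 0
        f_ok[tuple(edge_hi)] = False
        b_ok[tuple(edge_lo)] = False
        comp = np.zeros_like(u)
        both = finite & f_ok & b_ok
        comp[both] = (fwd[both] - bwd[both]) / (2 * h)
        fonly = finite & f_ok & ~b_ok
        comp[fonly] = (fwd[fonly] - u[fonly]) / h
        bonly = finite & ~f_ok & b_ok
        comp[bonly] = (u[bonly] - bwd[bonly]) / h
        g[..., ax] = comp
    if normalize:
        norm = np.linalg.norm(g, axis=-1)
        nz = norm > 0
        g[nz] /= norm[nz][..., None]
    return g


def trace_path(
    field: GeodesicField, start, max_steps: int = 100000
) -> np.ndarray:
    """Steepest-descent polyline (world mm) from a voxel back to the source.

    Descends through successively lower-``u`` neighbors (26-connectivity);
    when no lower neighbor exists off-source the path is truncated with a
    warning. Returns an (n, 3) array of points; a start on the source gives
    a single-point path.
    """
    start = tuple(int(x) for x in start)
    u = field.u
    if not np.isfinite(u[start]):
        raise ValueError("start voxel has infinite travel cost")
    shape = u.shape
    cur = start
    path_idx = [cur]
    for _ in range(max_steps):
        if field.source_mask[cur]:
            break
        best = None
        best_u = u[cur]
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    if di == dj == dk == 0:
                        continue
                    ni, nj, nk = cur[0] + di, cur[1] + dj, cur[2] + dk
                    if not (0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]):
                        continue
                    val = u[ni, nj, nk]
                    if np.isfinite(val) and val < best_u:
                        best_u = val
                        best = (ni, nj, nk)
        if best is None:
            warnings.warn("gradient stagnation: path truncated before reaching the source")
            break
        cur = best
        path_idx.append(cur)
    pts = np.asarray(
        [field.index_to_world(idx) for idx in path_idx], dtype=float
    ).reshape(-1, 3)
    return pts


def path_length_mm(path: np.ndarray) -> float:
    if len(path) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(path, axis=0), axis=1).sum())


def build_direction(
    field: GeodesicField, region: np.ndarray, region_id=0, min_voxels: int = 50
) -> BuildDirectionReport:
    """Average unit gradient of the travel-cost field over a comb region.

    The mean of per-voxel unit gradients is re-normalized to give the
    region's build direction; dispersion = 1 - |mean resultant| is 0 for
    perfectly aligned growth and approaches 1 for isotropic growth.
    """
    region = np.asarray(region, dtype=bool)
    sel = region & field.domain_mask & np.isfinite(field.u)
    n = int(sel.sum())
    if n == 0:
        raise ValueError("region has no finite travel cost")
    if n < min_voxels:
        raise ValueError(f"region too small: {n} voxels with finite u (need {min_voxels})")
    g = gradient_field(field, normalize=True)[sel]
    norms = np.linalg.norm(g, axis=1)
    g = g[norms > 0]
    if len(g) == 0:
        raise ValueError("region gradients all vanish")
    mean = g.mean(axis=0)
    resultant = np.linalg.norm(mean)
    direction = mean / resultant if resultant > 0 else mean
    return BuildDirectionReport(
        region_id=region_id,
        mean_gradient=direction,
        dispersion=float(1.0 - resultant),
    )
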