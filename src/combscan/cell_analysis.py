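"""Individual cell extraction, orientation frames, tilt and gravity.

The negative space of a comb section — the open cell interiors — is the
Boolean difference between the section's morphological closure (a 10-mm
ball caps the open cell mouths) and the section itself.  Iterative
morphological opening with a growing radius then severs any residual
thin connections until the connected-component count stabilizes, leaving
one component per cell.

Per-cell principal-component frames recover each cell's long axis.  Honey
bees build cells tilted upward, against gravity, from the comb's median
plane (the interface where the two mirrored cell sheets meet), canonically
by about 13 degrees; the common in-plane direction of the cell axes
therefore points opposite gravity, letting the gravity direction at build
time be reconstructed from geometry alone.

Tilt convention: ``tilt_deg`` is the angle between a cell's principal
axis and the *normal* of the median plane (equivalently 90 degrees minus
the angle to the plane itself), so a canonical comb reads ~13 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import morphology
from .volume_io import SignedDistanceVolume, signed_distance_from_mask

__all__ = [
    "CellSet",
    "MedianPlane",
    "extract_cells",
    "cell_frames",
    "median_plane",
    "tilt_and_gravity",
    "cell_metrics",
]

_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass
class MedianPlane:
    """The comb interface plane: a point and a unit normal (mm)."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        self.normal = n / np.linalg.norm(n)

    def signed_distance(self, pts: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(pts) - self.point) @ self.normal


@dataclass
class CellSet:
    """Labeled cell interiors with per-cell geometry.

    ``labels`` is 0 for background and 1..N for 6-connected cell
    components; frames are orthonormal with axes ordered by descending
    variance.
    """

    labels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]
    n_cells: int
    centroids_mm: np.ndarray = None  # (N, 3)
    volumes_mm3: np.ndarray = None  # (N,)
    frames: np.ndarray = None  # (N, 3, 3) rows = axes
    eigenvalues: np.ndarray = None  # (N, 3)
    degenerate: np.ndarray = None  # (N,) bool
    boundary_touch: np.ndarray = None  # (N,) bool
    tilt_deg: np.ndarray = None
    depth_mm: np.ndarray = None
    width_mm: np.ndarray = None
    opening_radius_mm: float = 0.0
    extra: dict = field(default_factory=dict)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def cell_indices(self, cell_id: int) -> np.ndarray:
        groups = self.extra.get("_index_groups")
        if groups is None:
            idx = np.argwhere(self.labels > 0)
            lab = self.labels[idx[:, 0], idx[:, 1], idx[:, 2]]
            order = np.argsort(lab, kind="stable")
            idx = idx[order]
            lab = lab[order]
            bounds = np.searchsorted(lab, np.arange(1, self.n_cells + 2))
            groups = {
                cid: idx[bounds[cid - 1] : bounds[cid]] for cid in range(1, self.n_cells + 1)
            }
            self.extra["_index_groups"] = groups
        return groups[cell_id]

    def cell_points_mm(self, cell_id: int) -> np.ndarray:
        idx = self.cell_indices(cell_id)
        return np.asarray(self.origin_mm) + idx * np.asarray(self.spacing_mm)


def _count_components(mask: np.ndarray) -> int:
    _, n = ndimage.label(mask, structure=_STRUCT6)
    return n


def extract_cells(
    section: SignedDistanceVolume,
    closure_radius_mm: float = 10.0,
    opening_step_mm: float | None = None,
    min_voxels: int = 20,
    max_opening_mm: float | None = None,
) -> CellSet:
    """Isolate cell interiors by closure difference and iterative opening.

    ``negative space = close(section, closure_radius) - section``; the
    opening radius then grows from one voxel in one-voxel steps (or
    ``opening_step_mm``) until the 6-connected component count is
    unchanged for two consecutive radii. Components smaller than
    ``min_voxels`` are discarded as voxelization slivers.
    """
    h = section.require_isotropic("extract_cells")
    step = h if opening_step_mm is None else float(opening_step_mm)
    solid = section.solid_mask
    closed_mask = morphology.close_mask(solid, closure_radius_mm, h)
    neg_mask = closed_mask & ~solid
    if not neg_mask.any():
        raise ValueError("no negative space: the section contains no open cells")

    if max_opening_mm is None:
        max_opening_mm = closure_radius_mm
    opened_counts: list[int] = []
    opened = neg_mask
    radius = 0.0
    r = step
    while r <= max_opening_mm:
        cand = morphology.open_mask(neg_mask, r, h)
        if not cand.any():
            raise ValueError(
                f"opening annihilated all negative space at radius {r:.3f} mm "
                f"(last non-empty radius {radius:.3f} mm)"
            )
        n = _count_components(cand)
        opened = cand
        radius = r
        opened_counts.append(n)
        # stop once the count is unchanged for two consecutive radii
        if len(opened_counts) >= 2 and opened_counts[-1] == opened_counts[-2]:
            break
        r += step

    labels, n_raw = ndimage.label(opened, structure=_STRUCT6)
    counts = np.bincount(labels.ravel())
    keep = [i for i in range(1, n_raw + 1) if counts[i] >= min_voxels]
    lut = np.zeros(n_raw + 1, dtype=np.int32)
    for new_id, old_id in enumerate(keep, start=1):
        lut[old_id] = new_id
    relabeled = lut[labels]
    n_cells = len(keep)

    cs = CellSet(
        labels=relabeled,
        spacing_mm=tuple(section.spacing_mm),
        origin_mm=tuple(section.origin_mm),
        n_cells=n_cells,
        opening_radius_mm=radius,
    )
    cs.extra["closed_sdf"] = signed_distance_from_mask(
        closed_mask, section.spacing_mm, section.origin_mm, section.iso_threshold
    )
    _basic_metrics(cs)
    return cs


def _basic_metrics(cs: CellSet) -> None:
    vox = cs.voxel_volume_mm3
    cents = []
    vols = []
    touch = []
    dims = np.asarray(cs.labels.shape)
    slices = ndimage.find_objects(cs.labels)
    for cid in range(1, cs.n_cells + 1):
        idx = cs.cell_indices(cid)
        cents.append(np.asarray(cs.origin_mm) + idx.mean(axis=0) * np.asarray(cs.spacing_mm))
        vols.append(len(idx) * vox)
        sl = slices[cid - 1]
        touches = any(s.start == 0 or s.stop == d for s, d in zip(sl, dims))
        touch.append(touches)
    cs.centroids_mm = np.asarray(cents).reshape(-1, 3)
    cs.volumes_mm3 = np.asarray(vols)
    cs.boundary_touch = np.asarray(touch, dtype=bool)


def cell_frames(
    cells: CellSet, min_voxels: int = 20, degeneracy_ratio: float = 1.2
) -> CellSet:
    """Populate per-cell orthonormal PCA frames (axes by descending variance).

    A cell whose two largest covariance eigenvalues differ by less than
    ``degeneracy_ratio`` (e.g. a near-spherical blob) is flagged
    degenerate; its frame is still orthonormal but its principal axis is
    not meaningful.
    """
    n = cells.n_cells
    frames = np.zeros((n, 3, 3))
    eigvals = np.zeros((n, 3))
    degen = np.zeros(n, dtype=bool)
    for cid in range(1, n + 1):
        pts = cells.cell_points_mm(cid)
        if len(pts) < min_voxels:
            raise ValueError(f"cell {cid} has fewer than {min_voxels} voxels")
        c = pts.mean(axis=0)
        cov = np.cov((pts - c).T)
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w = w[order]
        v = v[:, order]
        frames[cid - 1] = v.T  # rows are axes
        eigvals[cid - 1] = w
        if w[1] <= 0 or w[0] / max(w[1], 1e-30) < degeneracy_ratio:
            degen[cid - 1] = True
    cells.frames = frames
    cells.eigenvalues = eigvals
    cells.degenerate = degen
    return cells


def median_plane(
    section_or_cells: SignedDistanceVolume | CellSet,
    cells: CellSet | None = None,
) -> MedianPlane:
    """Least-squares plane through the cell base points.

    Each cell's base is the deep end of its long (principal) axis: of the
    two extreme ends of the cell along that axis, the one lying farther
    inside the *closed* comb (the end away from the opening). For a
    double-sided section the bases of the mirrored sheets bracket the
    interface symmetrically, so the fitted plane approximates it.
    """
    import warnings

    if isinstance(section_or_cells, CellSet):
        cs = section_or_cells
        closed = cs.extra.get("closed_sdf")
    else:
        if cells is None:
            cells = extract_cells(section_or_cells)
        cs = cells
        closed = cs.extra.get("closed_sdf")
    if closed is None:
        raise ValueError("CellSet lacks the closed-comb SDF needed for base points")
    if cs.frames is None:
        cell_frames(cs)

    base_pts = []
    for cid in range(1, cs.n_cells + 1):
        idx = cs.cell_indices(cid)
        pts = np.asarray(cs.origin_mm) + idx * np.asarray(cs.spacing_mm)
        axis = cs.frames[cid - 1, 0]
        proj = (pts - cs.centroids_mm[cid - 1]) @ axis
        d = closed.distances[idx[:, 0], idx[:, 1], idx[:, 2]]
        lo_band = proj <= np.quantile(proj, 0.05)
        hi_band = proj >= np.quantile(proj, 0.95)
        # the base end sits deeper inside the closed comb than the opening
        if d[lo_band].mean() < d[hi_band].mean():
            base_pts.append(pts[lo_band].mean(axis=0))
        else:
            base_pts.append(pts[hi_band].mean(axis=0))
    base_pts = np.asarray(base_pts)
    if len(base_pts) < 3:
        raise ValueError("need at least 3 cells to fit a median plane")
    centroid = base_pts.mean(axis=0)
    _, s, vt = np.linalg.svd(base_pts - centroid, full_matrices=False)
    if s[1] < 1e-9:
        warnings.warn("cell bases are nearly collinear; median plane poorly determined")
    normal = vt[2]
    return MedianPlane(point=centroid, normal=normal)


def _orient_frames(cells: CellSet, plane: MedianPlane) -> None:
    """Flip principal axes to point away from the median plane."""
    side = plane.signed_distance(cells.centroids_mm)
    for i in range(cells.n_cells):
        axis = cells.frames[i, 0]
        want = np.sign(side[i]) if side[i] != 0 else 1.0
        if np.sign(axis @ plane.normal) != want:
            cells.frames[i, 0] = -axis
        # keep the frame right-handed
        cells.frames[i, 2] = np.cross(cells.frames[i, 0], cells.frames[i, 1])


def tilt_and_gravity(
    cells: CellSet,
    plane: MedianPlane,
    min_cells: int = 5,
    min_projection: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell tilt angles and the reconstructed gravity direction.

    Tilt is the angle between a cell's principal axis and the median-plane
    normal. Gravity is minus the robust mean (componentwise median,
    re-normalized) of the unit projections of the principal axes onto the
    plane: cells tilt upward, so their in-plane components point against
    gravity. Cells flagged degenerate or touching the volume boundary are
    excluded. Raises when the projections are too small to resolve (cells
    effectively perpendicular to the plane).
    """
    if cells.frames is None:
        cell_frames(cells)
    _orient_frames(cells, plane)
    valid = ~cells.degenerate & ~cells.boundary_touch
    if valid.sum() < min_cells:
        valid = ~cells.degenerate  # fall back if clipping removed too many
    if valid.sum() < min_cells:
        raise ValueError(f"need at least {min_cells} cells with valid frames")

    n = plane.normal
    axes = cells.frames[:, 0, :]
    cosang = np.clip(np.abs(axes @ n), -1.0, 1.0)
    tilt = np.degrees(np.arccos(cosang))
    cells.tilt_deg = tilt

    proj = axes - np.outer(axes @ n, n)
    norms = np.linalg.norm(proj, axis=1)
    if np.median(norms[valid]) < min_projection:
        raise ValueError("tilt unresolvable: cell axes are perpendicular to the plane")
    unit_proj = proj[valid & (norms > 1e-12)] / norms[valid & (norms > 1e-12)][:, None]
    med = np.median(unit_proj, axis=0)
    if np.linalg.norm(med) < 1e-12:
        raise ValueError("tilt unresolvable: in-plane components cancel")
    gravity = -med / np.linalg.norm(med)
    return tilt, gravity


def cell_metrics(cells: CellSet, plane: MedianPlane | None = None) -> pd.DataFrame:
    """Per-cell morphometrics table: id, width, depth, volume, tilt.

    Depth is the caliper extent along the principal axis plus one voxel
    (voxel centers to voxel extents). Width is the *minimal* caliper
    extent over in-plane directions of the minor-axis plane — for a
    hexagonal cell that is the flat-to-flat width, the quantity measured
    with calipers in the field (the PCA minor axes themselves are
    arbitrary under the hexagon's six-fold symmetry). Tilt requires a
    median plane.
    """
    if cells.frames is None:
        cell_frames(cells)
    if plane is not None and cells.tilt_deg is None:
        tilt_and_gravity(cells, plane)
    h = cells.spacing_mm[0]
    depth = np.zeros(cells.n_cells)
    width = np.zeros(cells.n_cells)
    angles = np.linspace(0, np.pi, 90, endpoint=False)
    dirs = np.column_stack([np.cos(angles), np.sin(angles)])
    for cid in range(1, cells.n_cells + 1):
        pts = cells.cell_points_mm(cid)
        rel = pts - cells.centroids_mm[cid - 1]
        f = cells.frames[cid - 1]
        depth[cid - 1] = (rel @ f[0]).max() - (rel @ f[0]).min() + h
        plane_pts = np.column_stack([rel @ f[1], rel @ f[2]])
        try:
            from scipy.spatial import ConvexHull

            hull = plane_pts[ConvexHull(plane_pts).vertices]
        except Exception:
            hull = plane_pts
        spans = hull @ dirs.T
        width[cid - 1] = (spans.max(axis=0) - spans.min(axis=0)).min() + h
    cells.depth_mm = depth
    cells.width_mm = width
    return pd.DataFrame(
        {
            "id": np.arange(1, cells.n_cells + 1),
            "width_mm": width,
            "depth_mm": depth,
            "volume_mm3": cells.volumes_mm3,
            "tilt_deg": cells.tilt_deg if cells.tilt_deg is not None else np.nan,
        }
    )
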