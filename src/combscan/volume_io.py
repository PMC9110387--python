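"""Volumetric representations of comb scans and conversions between them.

A scanned comb is carried through three linked representations:

* :class:`DensityVolume` — a regular voxel grid of normalized attenuation
  values in [0, 1], the raw material field.
* :class:`SignedDistanceVolume` — the comb treated as a constant-density
  solid: per-voxel signed Euclidean distance to the boundary of the
  binarized solid, negative inside.
* :class:`SurfaceMesh` — a triangle discretization of the solid's boundary
  with named per-vertex attribute channels (curvatures, eigenvectors, ...).

World coordinates: voxel ``(i, j, k)`` has its *center* at
``origin_mm + (i, j, k) * spacing_mm``; indices are 0-based and arrays are
indexed ``values[i, j, k]`` with ``k`` the slice (z) axis.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DensityVolume",
    "SignedDistanceVolume",
    "SurfaceMesh",
    "FormatError",
    "EmptySolidError",
    "load_volume",
    "save_volume",
    "load_sdf",
    "to_sdf",
    "binarize",
    "extract_mesh",
    "downsample",
    "save_mesh",
]

#: Distance value used for an empty (or all-solid) phase instead of +inf,
#: large enough to exceed any grid diagonal we handle.
BIG_DISTANCE = 1.0e9


class FormatError(ValueError):
    """Raised for malformed or unsupported volume files."""


class EmptySolidError(ValueError):
    """Raised when a binarization produces no solid voxels."""


def _as_triple(x, name: str) -> tuple[float, float, float]:
    arr = np.asarray(x, dtype=float).reshape(-1)
    if arr.size == 1:
        arr = np.repeat(arr, 3)
    if arr.size != 3:
        raise ValueError(f"{name} must be a scalar or length-3 sequence")
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass
class _Grid:
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self._field().shape)  # pragma: no cover - overridden

    def _field(self) -> np.ndarray:
        raise NotImplementedError

    @property
    def is_isotropic(self) -> bool:
        s = self.spacing_mm
        return abs(s[0] - s[1]) < 1e-9 and abs(s[1] - s[2]) < 1e-9

    def require_isotropic(self, op: str) -> float:
        if not self.is_isotropic:
            raise ValueError(f"{op} requires isotropic voxel spacing, got {self.spacing_mm}")
        return self.spacing_mm[0]

    def world_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates of voxel centers."""
        return tuple(
            self.origin_mm[a] + self.spacing_mm[a] * np.arange(self._field().shape[a])
            for a in range(3)
        )

    def index_to_world(self, idx) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin_mm) + idx * np.asarray(self.spacing_mm)

    def world_to_index(self, pos) -> np.ndarray:
        pos = np.asarray(pos, dtype=float)
        return (pos - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)

    def same_grid(self, other: "_Grid") -> bool:
        return (
            self._field().shape == other._field().shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )


@dataclass
class DensityVolume(_Grid):
    """Regular 3-D grid of normalized attenuation values in [0, 1]."""

    values: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        if min(self.values.shape) < 2:
            raise ValueError("dims must be >= 2 along every axis")
        self.spacing_mm = _as_triple(self.spacing_mm, "spacing_mm")
        self.origin_mm = _as_triple(self.origin_mm, "origin_mm")
        if min(self.spacing_mm) <= 0:
            raise ValueError("spacing must be strictly positive")
        vmin, vmax = float(self.values.min()), float(self.values.max())
        if vmin < -1e-9 or vmax > 1 + 1e-9:
            raise ValueError(f"density values must lie in [0, 1], got [{vmin}, {vmax}]")

    def _field(self) -> np.ndarray:
        return self.values

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.values.shape)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass
class SignedDistanceVolume(_Grid):
    """Per-voxel signed Euclidean distance (mm) to the comb boundary.

    Negative strictly inside the solid, positive strictly outside;
    ``iso_threshold`` records the density level used to binarize.
    """

    distances: np.ndarray = None
    iso_threshold: float = 0.5

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=np.float64)
        if self.distances.ndim != 3:
            raise ValueError("distances must be a 3-D array")
        self.spacing_mm = _as_triple(self.spacing_mm, "spacing_mm")
        self.origin_mm = _as_triple(self.origin_mm, "origin_mm")
        if min(self.spacing_mm) <= 0:
            raise ValueError("spacing must be strictly positive")

    def _field(self) -> np.ndarray:
        return self.distances

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.distances.shape)

    @property
    def solid_mask(self) -> np.ndarray:
        """Boolean mask of inside voxels (distance < 0)."""
        return self.distances < 0

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def solid_volume_mm3(self) -> float:
        return float(self.solid_mask.sum()) * self.voxel_volume_mm3


@dataclass
class SurfaceMesh:
    """Triangle mesh of the comb boundary with per-vertex attribute channels."""

    vertices: np.ndarray
    faces: np.ndarray
    attributes: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("faces index out-of-range vertices")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges (sorted vertex pairs)."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(n, axis=1)

    def face_normals(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        norm = np.linalg.norm(n, axis=1)
        norm[norm == 0] = 1.0
        return n / norm[:, None]

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted average of incident face normals, unit length."""
        v = self.vertices
        f = self.faces
        fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])  # 2*area*unit
        vn = np.zeros_like(v)
        for c in range(3):
            np.add.at(vn, f[:, c], fn)
        norm = np.linalg.norm(vn, axis=1)
        norm[norm == 0] = 1.0
        return vn / norm[:, None]

    def vertex_areas(self) -> np.ndarray:
        """Barycentric vertex areas: one third of incident triangle area."""
        fa = self.face_areas()
        va = np.zeros(self.n_vertices)
        for c in range(3):
            np.add.at(va, self.faces[:, c], fa / 3.0)
        return va

    def total_area(self) -> float:
        return float(self.face_areas().sum())

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges) + self.n_faces

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_SUPPORTED_TIFF_DTYPES = ("uint8", "uint16", "int16", "float32", "float64")


def _normalize(values: np.ndarray) -> np.ndarray:
    vmin = float(values.min())
    vmax = float(values.max())
    if vmax - vmin <= 0:
        raise FormatError("degenerate range: constant-valued volume cannot be normalized")
    return (values - vmin) / (vmax - vmin)


def load_volume(
    path: str,
    format: str | None = None,
    normalize: bool = True,
    spacing_mm=(1.0, 1.0, 1.0),
    origin_mm=(0.0, 0.0, 0.0),
) -> DensityVolume:
    """Load a grayscale volume from a TIFF slice stack, NRRD or NIfTI file.

    Parameters
    ----------
    path
        Directory of per-slice TIFFs (lexicographic z order), a multi-page
        TIFF, an ``.nrrd`` or a ``.nii``/``.nii.gz`` file.
    format
        One of ``tiff_stack``, ``nrrd``, ``nifti``; inferred from the path
        when omitted.
    normalize
        Min-max normalize values into [0, 1] (matching how reconstructed
        16-bit scan stacks are treated). When off, values must already lie
        in [0, 1].
    spacing_mm, origin_mm
        Used for TIFF stacks, which carry no world metadata; NRRD/NIfTI
        spacing and origin are read from the file header.
    """
    if format is None:
        if os.path.isdir(path) or path.endswith((".tif", ".tiff")):
            format = "tiff_stack"
        elif path.endswith(".nrrd"):
            format = "nrrd"
        elif path.endswith((".nii", ".nii.gz")):
            format = "nifti"
        else:
            raise FormatError(f"cannot infer format of {path!r}")

    if format == "tiff_stack":
        values = _read_tiff_stack(path)
    elif format == "nrrd":
        values, spacing_mm, origin_mm = _read_sitk(path)
    elif format == "nifti":
        values, spacing_mm, origin_mm = _read_nifti(path)
    else:
        raise FormatError(f"unsupported format {format!r}")

    values = values.astype(np.float64)
    if normalize:
        values = _normalize(values)
    return DensityVolume(spacing_mm=spacing_mm, origin_mm=origin_mm, values=values)


def _read_tiff_stack(path: str) -> np.ndarray:
    import tifffile

    if os.path.isdir(path):
        names = sorted(f for f in os.listdir(path) if f.lower().endswith((".tif", ".tiff")))
        if not names:
            raise FormatError(f"no TIFF slices found in {path!r}")
        slices = []
        shape = None
        dtype = None
        for name in names:
            img = tifffile.imread(os.path.join(path, name))
            if img.ndim != 2:
                raise FormatError(f"slice {name!r} is not a single 2-D image")
            if str(img.dtype) not in _SUPPORTED_TIFF_DTYPES:
                raise FormatError(f"unsupported bit depth {img.dtype} in slice {name!r}")
            if shape is None:
                shape, dtype = img.shape, img.dtype
            elif img.shape != shape:
                raise FormatError(f"mixed slice shapes: {img.shape} vs {shape}")
            elif img.dtype != dtype:
                raise FormatError(f"mixed slice dtypes: {img.dtype} vs {dtype}")
            slices.append(img)
        stack = np.stack(slices, axis=0)  # (z, y, x)
    else:
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            raise FormatError("multi-page TIFF expected, got a single 2-D image")
        if str(stack.dtype) not in _SUPPORTED_TIFF_DTYPES:
            raise FormatError(f"unsupported bit depth {stack.dtype}")
    # slice index maps to z: reorder (z, y, x) -> (x, y, z)
    return np.transpose(stack, (2, 1, 0))


def _read_sitk(path: str):
    import SimpleITK as sitk

    img = sitk.ReadImage(path)
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    values = np.transpose(arr, (2, 1, 0))
    spacing = tuple(float(s) for s in img.GetSpacing())
    origin = tuple(float(o) for o in img.GetOrigin())
    return values, spacing, origin


def _read_nifti(path: str):
    import nibabel as nib

    img = nib.load(path)
    values = np.asarray(img.dataobj)
    if values.ndim != 3:
        raise FormatError("NIfTI volume must be 3-D")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return values, tuple(float(z) for z in zooms), origin


def save_volume(vol: DensityVolume | SignedDistanceVolume, path: str) -> None:
    """Write a volume to NRRD (``.nrrd``) or NIfTI (``.nii``/``.nii.gz``)."""
    values = vol.values if isinstance(vol, DensityVolume) else vol.distances
    if path.endswith(".nrrd"):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.transpose(values, (2, 1, 0)))
        img.SetSpacing(tuple(vol.spacing_mm))
        img.SetOrigin(tuple(vol.origin_mm))
        sitk.WriteImage(img, path)
    elif path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag(list(vol.spacing_mm) + [1.0])
        affine[:3, 3] = vol.origin_mm
        nib.save(nib.Nifti1Image(values.astype(np.float32), affine), path)
    else:
        raise FormatError(f"unsupported output format for {path!r}")


def load_sdf(path: str, iso_threshold: float = 0.5) -> SignedDistanceVolume:
    """Read a signed distance volume written by :func:`save_volume`."""
    if path.endswith(".nrrd"):
        values, spacing, origin = _read_sitk(path)
    elif path.endswith((".nii", ".nii.gz")):
        values, spacing, origin = _read_nifti(path)
    else:
        raise FormatError(f"unsupported SDF format for {path!r}")
    return SignedDistanceVolume(
        spacing_mm=spacing, origin_mm=origin, distances=np.asarray(values, float),
        iso_threshold=iso_threshold,
    )


def save_mesh(mesh: SurfaceMesh, path: str) -> None:
    """Write a mesh to PLY or OBJ, preserving vertex order."""
    if not path.endswith((".ply", ".obj")):
        raise FormatError(f"unsupported mesh format for {path!r}")
    mesh.to_trimesh().export(path)


# ---------------------------------------------------------------------------
# Representation conversions
# ---------------------------------------------------------------------------


def binarize(vol: DensityVolume, iso_threshold: float = 0.5) -> np.ndarray:
    """Solid mask: voxels with density >= iso_threshold."""
    if not 0 < iso_threshold < 1:
        raise ValueError("iso_threshold must lie in (0, 1)")
    return vol.values >= iso_threshold


def signed_distance_from_mask(
    mask: np.ndarray,
    spacing_mm,
    origin_mm=(0.0, 0.0, 0.0),
    iso_threshold: float = 0.5,
) -> SignedDistanceVolume:
    """Exact signed Euclidean distance transform of a boolean solid mask.

    Each voxel's distance is to the nearest voxel *center* of the opposite
    phase: negative (minus the depth) inside, positive outside. Empty/full
    phases get a large sentinel magnitude rather than infinity.
    """
    from scipy import ndimage

    mask = np.asarray(mask, dtype=bool)
    spacing = _as_triple(spacing_mm, "spacing_mm")
    if not mask.any():
        dist = np.full(mask.shape, BIG_DISTANCE)
    elif mask.all():
        dist = np.full(mask.shape, -BIG_DISTANCE)
    else:
        dist_out = ndimage.distance_transform_edt(~mask, sampling=spacing)
        dist_in = ndimage.distance_transform_edt(mask, sampling=spacing)
        dist = dist_out - dist_in
    return SignedDistanceVolume(
        spacing_mm=spacing, origin_mm=origin_mm, distances=dist, iso_threshold=iso_threshold
    )


def to_sdf(vol: DensityVolume, iso_threshold: float = 0.5) -> SignedDistanceVolume:
    """Binarize a density volume at ``iso_threshold`` and compute its SDF.

    The density field is discarded: the solid is treated as uniform, which
    is how shape-only operators (morphology, meshing) see the comb.
    """
    mask = binarize(vol, iso_threshold)
    if not mask.any():
        raise EmptySolidError(f"no voxel reaches iso_threshold={iso_threshold}")
    return signed_distance_from_mask(mask, vol.spacing_mm, vol.origin_mm, iso_threshold)


def extract_mesh(sdf: SignedDistanceVolume, cleanup: bool = True) -> SurfaceMesh:
    """Marching-cubes surface at the SDF zero level set, in world mm.

    Normals are oriented outward (toward positive distance). Degenerate
    faces and unreferenced vertices are removed when ``cleanup`` is set.
    """
    from skimage import measure

    d = sdf.distances
    if d.min() >= 0 or d.max() <= 0:
        raise EmptySolidError("zero level set is empty")
    verts, faces, _, _ = measure.marching_cubes(
        d, level=0.0, spacing=sdf.spacing_mm, gradient_direction="descent"
    )
    verts = verts + np.asarray(sdf.origin_mm)
    mesh = SurfaceMesh(vertices=verts, faces=faces)
    if cleanup:
        import trimesh

        tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=True)
        tm.update_faces(tm.nondegenerate_faces())
        tm.remove_unreferenced_vertices()
        mesh = SurfaceMesh(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces))
    return mesh


def downsample(vol: DensityVolume, factor: int) -> DensityVolume:
    """Block-mean pooling by an integer factor (trailing remainders cropped).

    Used to halve resolution before the computationally heavy operators;
    spacing is multiplied by ``factor`` and the origin shifted to keep the
    pooled voxel centers at the block centers.
    """
    if factor < 1 or factor != int(factor):
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return replace(vol, values=vol.values.copy())
    if any(factor > s for s in vol.values.shape):
        raise ValueError(f"factor {factor} exceeds volume dims {vol.values.shape}")
    nx, ny, nz = (s // factor for s in vol.values.shape)
    v = vol.values[: nx * factor, : ny * factor, : nz * factor]
    pooled = v.reshape(nx, factor, ny, factor, nz, factor).mean(axis=(1, 3, 5))
    spacing = tuple(s * factor for s in vol.spacing_mm)
    origin = tuple(
        o + 0.5 * (factor - 1) * s for o, s in zip(vol.origin_mm, vol.spacing_mm)
    )
    return DensityVolume(spacing_mm=spacing, origin_mm=origin, values=pooled)
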