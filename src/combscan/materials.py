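"""Attenuation-to-density calibration and material quantification.

X-ray attenuation of light organic materials scales approximately with
physical density, so the normalized voxel values of a comb scan can be
mapped to g/cm^3 by an affine fit through reference materials of known
density present in the scan (e.g. a 3D-printed substrate at 1.19 g/cm^3
and honey at 1.4 g/cm^3; new beeswax lies near 0.958-0.970 g/cm^3 and
propolis near 1.16 g/cm^3).  Density bands then segment the volume into
materials and integrate their volumes — for instance the honey held in a
comb's cells, reported in millilitres.

No partial-volume correction is applied: voxels straddling material
boundaries are assigned whole to one band, a known (and documented) bias
of attenuation-based density estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cell_analysis import CellSet
from .volume_io import DensityVolume

__all__ = [
    "DensityCalibration",
    "MaterialBand",
    "calibrate",
    "segment_bands",
    "honey_volume",
    "density_profile",
    "BEESWAX_DENSITY_G_CM3",
    "PROPOLIS_DENSITY_G_CM3",
    "PRINT_POLYMER_DENSITY_G_CM3",
    "HONEY_DENSITY_G_CM3",
]

# Reference densities of materials commonly present in scanned hives.
BEESWAX_DENSITY_G_CM3 = (0.958, 0.970)
PROPOLIS_DENSITY_G_CM3 = 1.16
PRINT_POLYMER_DENSITY_G_CM3 = 1.19
HONEY_DENSITY_G_CM3 = 1.4


@dataclass
class DensityCalibration:
    """Affine map from normalized attenuation value to density (g/cm^3)."""

    slope: float
    intercept: float
    references: list[tuple[float, float, str]] = field(default_factory=list)

    def density(self, values) -> np.ndarray:
        return self.slope * np.asarray(values, dtype=float) + self.intercept

    def value(self, density) -> np.ndarray:
        return (np.asarray(density, dtype=float) - self.intercept) / self.slope


@dataclass(frozen=True)
class MaterialBand:
    """Half-open density band ``(lo, hi]`` in g/cm^3 with a label."""

    label: str
    lo: float
    hi: float
    color: str | None = None

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError(f"band {self.label!r}: lo must be < hi")

    def contains(self, density: np.ndarray) -> np.ndarray:
        d = np.asarray(density)
        return (d > self.lo) & (d <= self.hi)


def _check_disjoint(bands: list[MaterialBand]) -> None:
    for i, a in enumerate(bands):
        for b in bands[i + 1 :]:
            if a.lo < b.hi and b.lo < a.hi:
                raise ValueError(f"overlapping bands: {a.label!r} and {b.label!r}")


def calibrate(references: list[tuple[float, float, str]]) -> DensityCalibration:
    """Least-squares line through (normalized value, known density) pairs.

    With exactly two references the line interpolates both. References
    must be monotone: a higher attenuation value must correspond to a
    higher density.
    """
    if len(references) < 2:
        raise ValueError("need at least 2 reference points")
    vals = np.asarray([r[0] for r in references], dtype=float)
    dens = np.asarray([r[1] for r in references], dtype=float)
    if len(np.unique(vals)) < 2:
        raise ValueError("reference values must be distinct")
    order = np.argsort(vals)
    if np.any(np.diff(dens[order]) <= 0):
        raise ValueError("non-monotone references: higher value with lower density")
    slope, intercept = np.polyfit(vals, dens, 1)
    if slope <= 0:
        raise ValueError("calibration must be strictly increasing")
    return DensityCalibration(
        slope=float(slope),
        intercept=float(intercept),
        references=[(float(v), float(d), str(l)) for v, d, l in references],
    )


def segment_bands(
    vol: DensityVolume,
    cal: DensityCalibration,
    bands: list[MaterialBand],
) -> tuple[np.ndarray, pd.DataFrame]:
    """Assign each voxel to the band containing its calibrated density.

    Returns a label volume (0 = background, i.e. no band) and a table with
    per-band voxel counts and volumes in mm^3 and ml.
    """
    _check_disjoint(bands)
    density = cal.density(vol.values)
    labels = np.zeros(vol.values.shape, dtype=np.uint16)
    rows = []
    vox = vol.voxel_volume_mm3
    for i, band in enumerate(bands, start=1):
        sel = band.contains(density) & (labels == 0)
        labels[sel] = i
        n = int(sel.sum())
        rows.append(
            {
                "label": band.label,
                "voxels": n,
                "mm3": n * vox,
                "ml": n * vox / 1000.0,
            }
        )
    return labels, pd.DataFrame(rows)


def honey_volume(
    vol: DensityVolume,
    cal: DensityCalibration,
    honey_band: MaterialBand,
    restrict_to_cells: CellSet | None = None,
) -> float:
    """Volume of honey-density material in millilitres.

    Optionally restricted to extracted cell interiors, which excludes
    honey-density material smeared outside cells.
    """
    density = cal.density(vol.values)
    sel = honey_band.contains(density)
    if restrict_to_cells is not None:
        if restrict_to_cells.labels.shape != vol.values.shape:
            raise ValueError("cell label volume does not match the density grid")
        sel &= restrict_to_cells.labels > 0
    return float(sel.sum()) * vol.voxel_volume_mm3 / 1000.0


def density_profile(
    vol: DensityVolume,
    cal: DensityCalibration,
    region: np.ndarray,
    bins: int = 50,
) -> tuple[pd.DataFrame, dict]:
    """Calibrated-density histogram and summary statistics over a region.

    Returns (histogram table with bin_lo/bin_hi/count, summary dict with
    median and IQR in g/cm^3).
    """
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError("empty region")
    d = cal.density(vol.values[region])
    lo, hi = float(d.min()), float(d.max())
    if hi - lo <= 0:
        edges = np.linspace(lo - 0.5, lo + 0.5, bins + 1)
    else:
        edges = np.linspace(lo, hi, bins + 1)
    counts, _ = np.histogram(d, bins=edges)
    q25, q50, q75 = np.percentile(d, [25, 50, 75])
    hist = pd.DataFrame({"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts})
    summary = {
        "median_g_cm3": float(q50),
        "iqr_g_cm3": float(q75 - q25),
        "q25_g_cm3": float(q25),
        "q75_g_cm3": float(q75),
        "n_voxels": int(region.sum()),
    }
    return hist, summary
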