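"""Shared fixtures: small comb phantoms and analytic shapes.

Phantoms are generated once per session at coarse-but-sufficient
resolution (walls >= 2 voxels) so the many tests that consume them stay
fast.
"""

import numpy as np
import pytest

from combscan import cell_analysis as ca
from combscan import synthetic_comb as syn
from combscan import volume_io as vio

ISO = 0.2  # binarization threshold between air (0) and wax (0.475)


@pytest.fixture(scope="session")
def small_phantom():
    """Double-sided 3x4-cell comb at 0.3 mm spacing with ground truth."""
    spec = syn.CombPhantomSpec(rows=3, cols=4, spacing_mm=0.3, rng_seed=11)
    vol, gt = syn.generate(spec)
    return vol, gt


@pytest.fixture(scope="session")
def small_phantom_sdf(small_phantom):
    """SDF of the constructed comb only (substrate isolated out, as the
    density-discrimination step would do on a real scan)."""
    vol, gt = small_phantom
    mask = (vol.values >= ISO) & ~gt.substrate_mask
    return vio.signed_distance_from_mask(mask, vol.spacing_mm, vol.origin_mm, ISO)


@pytest.fixture(scope="session")
def small_phantom_cells(small_phantom, small_phantom_sdf):
    _, gt = small_phantom
    cells = ca.extract_cells(small_phantom_sdf)
    ca.cell_frames(cells)
    plane = ca.median_plane(cells)
    return cells, plane, gt


@pytest.fixture(scope="session")
def ball_sdf():
    return syn.analytic_shapes("ball", radius=10.0, spacing_mm=0.5)


@pytest.fixture(scope="session")
def ball_mesh(ball_sdf):
    return vio.extract_mesh(ball_sdf)


@pytest.fixture(scope="session")
def icosphere():
    import trimesh

    tm = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
    return vio.SurfaceMesh(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces))


def comb_only_sdf(vol, gt, iso=ISO):
    """SDF of the comb material with the substrate isolated out."""
    mask = (vol.values >= iso) & ~gt.substrate_mask
    return vio.signed_distance_from_mask(mask, vol.spacing_mm, vol.origin_mm, iso)


def random_solid(rng, shape=(16, 16, 16), p=0.5, smooth=True):
    """Random but blob-like binary solid for morphology oracles."""
    from scipy import ndimage

    noise = rng.random(shape)
    if smooth:
        noise = ndimage.gaussian_filter(noise, 1.5)
    mask = noise > np.quantile(noise, 1 - p)
    return mask
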