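import numpy as np
import pytest

from prlcortex.synthetic import SurfaceSpec, gen_surface
from prlcortex.types import SensitivityMap, VisualFieldROI


@pytest.fixture(scope="session")
def surface_small():
    """800 vertices per hemisphere; enough for LPZ (100/hemi) and dilation."""
    return gen_surface(SurfaceSpec(n_vertices_per_hemi=800, seed=11))


@pytest.fixture(scope="session")
def surface_big():
    """20k vertices per hemisphere, for density/round-trip contracts."""
    return gen_surface(SurfaceSpec(n_vertices_per_hemi=20_000, seed=5))


def make_disc_roi(center, radius, step=0.1, role="PRL"):
    """Rasterised disc: all grid cells whose centres lie within the radius."""
    cx, cy = center
    xs = np.arange(cx - radius - step, cx + radius + step, step)
    ys = np.arange(cy - radius - step, cy + radius + step, step)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    cells = pts[np.hypot(pts[:, 0] - cx, pts[:, 1] - cy) <= radius]
    return VisualFieldROI(role=role, cells=cells, step=step, center=center)


def make_uniform_map(extent=14.0, spacing=1.0, seen=True, threshold=25.0):
    """Square grid of loci, all seen (or all unseen)."""
    xs = np.arange(-extent, extent + spacing / 2, spacing)
    gx, gy = np.meshgrid(xs, xs)
    xy = np.column_stack([gx.ravel(), gy.ravel()])
    n = len(xy)
    return SensitivityMap(
        eye="fused",
        xy=xy,
        threshold_db=np.full(n, threshold if seen else np.nan),
        seen=np.full(n, seen),
    )


@pytest.fixture
def uniform_seeing():
    return make_uniform_map()
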