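"""Core domain types shared across the pipeline.

Coordinate conventions
----------------------
All planar coordinates are visual-field degrees relative to the fovea at the
origin. Polar angle is measured counter-clockwise from the positive x axis
(right horizontal meridian) and stored in degrees in ``(-180, 180]``. The
right visual hemifield (``x > 0``) projects to the left cortical hemisphere
(``"lh"``) and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

HEMIS = ("lh", "rh")

#: metric columns a fully annotated surface carries
METRIC_COLUMNS = ("thickness_mm", "ficvf", "odi")


@dataclass
class FixationCloud:
    """A set of fixation samples for one eye.

    ``points`` are absolute coordinates in degrees; ``fovea`` is the origin
    reference subtracted before any statistic is computed. ``px_per_deg``
    records the ingest conversion factor (1.0 when data were already in
    degrees).
    """

    eye: str
    points: np.ndarray
    fovea: Tuple[float, float] = (0.0, 0.0)
    px_per_deg: float = 1.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if self.px_per_deg <= 0:
            raise InvalidParameterError("px_per_deg must be positive")

    @property
    def n(self) -> int:
        return len(self.points)

    def relative(self) -> np.ndarray:
        """Points with the fovea subtracted (fovea-centred degrees)."""
        return self.points - np.asarray(self.fovea, dtype=float)


@dataclass
class BCEAResult:
    """Bivariate contour ellipse fit of a fixation cloud."""

    center: Tuple[float, float]
    sigma_h: float
    sigma_v: float
    rho: float
    coverage: float
    chi2_quantile: float
    area: float
    semi_axes: Tuple[float, float]
    orientation_deg: float
    degenerate: bool = False


@dataclass
class SensitivityMap:
    """Detection thresholds at a set of test loci for one eye (or the fused
    binocular map). Unseen loci carry ``seen=False`` and a NaN threshold."""

    eye: str
    xy: np.ndarray
    threshold_db: np.ndarray
    seen: np.ndarray
    fovea: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        self.threshold_db = np.asarray(self.threshold_db, dtype=float)
        self.seen = np.asarray(self.seen, dtype=bool)
        if not (len(self.xy) == len(self.threshold_db) == len(self.seen)):
            raise InvalidParameterError("sensitivity map arrays must align")
        if not np.all(np.isfinite(self.xy)):
            raise InvalidParameterError("locus coordinates must be finite")

    @property
    def n(self) -> int:
        return len(self.xy)

    def centered(self) -> "SensitivityMap":
        """Same map translated so the fovea sits at the origin."""
        return SensitivityMap(
            eye=self.eye,
            xy=self.xy - np.asarray(self.fovea, dtype=float),
            threshold_db=self.threshold_db.copy(),
            seen=self.seen.copy(),
            fovea=(0.0, 0.0),
        )


@dataclass
class VisualFieldROI:
    """A planar region represented as rasterised cell centres.

    ``cells`` holds the centres of occupied raster cells of side ``step``
    degrees. ``center`` is the nominal ROI centre (the BCEA centre for a PRL,
    the transformed centre for a URL, the cell centroid after trimming).
    """

    role: str
    cells: np.ndarray
    step: float
    center: Tuple[float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=float).reshape(-1, 2)
        if self.step <= 0:
            raise InvalidParameterError("raster step must be positive")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def area_deg2(self) -> float:
        return self.n_cells * self.step**2

    @property
    def eccentricity(self) -> float:
        return float(np.hypot(*self.center))

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Membership of arbitrary field points.

        A point belongs to the ROI iff it falls inside the axis-aligned box of
        some occupied cell (half-step Chebyshev distance to a cell centre).
        """
        from scipy.spatial import cKDTree

        points = np.asarray(points, dtype=float).reshape(-1, 2)
        if self.n_cells == 0:
            return np.zeros(len(points), dtype=bool)
        tree = cKDTree(self.cells)
        _, idx = tree.query(points)
        delta = np.abs(points - self.cells[idx])
        half = self.step / 2 + 1e-9
        return np.all(delta <= half, axis=1)


class RetinotopicSurface:
    """Per-participant triangulated cortical surface with retinotopy.

    ``vertices`` is indexed by vertex id with columns ``hemi``, ``ecc_deg``,
    ``angle_deg``, ``v1`` and, once metric maps exist, ``thickness_mm``,
    ``ficvf``, ``odi`` (plus ``thickness_norm`` after normalisation).
    ``triangles`` is an ``(m, 3)`` integer array of vertex ids.
    """

    def __init__(self, vertices: pd.DataFrame, triangles: np.ndarray):
        required = {"hemi", "ecc_deg", "angle_deg", "v1"}
        missing = required - set(vertices.columns)
        if missing:
            raise InvalidParameterError(f"surface table missing columns {sorted(missing)}")
        if (vertices["ecc_deg"] < 0).any():
            raise InvalidParameterError("eccentricity must be non-negative")
        self.vertices = vertices
        self.triangles = np.asarray(triangles, dtype=int).reshape(-1, 3)
        self._adjacency: Optional[Dict[int, set]] = None

    def copy(self) -> "RetinotopicSurface":
        out = RetinotopicSurface(self.vertices.copy(), self.triangles.copy())
        out._adjacency = self._adjacency
        return out

    @property
    def has_metrics(self) -> bool:
        return all(c in self.vertices.columns for c in METRIC_COLUMNS)

    def field_xy(self) -> np.ndarray:
        """Visual-field Cartesian coordinates of every vertex, degrees."""
        theta = np.deg2rad(self.vertices["angle_deg"].to_numpy())
        ecc = self.vertices["ecc_deg"].to_numpy()
        return np.column_stack([ecc * np.cos(theta), ecc * np.sin(theta)])

    @property
    def adjacency(self) -> Dict[int, set]:
        """Undirected one-ring neighbourhood from the triangle list."""
        if self._adjacency is None:
            adj: Dict[int, set] = {int(v): set() for v in self.vertices.index}
            for a, b, c in self.triangles:
                adj[int(a)].update((int(b), int(c)))
                adj[int(b)].update((int(a), int(c)))
                adj[int(c)].update((int(a), int(b)))
            self._adjacency = adj
        return self._adjacency

    def neighbors(self, vertex_ids) -> set:
        adj = self.adjacency
        out: set = set()
        for v in vertex_ids:
            out |= adj.get(int(v), set())
        return out

    def validity_mask(self) -> pd.Series:
        """Per-vertex validity: metric columns present must be finite and
        non-zero. Surfaces without metrics are fully valid."""
        ok = pd.Series(True, index=self.vertices.index)
        for col in METRIC_COLUMNS:
            if col in self.vertices.columns:
                vals = self.vertices[col]
                ok &= np.isfinite(vals) & (vals != 0)
        return ok


@dataclass
class CorticalROI:
    """A labelled set of surface vertices, split by hemisphere."""

    label: str
    vertices: Dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = {
            h: np.unique(np.asarray(v, dtype=int)) for h, v in self.vertices.items()
        }

    @property
    def n_vertices(self) -> int:
        return sum(len(v) for v in self.vertices.values())

    def all_vertices(self) -> np.ndarray:
        parts = [self.vertices[h] for h in sorted(self.vertices)]
        if not parts:
            return np.array([], dtype=int)
        return np.concatenate(parts)

    def mean_ecc(self, surface: RetinotopicSurface) -> float:
        ids = self.all_vertices()
        if len(ids) == 0:
            return float("nan")
        return float(surface.vertices.loc[ids, "ecc_deg"].mean())
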