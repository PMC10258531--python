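"""Projection of visual-field ROIs onto V1 surface vertices, mesh dilation to
a minimum vertex count, and LPZ / eccentricity-band ROI definitions."""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import (
    EmptyROIError,
    InsufficientSurfaceError,
    InvalidParameterError,
    MissingAnnotationError,
    UncoveredVertexError,
)
from .types import HEMIS, CorticalROI, RetinotopicSurface, VisualFieldROI

#: default fixed eccentricity-band limits (degrees); eight bands, shared
#: across hemispheres
DEFAULT_ECC_BAND_LIMITS = (0.0, 2.0, 4.3, 6.8, 9.3, 15.7, 26.6, 45.4, 90.0)

DEFAULT_MIN_ROI_VERTICES = 50
DEFAULT_LPZ_SIZE_PER_HEMI = 100


def field_to_hemifield(point: Sequence[float]) -> str:
    """Contralateral projection: left field -> right hemisphere and vice
    versa. Points on the vertical meridian return ``"both"``."""
    x, y = float(point[0]), float(point[1])
    if not (np.isfinite(x) and np.isfinite(y)):
        raise InvalidParameterError("point must be finite")
    if x > 0:
        return "lh"
    if x < 0:
        return "rh"
    return "both"


def _v1_valid_ids(surface: RetinotopicSurface) -> pd.Index:
    valid = surface.validity_mask()
    flags = surface.vertices["v1"] & valid
    return surface.vertices.index[flags]


def map_roi_to_surface(roi: VisualFieldROI, surface: RetinotopicSurface) -> CorticalROI:
    """Vertex membership by retinotopic lookup.

    Each V1 vertex's (eccentricity, polar angle) is converted to field
    Cartesian coordinates; the vertex joins the cortical ROI iff its nearest
    raster cell (Euclidean distance in field degrees) is an ROI cell, i.e. the
    vertex falls inside that cell's box.
    """
    for col in ("ecc_deg", "angle_deg"):
        if col not in surface.vertices.columns:
            raise MissingAnnotationError(f"surface lacks {col}")
    ids = _v1_valid_ids(surface)
    label = {"PRL": "cPRL", "URL": "cURL"}.get(roi.role, roi.role)
    if roi.n_cells == 0:
        return CorticalROI(label=label, vertices={})
    xy = surface.field_xy()[surface.vertices.index.get_indexer(ids)]
    member = roi.contains(xy)
    chosen = ids[member]
    hemis = surface.vertices.loc[chosen, "hemi"]
    vertices = {
        h: chosen[hemis == h].to_numpy() for h in HEMIS if (hemis == h).any()
    }
    return CorticalROI(label=label, vertices=vertices, meta={"source_role": roi.role})


def dilate_roi(
    roi: CorticalROI,
    surface: RetinotopicSurface,
    min_vertices: int = DEFAULT_MIN_ROI_VERTICES,
) -> CorticalROI:
    """One-ring mesh dilation of the larger hemisphere portion until the
    combined V1 vertex count reaches ``min_vertices``.

    The smaller portion stays fixed. Non-V1 (and invalid) vertices reached by
    a ring are pruned before counting, and dilation proceeds from the pruned
    set. Raises once a ring adds no new V1 vertex while still short.
    """
    if roi.n_vertices == 0:
        raise EmptyROIError("cannot dilate an empty ROI")
    keep = set(_v1_valid_ids(surface))
    portions: Dict[str, set] = {
        h: set(int(v) for v in ids) & keep for h, ids in roi.vertices.items()
    }
    portions = {h: s for h, s in portions.items() if s}
    if not portions:
        raise EmptyROIError("ROI contains no valid V1 vertices")
    # larger portion grows; ties resolve to 'lh'
    grow = max(sorted(portions), key=lambda h: len(portions[h]))
    hemi_of = surface.vertices["hemi"].to_dict()
    rings = 0
    pruned = 0

    def total() -> int:
        return sum(len(s) for s in portions.values())

    while total() < min_vertices:
        ring = surface.neighbors(portions[grow]) - portions[grow]
        # stay within the growing hemisphere
        ring = {v for v in ring if hemi_of[v] == grow}
        new = ring & keep
        pruned += len(ring) - len(new)
        if not new:
            raise InsufficientSurfaceError(
                f"dilation exhausted the mesh at {total()} < {min_vertices} vertices"
            )
        portions[grow] |= new
        rings += 1
    meta = dict(roi.meta, dilation_rings=rings, dilation_pruned=pruned)
    return CorticalROI(
        label=roi.label,
        vertices={h: np.fromiter(s, dtype=int) for h, s in portions.items()},
        meta=meta,
    )


def define_lpz(
    surface: RetinotopicSurface, n_per_hemi: int = DEFAULT_LPZ_SIZE_PER_HEMI
) -> CorticalROI:
    """The ``n_per_hemi`` lowest-eccentricity V1 vertices of each hemisphere.

    Ties at the cutoff break by vertex id (ascending).
    """
    ids = _v1_valid_ids(surface)
    vertices = {}
    for h in HEMIS:
        sub = surface.vertices.loc[ids]
        sub = sub[sub["hemi"] == h]
        if len(sub) < n_per_hemi:
            raise InsufficientSurfaceError(
                f"hemisphere {h} has {len(sub)} < {n_per_hemi} V1 vertices"
            )
        order = sub.sort_values(["ecc_deg"], kind="stable").index
        vertices[h] = order[:n_per_hemi].to_numpy()
    return CorticalROI(label="LPZ", vertices=vertices)


def quantile_band_limits(
    surface: RetinotopicSurface, n_bands: int
) -> List[float]:
    """Band limits at pooled (across-hemisphere) vertex-count quantiles, so
    that binning by the shared limits yields equal band sizes within one
    vertex."""
    ids = _v1_valid_ids(surface)
    ecc = np.sort(surface.vertices.loc[ids, "ecc_deg"].to_numpy())
    n = len(ecc)
    limits = [0.0]
    for k in range(1, n_bands):
        c = int(round(k * n / n_bands))
        limits.append(float((ecc[c - 1] + ecc[c]) / 2))
    limits.append(float(ecc[-1]))
    return limits


def define_eccentricity_bands(
    surface: RetinotopicSurface,
    n_bands: int = 8,
    fixed_ranges: Optional[Sequence[float]] = None,
) -> List[CorticalROI]:
    """Partition V1 into eccentricity bands shared across hemispheres.

    ``fixed_ranges`` is a monotone limit sequence of length ``n_bands + 1``;
    when omitted, limits are chosen at pooled vertex-count quantiles. Bins are
    half-open ``[lo, hi)`` with the last bin closed.
    """
    if n_bands < 2:
        raise InvalidParameterError("n_bands must be >= 2")
    ids = _v1_valid_ids(surface)
    ecc = surface.vertices.loc[ids, "ecc_deg"].to_numpy()
    if fixed_ranges is not None:
        limits = [float(x) for x in fixed_ranges]
        if len(limits) != n_bands + 1 or np.any(np.diff(limits) <= 0):
            raise InvalidParameterError("fixed_ranges must be n_bands+1 increasing values")
        if (ecc < limits[0]).any() or (ecc > limits[-1]).any():
            raise UncoveredVertexError("eccentricity ranges do not cover all V1 vertices")
    else:
        limits = quantile_band_limits(surface, n_bands)
    # np.digitize with right-open bins; clamp the top edge into the last band
    band = np.digitize(ecc, limits[1:-1], right=False)
    hemis = surface.vertices.loc[ids, "hemi"].to_numpy()
    rois = []
    for k in range(n_bands):
        sel = ids[band == k]
        hs = hemis[band == k]
        rois.append(
            CorticalROI(
                label=f"ecc-band-{k + 1}",
                vertices={h: sel[hs == h].to_numpy() for h in HEMIS},
                meta={"lo": limits[k], "hi": limits[k + 1]},
            )
        )
    return rois
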