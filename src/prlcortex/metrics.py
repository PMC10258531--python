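"""Thickness normalisation and per-ROI metric aggregation."""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyAggregateError, InvalidParameterError, NormalizationError
from .types import CorticalROI, RetinotopicSurface

METRIC_TABLE_COLUMNS = (
    "participant",
    "roi_label",
    "metric",
    "value",
    "n_vertices",
    "mean_ecc",
)


def normalize_thickness(surface: RetinotopicSurface) -> RetinotopicSurface:
    """Divide each vertex's thickness by its hemisphere's mean thickness.

    The hemispheric mean is taken over all valid vertices of that hemisphere
    (not only V1), so the per-hemisphere mean of the normalised values is
    exactly 1 and the result is invariant to rescaling the raw map.
    """
    if "thickness_mm" not in surface.vertices.columns:
        raise NormalizationError("surface carries no thickness map")
    out = surface.copy()
    valid = out.validity_mask()
    norm = pd.Series(np.nan, index=out.vertices.index)
    for h, sub in out.vertices.groupby("hemi"):
        sel = valid.loc[sub.index]
        vals = sub.loc[sel, "thickness_mm"]
        if len(vals) == 0 or not np.isfinite(vals.mean()) or vals.mean() == 0:
            raise NormalizationError(f"hemisphere {h} mean thickness undefined or zero")
        norm.loc[sub.index] = sub["thickness_mm"] / vals.mean()
    out.vertices["thickness_norm"] = norm
    return out


def extract_roi_metrics(
    surface: RetinotopicSurface,
    rois: Sequence[CorticalROI],
    metrics: Sequence[str] = ("thickness_norm", "ficvf", "odi"),
    participant: str = "",
) -> pd.DataFrame:
    """Tidy table of unweighted per-ROI means (hemispheres pooled).

    Vertices failing the validity mask are dropped from both numerator and
    count. One row per (participant, roi, metric).
    """
    if not rois:
        raise InvalidParameterError("no ROIs given")
    for m in metrics:
        if m not in surface.vertices.columns:
            raise InvalidParameterError(f"surface lacks metric {m!r}")
    valid = surface.validity_mask()
    rows = []
    for roi in rois:
        ids = roi.all_vertices()
        ids = ids[valid.loc[ids].to_numpy()] if len(ids) else ids
        if len(ids) == 0:
            raise EmptyAggregateError(f"ROI {roi.label} has no valid vertices")
        sub = surface.vertices.loc[ids]
        mean_ecc = float(sub["ecc_deg"].mean())
        for m in metrics:
            rows.append(
                {
                    "participant": participant,
                    "roi_label": roi.label,
                    "metric": m,
                    "value": float(sub[m].mean()),
                    "n_vertices": len(ids),
                    "mean_ecc": mean_ecc,
                }
            )
    return pd.DataFrame(rows, columns=list(METRIC_TABLE_COLUMNS))
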