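"""PRL/URL definition from microperimetry: fixation statistics, bivariate
contour ellipses, binocular fusion, scotoma trimming, and URL placement."""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import chi2

from .errors import (
    AlignmentError,
    EmptyInputError,
    EmptyROIError,
    InvalidParameterError,
    NoValidURLError,
)
from .types import BCEAResult, FixationCloud, SensitivityMap, VisualFieldROI

DEFAULT_RASTER_STEP = 0.1
DEFAULT_BCEA_ECC_THRESHOLD = 7.0


def compute_prl_center(cloud: FixationCloud) -> np.ndarray:
    """Centre of mass of the fixation cloud, fovea-centred degrees."""
    if cloud.n == 0:
        raise EmptyInputError("fixation cloud is empty")
    return cloud.relative().mean(axis=0)


def fit_bcea(cloud: FixationCloud, coverage: float = 0.63) -> BCEAResult:
    """Fit the bivariate contour ellipse containing ``coverage`` of fixations.

    Sample statistics use the n-1 denominator. The ellipse area is
    ``chi2_quantile * pi * sigma_h * sigma_v * sqrt(1 - rho^2)`` with the
    chi-square quantile evaluated exactly at 2 degrees of freedom. A cloud
    with (numerically) singular covariance yields a zero-area result flagged
    ``degenerate`` instead of an exception, so all-identical clouds report an
    area of 0.
    """
    if not 0 < coverage < 1:
        raise InvalidParameterError("coverage must be in (0, 1)")
    if cloud.n < 3:
        raise InvalidParameterError("need >= 3 points for an ellipse fit")
    pts = cloud.relative()
    center = pts.mean(axis=0)
    sigma_h = float(pts[:, 0].std(ddof=1))
    sigma_v = float(pts[:, 1].std(ddof=1))
    k = float(chi2.ppf(coverage, df=2))
    cov = np.cov(pts.T, ddof=1)
    degenerate = False
    rho = 0.0
    if sigma_h > 0 and sigma_v > 0:
        rho = float(cov[0, 1] / (sigma_h * sigma_v))
    if sigma_h == 0 or sigma_v == 0 or 1 - rho**2 <= 1e-12:
        degenerate = True
        area = 0.0
        axes = (0.0, 0.0)
        orient = 0.0
    else:
        area = k * np.pi * sigma_h * sigma_v * np.sqrt(1 - rho**2)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        axes = tuple(np.sqrt(k * np.maximum(evals, 0.0)))
        orient = float(np.degrees(np.arctan2(evecs[1, 0], evecs[0, 0])))
    return BCEAResult(
        center=(float(center[0]), float(center[1])),
        sigma_h=sigma_h,
        sigma_v=sigma_v,
        rho=rho,
        coverage=coverage,
        chi2_quantile=k,
        area=float(area),
        semi_axes=axes,
        orientation_deg=orient,
        degenerate=degenerate,
    )


def select_bcea_level(
    prl_ecc: float, threshold: float = DEFAULT_BCEA_ECC_THRESHOLD
) -> float:
    """0.95 for PRLs strictly beyond ``threshold`` degrees, else 0.63.

    The tie (ecc == threshold) resolves to 0.63.
    """
    if prl_ecc < 0:
        raise InvalidParameterError("eccentricity must be non-negative")
    return 0.95 if prl_ecc > threshold else 0.63


def bcea_to_roi(
    bcea: BCEAResult, step: float = DEFAULT_RASTER_STEP, role: str = "PRL"
) -> VisualFieldROI:
    """Rasterise the fitted ellipse: a cell belongs to the ROI iff its centre
    has squared Mahalanobis distance <= the chi-square quantile."""
    if bcea.degenerate or bcea.area == 0:
        raise EmptyROIError("degenerate BCEA cannot be rasterised")
    cx, cy = bcea.center
    a = max(bcea.semi_axes)
    xs = np.arange(cx - a - step, cx + a + step, step)
    ys = np.arange(cy - a - step, cy + a + step, step)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    cov = np.array(
        [
            [bcea.sigma_h**2, bcea.rho * bcea.sigma_h * bcea.sigma_v],
            [bcea.rho * bcea.sigma_h * bcea.sigma_v, bcea.sigma_v**2],
        ]
    )
    d = pts - np.array([cx, cy])
    m2 = np.einsum("ij,jk,ik->i", d, np.linalg.inv(cov), d)
    cells = pts[m2 <= bcea.chi2_quantile]
    return VisualFieldROI(
        role=role,
        cells=cells,
        step=step,
        center=bcea.center,
        meta={"coverage": bcea.coverage},
    )


def overlay_eyes(
    left: SensitivityMap, right: SensitivityMap, pair_radius: float = 0.5
) -> SensitivityMap:
    """Fuse the two monocular maps after aligning their foveae at the origin.

    Loci are paired by nearest neighbour within ``pair_radius`` degrees; a
    fused locus is seen iff seen in at least one eye and carries the max
    threshold across paired eyes. Unpaired loci pass through unchanged.
    """
    for m in (left, right):
        if m.fovea is None:
            raise AlignmentError(f"{m.eye} map lacks a fovea reference")
    lc, rc = left.centered(), right.centered()
    xy = lc.xy.copy()
    thr = lc.threshold_db.copy()
    seen = lc.seen.copy()
    used = np.zeros(rc.n, dtype=bool)
    if rc.n:
        tree = cKDTree(rc.xy)
        dist, idx = tree.query(lc.xy)
        for i, (d, j) in enumerate(zip(dist, idx)):
            if d <= pair_radius and not used[j]:
                used[j] = True
                seen[i] = seen[i] or rc.seen[j]
                cand = rc.threshold_db[j]
                if not np.isnan(cand):
                    thr[i] = cand if np.isnan(thr[i]) else max(thr[i], cand)
    extra = ~used
    return SensitivityMap(
        eye="fused",
        xy=np.vstack([xy, rc.xy[extra]]),
        threshold_db=np.concatenate([thr, rc.threshold_db[extra]]),
        seen=np.concatenate([seen, rc.seen[extra]]),
    )


def _nearest_seen(cells: np.ndarray, fused: SensitivityMap) -> np.ndarray:
    tree = cKDTree(fused.xy)
    _, idx = tree.query(cells)
    return fused.seen[idx]


def trim_to_seeing(roi: VisualFieldROI, fused: SensitivityMap) -> VisualFieldROI:
    """Remove cells whose nearest fused locus is unseen (bilateral scotoma).

    Idempotent; raises if nothing survives (PRL entirely inside the lesion).
    """
    if roi.n_cells == 0:
        raise EmptyROIError("ROI has no cells")
    keep = _nearest_seen(roi.cells, fused)
    if not keep.any():
        raise EmptyROIError(f"{roi.role} lies entirely inside the bilateral scotoma")
    cells = roi.cells[keep]
    meta = dict(roi.meta, trimmed=bool((~keep).any()))
    return VisualFieldROI(
        role=roi.role,
        cells=cells,
        step=roi.step,
        center=tuple(cells.mean(axis=0)),
        meta=meta,
    )


def _candidate_transforms(n_candidates: int):
    """(name, 2x2 matrix, preference rank). Eccentricity-preserving maps
    about the fovea: vertical-meridian flip, horizontal-meridian flip, then
    rotations at equal angular steps (identity excluded)."""
    out = [
        ("flip_vertical", np.array([[-1.0, 0.0], [0.0, 1.0]]), 0),
        ("flip_horizontal", np.array([[1.0, 0.0], [0.0, -1.0]]), 1),
    ]
    for k in range(1, n_candidates):
        ang = 2 * np.pi * k / n_candidates
        c, s = np.cos(ang), np.sin(ang)
        out.append((f"rot_{360.0 * k / n_candidates:.1f}", np.array([[c, -s], [s, c]]), 2 + k))
    return out


def place_url(
    prl: VisualFieldROI,
    fused: SensitivityMap,
    n_candidates: int = 72,
) -> VisualFieldROI:
    """Duplicate the PRL shape elsewhere at equal eccentricity.

    Candidates are the two meridian flips plus ``n_candidates - 1`` rotations
    about the fovea. The winner maximises the number of seen fused loci inside
    the transformed ROI; ties resolve by the sum of thresholds at those loci,
    then by preference order (vertical flip, horizontal flip, smallest
    rotation angle).
    """
    if prl.n_cells == 0:
        raise EmptyROIError("PRL is empty")
    if n_candidates < 1:
        raise InvalidParameterError("n_candidates must be >= 1")
    fused = fused.centered()
    best = None
    prl_center = np.asarray(prl.center, dtype=float)
    for name, mat, rank in _candidate_transforms(n_candidates):
        # a candidate landing back on the PRL itself is no control region
        if np.hypot(*(prl_center @ mat.T - prl_center)) < prl.step / 2:
            continue
        cells = prl.cells @ mat.T
        roi = VisualFieldROI(
            role="URL",
            cells=cells,
            step=prl.step,
            center=tuple(np.asarray(prl.center) @ mat.T),
            meta=dict(prl.meta, transform=name),
        )
        inside = roi.contains(fused.xy)
        n_seen = int(np.sum(inside & fused.seen))
        thr_sum = float(np.nansum(fused.threshold_db[inside & fused.seen]))
        key = (n_seen, thr_sum, -rank)
        if best is None or key > best[0]:
            best = (key, roi)
    if best is None or best[0][0] == 0:
        raise NoValidURLError("no candidate contains any seen locus")
    return best[1]


def roi_eccentricity(
    roi: VisualFieldROI,
    fovea: Tuple[float, float] = (0.0, 0.0),
    px_per_deg: float = 1.0,
) -> float:
    """Distance from fovea to ROI centre, converted to degrees."""
    if px_per_deg <= 0:
        raise InvalidParameterError("px_per_deg must be positive")
    d = np.asarray(roi.center, dtype=float) - np.asarray(fovea, dtype=float)
    return float(np.hypot(*d) / px_per_deg)
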