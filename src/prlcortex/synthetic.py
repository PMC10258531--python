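"""Synthetic study-data generator.

Produces every input the analysis pipeline consumes — fixation clouds,
radial sensitivity grids with central scotomas, analytically retinotopic
triangulated hemisphere meshes, per-vertex structural metrics with injected
group effects, and a participant design table — so all downstream stages are
testable without any imaging data.

The surface model places vertices in the visual field with areal density
proportional to the squared cortical magnification ``M(e) = A / (e + e0)``,
so the central field is over-represented as in real V1. Each hemisphere is
triangulated on a flattened sheet ``(u, theta)`` with ``u = A log(1 + e/e0)``
(cortical distance along the eccentricity axis); a ring of extra vertices
around the sheet is flagged non-V1 to exercise boundary pruning downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay

from .errors import GenerationError, InvalidParameterError
from .types import FixationCloud, RetinotopicSurface, SensitivityMap

# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------


@dataclass
class SurfaceSpec:
    """Parameters of a synthetic retinotopic hemisphere pair."""

    n_vertices_per_hemi: int = 2000
    max_ecc_deg: float = 90.0
    magnification_A_mm: float = 17.3
    magnification_e0_deg: float = 0.75
    seed: int = 0

    def validate(self) -> None:
        if self.n_vertices_per_hemi < 300:
            raise InvalidParameterError("n_vertices_per_hemi must be >= 300")
        if self.max_ecc_deg <= 0:
            raise InvalidParameterError("max_ecc_deg must be positive")
        if self.magnification_e0_deg <= 0:
            raise InvalidParameterError("magnification e0 must be positive")
        if self.magnification_A_mm <= 0:
            raise InvalidParameterError("magnification A must be positive")


@dataclass
class CohortSpec:
    """Parameters of a synthetic 2x2 (diagnosis x onset) cohort.

    Effect knobs are additive offsets on the named per-vertex metric, in that
    metric's own units. ``effect_diagnosis`` shifts every MD participant;
    ``effect_onset_x_diagnosis`` is a pure diagnosis-by-onset pattern applied
    with opposite signs to early- vs late-onset MD participants.
    ``participant_sd`` is a per-participant random intercept shared across a
    participant's vertices; ``noise_sd`` is independent vertex-level noise.
    """

    n_per_cell: int = 5
    effect_diagnosis: float = 0.0
    effect_onset_x_diagnosis: float = 0.0
    effect_diagnosis_ficvf: float = 0.0
    effect_onset_x_diagnosis_ficvf: float = 0.0
    effect_diagnosis_odi: float = 0.0
    effect_onset_x_diagnosis_odi: float = 0.0
    noise_sd: float = 0.05
    participant_sd: float = 0.05
    seed: int = 0
    scotoma_radius_deg: float = 5.0
    prl_ecc_deg: float = 8.0
    prl_sd_deg: float = 2.0
    n_fixations: int = 400
    fixation_sigma_deg: float = 1.0

    def validate(self) -> None:
        if self.n_per_cell < 2:
            raise InvalidParameterError("n_per_cell must be >= 2")
        if self.noise_sd < 0 or self.participant_sd < 0:
            raise InvalidParameterError("noise SDs must be non-negative")
        if self.scotoma_radius_deg < 0:
            raise InvalidParameterError("scotoma_radius_deg must be >= 0")
        if self.n_fixations < 3:
            raise InvalidParameterError("n_fixations must be >= 3")


# --------------------------------------------------------------------------
# fixations
# --------------------------------------------------------------------------


def gen_fixations(
    center: Tuple[float, float],
    sigma_h: float,
    sigma_v: float,
    rho: float,
    n: int,
    seed=None,
    eye: str = "left",
) -> FixationCloud:
    """Draw ``n`` fixation points from a bivariate normal in field degrees."""
    if n < 3:
        raise InvalidParameterError("need at least 3 fixation points")
    if abs(rho) >= 1:
        raise InvalidParameterError("|rho| must be < 1")
    if sigma_h < 0 or sigma_v < 0:
        raise InvalidParameterError("sigmas must be non-negative")
    rng = np.random.default_rng(seed)
    cov = np.array(
        [
            [sigma_h**2, rho * sigma_h * sigma_v],
            [rho * sigma_h * sigma_v, sigma_v**2],
        ]
    )
    pts = rng.multivariate_normal(center, cov, size=n, method="svd")
    return FixationCloud(eye=eye, points=pts)


# --------------------------------------------------------------------------
# sensitivity grid
# --------------------------------------------------------------------------

_RING_RADII = (1.0, 3.0, 5.0, 7.0, 9.0)
_LOCI_PER_RING = 16


def default_grid(grid_loci: int = 65) -> np.ndarray:
    """Radial test grid: one central locus plus concentric 16-locus rings,
    truncated to ``grid_loci`` points in ring order."""
    if grid_loci < 1:
        raise InvalidParameterError("grid_loci must be >= 1")
    pts = [(0.0, 0.0)]
    for r in _RING_RADII:
        ang = np.linspace(0, 2 * np.pi, _LOCI_PER_RING, endpoint=False)
        pts.extend(zip(r * np.cos(ang), r * np.sin(ang)))
        if len(pts) >= grid_loci:
            break
    if len(pts) < grid_loci:
        raise InvalidParameterError(
            f"radial grid supports at most {len(pts)} loci, requested {grid_loci}"
        )
    return np.asarray(pts[:grid_loci], dtype=float)


def gen_sensitivity_map(
    scotoma_radius: float,
    grid_loci: int = 65,
    seed=None,
    eye: str = "left",
) -> SensitivityMap:
    """Sensitivity map on the radial grid with a central absolute scotoma.

    Loci with eccentricity strictly below ``scotoma_radius`` are "not seen"
    (NaN threshold); the rest carry positive dB thresholds that decline with
    eccentricity plus Gaussian noise.
    """
    if scotoma_radius < 0:
        raise InvalidParameterError("scotoma_radius must be >= 0")
    rng = np.random.default_rng(seed)
    xy = default_grid(grid_loci)
    ecc = np.hypot(xy[:, 0], xy[:, 1])
    seen = ecc >= scotoma_radius - 1e-9  # ring radii fall exactly on the cutoff
    thr = 30.0 - 2.0 * ecc + rng.normal(0.0, 1.0, size=len(xy))
    thr = np.clip(thr, 1.0, 36.0)
    thr[~seen] = np.nan
    return SensitivityMap(eye=eye, xy=xy, threshold_db=thr, seen=seen)


# --------------------------------------------------------------------------
# surface
# --------------------------------------------------------------------------


def magnification(ecc, A: float = 17.3, e0: float = 0.75):
    """Linear cortical magnification M(e) = A / (e + e0), mm per degree."""
    return A / (np.asarray(ecc, dtype=float) + e0)


def annulus_weight(lo: float, hi: float, A: float = 17.3, e0: float = 0.75) -> float:
    """Closed form of the unnormalised vertex mass in an annulus:
    integral of M(e)^2 * 2*pi*e de over [lo, hi] (constants dropped)."""

    def F(e):
        return np.log(e + e0) + e0 / (e + e0)

    return float(F(hi) - F(lo))


def _sample_ecc(n: int, spec: SurfaceSpec, rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF sampling of eccentricity with density ~ M(e)^2 * e."""
    grid = np.linspace(0.0, spec.max_ecc_deg, 4096)
    pdf = grid / (grid + spec.magnification_e0_deg) ** 2
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2 * np.diff(grid))])
    cdf /= cdf[-1]
    return np.interp(rng.random(n), cdf, grid)


def _flatmap_u(ecc, spec: SurfaceSpec):
    return spec.magnification_A_mm * np.log1p(
        np.asarray(ecc, dtype=float) / spec.magnification_e0_deg
    )


def _flatmap_u_inv(u, spec: SurfaceSpec):
    return spec.magnification_e0_deg * np.expm1(
        np.asarray(u, dtype=float) / spec.magnification_A_mm
    )


def _gen_hemisphere(
    hemi: str, spec: SurfaceSpec, rng: np.random.Generator, id_offset: int
):
    n = spec.n_vertices_per_hemi
    if n < 4:
        raise GenerationError("too few vertices to triangulate")
    ecc = _sample_ecc(n, spec, rng)
    # lh carries the right hemifield (theta in (-90, 90)); rh the left one,
    # parameterised continuously as t in (90, 270) then wrapped.
    t0 = -90.0 if hemi == "lh" else 90.0
    t = t0 + 180.0 * rng.random(n)

    u = _flatmap_u(ecc, spec)
    umax = _flatmap_u(spec.max_ecc_deg, spec)
    # normalised flat-sheet coordinates for triangulation
    uu = u / umax
    vv = (t - t0) / 180.0

    # non-V1 boundary ring around the unit square
    n_edge = max(8, int(np.ceil(np.sqrt(n))))
    m = 1.0 / np.sqrt(n)
    edge = np.linspace(-m, 1 + m, n_edge)
    ring = []
    for e in edge:
        ring.extend([(e, -m), (e, 1 + m)])
    for e in edge[1:-1]:
        ring.extend([(-m, e), (1 + m, e)])
    ring = np.asarray(ring, dtype=float)

    pts = np.vstack([np.column_stack([uu, vv]), ring])
    v1 = np.zeros(len(pts), dtype=bool)
    v1[:n] = True

    ring_u = np.clip(ring[:, 0], 0.0, 1.0) * umax
    ring_ecc = np.clip(_flatmap_u_inv(ring_u, spec), 0.0, spec.max_ecc_deg)
    ring_t = t0 + ring[:, 1] * 180.0

    all_ecc = np.concatenate([ecc, ring_ecc])
    all_t = np.concatenate([t, ring_t])
    angle = np.where(all_t > 180.0, all_t - 360.0, all_t)

    try:
        tri = Delaunay(pts)
    except Exception as exc:  # pragma: no cover - scipy failure modes
        raise GenerationError(f"triangulation failed: {exc}") from exc

    ids = np.arange(len(pts)) + id_offset
    verts = pd.DataFrame(
        {
            "hemi": hemi,
            "ecc_deg": all_ecc,
            "angle_deg": angle,
            "v1": v1,
        },
        index=pd.Index(ids, name="vertex_id"),
    )
    return verts, tri.simplices + id_offset


def gen_surface(spec: SurfaceSpec) -> RetinotopicSurface:
    """Generate both hemispheres of an annotated, triangulated surface."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lh_v, lh_t = _gen_hemisphere("lh", spec, rng, 0)
    rh_v, rh_t = _gen_hemisphere("rh", spec, rng, len(lh_v))
    return RetinotopicSurface(pd.concat([lh_v, rh_v]), np.vstack([lh_t, rh_t]))


# --------------------------------------------------------------------------
# metric maps
# --------------------------------------------------------------------------


def _baselines(ecc: np.ndarray) -> Dict[str, np.ndarray]:
    # central field thicker / denser, mild eccentricity gradients
    return {
        "thickness_mm": 1.9 + 1.1 * np.exp(-ecc / 20.0),
        "ficvf": 0.30 + 0.25 * np.exp(-ecc / 30.0),
        "odi": 0.50 - 0.15 * np.exp(-ecc / 30.0),
    }


def gen_metric_maps(
    surface: RetinotopicSurface,
    cohort: CohortSpec,
    diagnosis: str,
    onset: str,
    seed=None,
) -> RetinotopicSurface:
    """Attach thickness/FICVF/ODI maps with the cohort's injected effects.

    Offsets: MD participants get ``effect_diagnosis`` added everywhere; MD
    participants additionally get ``+effect_onset_x_diagnosis`` (early) or
    ``-effect_onset_x_diagnosis`` (late). A per-participant random intercept
    (``participant_sd``) and vertex-level Gaussian noise (``noise_sd``) are
    added on top. FICVF/ODI use their own effect knobs and are clipped to
    [0, 1].
    """
    cohort.validate()
    if surface.has_metrics:
        raise InvalidParameterError("surface already carries metric maps")
    if diagnosis not in ("MD", "HC") or onset not in ("early", "late"):
        raise InvalidParameterError("diagnosis must be MD/HC, onset early/late")
    rng = np.random.default_rng(seed)
    out = surface.copy()
    ecc = out.vertices["ecc_deg"].to_numpy()
    base = _baselines(ecc)
    is_md = diagnosis == "MD"
    ixn_sign = 1.0 if onset == "early" else -1.0
    effects = {
        "thickness_mm": (cohort.effect_diagnosis, cohort.effect_onset_x_diagnosis),
        "ficvf": (cohort.effect_diagnosis_ficvf, cohort.effect_onset_x_diagnosis_ficvf),
        "odi": (cohort.effect_diagnosis_odi, cohort.effect_onset_x_diagnosis_odi),
    }
    for name, b in base.items():
        diag_off, ixn_off = effects[name]
        shift = (diag_off + ixn_sign * ixn_off) if is_md else 0.0
        intercept = rng.normal(0.0, cohort.participant_sd) if cohort.participant_sd else 0.0
        vals = b + shift + intercept + (
            rng.normal(0.0, cohort.noise_sd, size=len(b)) if cohort.noise_sd else 0.0
        )
        if name in ("ficvf", "odi"):
            vals = np.clip(vals, 0.0, 1.0)
        out.vertices[name] = vals
    return out


# --------------------------------------------------------------------------
# cohort bundles
# --------------------------------------------------------------------------


@dataclass
class ParticipantData:
    participant: str
    diagnosis: str
    onset: str
    age: float
    acuity_logmar: float
    matched_id: Optional[str]
    better_eye: str
    fixations: Dict[str, FixationCloud]
    sensitivity: Dict[str, SensitivityMap]
    surface: RetinotopicSurface
    scotoma_radius_deg: float


@dataclass
class StudyBundle:
    participants: List[ParticipantData]
    design: pd.DataFrame
    cohort_spec: CohortSpec
    surface_spec: SurfaceSpec

    def get(self, participant: str) -> ParticipantData:
        for p in self.participants:
            if p.participant == participant:
                return p
        raise KeyError(participant)


def gen_cohort(cohort: CohortSpec, surface_spec: SurfaceSpec) -> StudyBundle:
    """Generate a full matched-pairs study bundle.

    Per (onset x n_per_cell) slot an MD participant and a matched control are
    generated. The control shares the MD participant's surface geometry (its
    own metric maps are drawn independently), mirroring the design in which a
    control inherits its matched patient's ROI definitions.
    """
    cohort.validate()
    surface_spec.validate()
    rng = np.random.default_rng(cohort.seed)
    participants: List[ParticipantData] = []
    rows = []
    idx = 0
    for onset in ("early", "late"):
        for j in range(cohort.n_per_cell):
            idx += 1
            md_id = f"MD{idx:03d}"
            hc_id = f"HC{idx:03d}"
            geom = replace(surface_spec, seed=int(rng.integers(2**31)))
            base_surface = gen_surface(geom)

            md_age = float(rng.normal(48 if onset == "early" else 70, 8))
            hc_age = md_age + float(rng.normal(0, 3))
            md_acuity = float(rng.normal(1.1 if onset == "early" else 0.75, 0.2))
            hc_acuity = abs(float(rng.normal(0.05, 0.08)))

            prl_ecc = max(
                float(rng.normal(cohort.prl_ecc_deg, cohort.prl_sd_deg)),
                cohort.scotoma_radius_deg + 1.0,
            )
            prl_angle = float(rng.uniform(-np.pi, np.pi))
            prl_center = (prl_ecc * np.cos(prl_angle), prl_ecc * np.sin(prl_angle))

            for pid, diagnosis, age, acuity, matched in (
                (md_id, "MD", md_age, md_acuity, hc_id),
                (hc_id, "HC", hc_age, hc_acuity, md_id),
            ):
                is_md = diagnosis == "MD"
                center = prl_center if is_md else (0.0, 0.0)
                scot = cohort.scotoma_radius_deg if is_md else 0.0
                fixations = {
                    eye: gen_fixations(
                        center,
                        cohort.fixation_sigma_deg,
                        cohort.fixation_sigma_deg,
                        0.0,
                        cohort.n_fixations,
                        seed=int(rng.integers(2**31)),
                        eye=eye,
                    )
                    for eye in ("left", "right")
                }
                sensitivity = {
                    eye: gen_sensitivity_map(
                        scot, seed=int(rng.integers(2**31)), eye=eye
                    )
                    for eye in ("left", "right")
                }
                surface = gen_metric_maps(
                    base_surface,
                    cohort,
                    diagnosis,
                    onset,
                    seed=int(rng.integers(2**31)),
                )
                participants.append(
                    ParticipantData(
                        participant=pid,
                        diagnosis=diagnosis,
                        onset=onset,
                        age=age,
                        acuity_logmar=acuity,
                        matched_id=matched,
                        better_eye="left",
                        fixations=fixations,
                        sensitivity=sensitivity,
                        surface=surface,
                        scotoma_radius_deg=scot,
                    )
                )
                rows.append(
                    {
                        "participant": pid,
                        "diagnosis": diagnosis,
                        "onset": onset,
                        "age": round(age, 1),
                        "acuity_logmar": round(acuity, 2),
                        "matched_id": matched,
                        "better_eye": "left",
                    }
                )
    design = pd.DataFrame(rows).set_index("participant")
    return StudyBundle(participants, design, cohort, surface_spec)


# --------------------------------------------------------------------------
# fast participant-by-ROI table generator (for calibration studies)
# --------------------------------------------------------------------------


def simulate_roi_table(
    cohort: CohortSpec,
    n_within: int = 2,
    seed=None,
    within_effects: Optional[np.ndarray] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Draw ROI-level outcomes directly from the cohort's statistical model.

    Bypasses surface generation: each participant contributes one value per
    within-level, ``value = 1 + b_p + roi_offset + cell_offsets + noise`` with
    ``b_p ~ N(0, participant_sd)`` and residual SD ``noise_sd``. Returns
    ``(metric table, design table)`` in the layout the stats module consumes.
    Used by the type-I / power calibration suites, where generating a full
    surface per replicate would be wasteful.
    """
    cohort.validate()
    rng = np.random.default_rng(seed)
    if within_effects is None:
        within_effects = np.zeros(n_within)
    within_effects = np.asarray(within_effects, dtype=float)
    if len(within_effects) != n_within:
        raise InvalidParameterError("within_effects length must equal n_within")
    roi_labels = [f"roi{k + 1}" for k in range(n_within)]
    rows, design_rows = [], []
    idx = 0
    for diagnosis in ("MD", "HC"):
        for onset in ("early", "late"):
            for _ in range(cohort.n_per_cell):
                idx += 1
                pid = f"S{idx:03d}"
                shift = 0.0
                if diagnosis == "MD":
                    shift += cohort.effect_diagnosis
                    shift += (
                        cohort.effect_onset_x_diagnosis
                        if onset == "early"
                        else -cohort.effect_onset_x_diagnosis
                    )
                b_p = rng.normal(0.0, cohort.participant_sd)
                for k, roi in enumerate(roi_labels):
                    val = 1.0 + b_p + shift + within_effects[k]
                    val += rng.normal(0.0, cohort.noise_sd)
                    rows.append(
                        {
                            "participant": pid,
                            "roi_label": roi,
                            "metric": "thickness_norm",
                            "value": val,
                            "n_vertices": 50,
                            "mean_ecc": 8.0,
                        }
                    )
                design_rows.append(
                    {
                        "participant": pid,
                        "diagnosis": diagnosis,
                        "onset": onset,
                        "age": 60.0,
                        "acuity_logmar": 0.5,
                        "matched_id": "",
                        "better_eye": "left",
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(design_rows).set_index("participant")
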