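"""End-to-end orchestration: visual-field ROI definition per participant,
transfer to cortex, metric extraction, and the group statistics battery."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd

from . import fixation as fx
from . import metrics as mx
from . import stats as st
from . import transfer as tf
from .errors import PRLCortexError, InvalidParameterError
from .io import write_json, write_roi_labels
from .synthetic import ParticipantData, StudyBundle
from .types import CorticalROI, VisualFieldROI


@dataclass
class PipelineConfig:
    bcea_ecc_threshold_deg: float = fx.DEFAULT_BCEA_ECC_THRESHOLD
    raster_step_deg: float = fx.DEFAULT_RASTER_STEP
    min_roi_vertices: int = tf.DEFAULT_MIN_ROI_VERTICES
    lpz_per_hemi: int = tf.DEFAULT_LPZ_SIZE_PER_HEMI
    ecc_band_mode: str = "none"  # none | fixed | quantile
    n_bands: int = 8
    url_candidates: int = 72
    metrics: Sequence[str] = ("thickness_norm", "ficvf", "odi")
    alpha: float = 0.05
    q_fdr: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.raster_step_deg <= 0 or self.bcea_ecc_threshold_deg <= 0:
            raise InvalidParameterError("thresholds must be positive")
        if self.ecc_band_mode not in ("none", "fixed", "quantile"):
            raise InvalidParameterError("ecc_band_mode must be none|fixed|quantile")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})
        cfg.validate()
        return cfg


@dataclass
class PipelineResult:
    metric_table: pd.DataFrame
    design: pd.DataFrame
    rois: Dict[str, List[CorticalROI]]
    anova: Dict[str, st.AnovaResult]
    ancova: Dict[str, st.AnovaResult]
    lpz_anova: Dict[str, st.AnovaResult]
    posthoc: Dict[str, pd.DataFrame]
    provenance: dict = field(default_factory=dict)


def define_field_rois(
    p: ParticipantData, config: PipelineConfig
) -> Dict[str, VisualFieldROI]:
    """PRL and URL in visual-field space for one (patient) participant."""
    cloud = p.fixations[p.better_eye]
    center = fx.compute_prl_center(cloud)
    ecc = float((center**2).sum() ** 0.5)
    coverage = fx.select_bcea_level(ecc, config.bcea_ecc_threshold_deg)
    bcea = fx.fit_bcea(cloud, coverage)
    prl = fx.bcea_to_roi(bcea, step=config.raster_step_deg, role="PRL")
    eyes = p.sensitivity
    fused = fx.overlay_eyes(eyes["left"], eyes["right"])
    prl = fx.trim_to_seeing(prl, fused)
    url = fx.place_url(prl, fused, n_candidates=config.url_candidates)
    return {"PRL": prl, "URL": url}


def _cortical_rois(
    p: ParticipantData, field_rois: Dict[str, VisualFieldROI], config: PipelineConfig
) -> List[CorticalROI]:
    out = []
    for roi in field_rois.values():
        c = tf.map_roi_to_surface(roi, p.surface)
        c = tf.dilate_roi(c, p.surface, min_vertices=config.min_roi_vertices)
        out.append(c)
    out.append(tf.define_lpz(p.surface, n_per_hemi=config.lpz_per_hemi))
    if config.ecc_band_mode != "none":
        ranges = (
            tf.DEFAULT_ECC_BAND_LIMITS if config.ecc_band_mode == "fixed" else None
        )
        out.extend(
            tf.define_eccentricity_bands(p.surface, config.n_bands, fixed_ranges=ranges)
        )
    return out


def run_pipeline(
    bundle: StudyBundle,
    config: Optional[PipelineConfig] = None,
    out_dir=None,
) -> PipelineResult:
    """Run every stage on an in-memory study bundle.

    Patients are processed first; each control inherits its matched patient's
    visual-field ROI definitions. Any per-participant failure aborts the run
    with an error naming the participant.
    """
    config = config or PipelineConfig()
    config.validate()

    field_rois: Dict[str, Dict[str, VisualFieldROI]] = {}
    rois: Dict[str, List[CorticalROI]] = {}
    tables = []
    provenance: dict = {"config": asdict(config), "participants": {}}

    ordered = sorted(
        bundle.participants, key=lambda p: (p.diagnosis != "MD", p.participant)
    )
    for p in ordered:
        try:
            if p.diagnosis == "MD":
                fr = define_field_rois(p, config)
            else:
                if p.matched_id not in field_rois:
                    raise InvalidParameterError(
                        f"control {p.participant} has no matched patient ROI "
                        f"({p.matched_id!r})"
                    )
                fr = field_rois[p.matched_id]
            field_rois[p.participant] = fr
            surface = mx.normalize_thickness(p.surface)
            p_norm = ParticipantData(**{**p.__dict__, "surface": surface})
            cr = _cortical_rois(p_norm, fr, config)
            rois[p.participant] = cr
            tables.append(
                mx.extract_roi_metrics(
                    surface, cr, metrics=config.metrics, participant=p.participant
                )
            )
            provenance["participants"][p.participant] = {
                "coverage": fr["PRL"].meta.get("coverage"),
                "url_transform": fr["URL"].meta.get("transform"),
                "dilation": {
                    c.label: {
                        "rings": c.meta.get("dilation_rings"),
                        "pruned": c.meta.get("dilation_pruned"),
                    }
                    for c in cr
                    if "dilation_rings" in c.meta
                },
            }
        except PRLCortexError as exc:
            raise type(exc)(f"participant {p.participant}: {exc}") from exc

    metric_table = pd.concat(tables, ignore_index=True)
    design = bundle.design

    long = metric_table.merge(design.reset_index(), on="participant")
    anova, ancova, lpz_anova, posthoc = {}, {}, {}, {}
    design_cov = st.prepare_covariates(metric_table, design)
    long_cov = metric_table.merge(design_cov.reset_index(), on="participant")
    for metric in config.metrics:
        sub = long[(long["metric"] == metric)]
        pu = sub[sub["roi_label"].isin(["cPRL", "cURL"])]
        anova[metric] = st.mixed_anova(
            pu, "value", "roi_label", "participant", ["diagnosis", "onset"]
        )
        subc = long_cov[long_cov["metric"] == metric]
        puc = subc[subc["roi_label"].isin(["cPRL", "cURL"])]
        ancova[metric] = st.mixed_ancova(
            puc, "value", "roi_label", "participant", ["diagnosis", "onset"],
            covariates=["cov_ecc", "cov_size"],
        )
        lpz = sub[sub["roi_label"] == "LPZ"]
        lpz_anova[metric] = st.mixed_anova(
            lpz, "value", "roi_label", "participant", ["diagnosis", "onset"]
        )
        if config.ecc_band_mode != "none":
            bands = sub[sub["roi_label"].str.startswith("ecc-band-")]
            posthoc[metric] = st.posthoc_fdr(
                bands, "value", "diagnosis", "roi_label", q=config.q_fdr
            )

    result = PipelineResult(
        metric_table=metric_table,
        design=design,
        rois=rois,
        anova=anova,
        ancova=ancova,
        lpz_anova=lpz_anova,
        posthoc=posthoc,
        provenance=provenance,
    )
    if out_dir is not None:
        _write_result(result, out_dir)
    return result


def _write_result(result: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.metric_table.to_csv(out / "metrics.csv", index=False)
    write_roi_labels(result.rois, out / "roi_labels.csv")
    for name, group in (
        ("anova", result.anova),
        ("ancova", result.ancova),
        ("lpz_anova", result.lpz_anova),
    ):
        for metric, res in group.items():
            res.table.to_csv(out / f"{name}_{metric}.csv", index=False)
    for metric, df in result.posthoc.items():
        df.to_csv(out / f"posthoc_{metric}.csv", index=False)
    write_json(result.provenance, out / "provenance.json")
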