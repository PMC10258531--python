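"""Plain-CSV I/O for every pipeline artefact, plus input validation.

File formats (all headers mandatory):

- fixations.csv: participant, eye, x_deg, y_deg
- sensitivity.csv: participant, eye, x_deg, y_deg, threshold_db, seen
- surface.csv: participant, vertex_id, hemi, ecc_deg, angle_deg, v1_flag
  [, thickness_mm, ficvf, odi]
- triangles.csv: participant, v1, v2, v3
- design.csv: participant, diagnosis, onset, age, acuity_logmar, matched_id,
  better_eye
- roi_labels.csv: participant, vertex_id, hemi, label
- metrics.csv: participant, roi_label, metric, value, n_vertices, mean_ecc
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .errors import ValidationError
from .types import CorticalROI, FixationCloud, RetinotopicSurface, SensitivityMap
from .synthetic import StudyBundle

_SCHEMAS = {
    "fixations": ["participant", "eye", "x_deg", "y_deg"],
    "sensitivity": ["participant", "eye", "x_deg", "y_deg", "threshold_db", "seen"],
    "surface": ["participant", "vertex_id", "hemi", "ecc_deg", "angle_deg", "v1_flag"],
    "triangles": ["participant", "v1", "v2", "v3"],
    "design": ["participant", "diagnosis", "onset", "age", "acuity_logmar",
               "matched_id", "better_eye"],
    "metrics": ["participant", "roi_label", "metric", "value", "n_vertices",
                "mean_ecc"],
}


def _read(path, kind: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: file not found")
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValidationError(f"{path}: parse error: {exc}") from exc
    missing = [c for c in _SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return df


# --------------------------------------------------------------------------
# bundle writing
# --------------------------------------------------------------------------


def write_bundle(bundle: StudyBundle, out_dir) -> Dict[str, Path]:
    """Serialise a synthetic study bundle into the CSV formats above."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fix_rows, sens_rows, surf_frames, tri_rows = [], [], [], []
    for p in bundle.participants:
        for eye, cloud in p.fixations.items():
            for x, y in cloud.points:
                fix_rows.append((p.participant, eye, x, y))
        for eye, smap in p.sensitivity.items():
            for (x, y), thr, seen in zip(smap.xy, smap.threshold_db, smap.seen):
                sens_rows.append((p.participant, eye, x, y, thr, bool(seen)))
        v = p.surface.vertices.reset_index()
        v.insert(0, "participant", p.participant)
        v = v.rename(columns={"v1": "v1_flag"})
        surf_frames.append(v)
        for a, b, c in p.surface.triangles:
            tri_rows.append((p.participant, a, b, c))
    paths = {
        "fixations": out / "fixations.csv",
        "sensitivity": out / "sensitivity.csv",
        "surface": out / "surface.csv",
        "triangles": out / "triangles.csv",
        "design": out / "design.csv",
    }
    pd.DataFrame(fix_rows, columns=_SCHEMAS["fixations"]).to_csv(
        paths["fixations"], index=False
    )
    pd.DataFrame(sens_rows, columns=_SCHEMAS["sensitivity"]).to_csv(
        paths["sensitivity"], index=False
    )
    pd.concat(surf_frames).to_csv(paths["surface"], index=False)
    pd.DataFrame(tri_rows, columns=["participant", "v1", "v2", "v3"]).to_csv(
        paths["triangles"], index=False
    )
    bundle.design.reset_index().to_csv(paths["design"], index=False)
    return paths


# --------------------------------------------------------------------------
# bundle reading
# --------------------------------------------------------------------------


def read_bundle(in_dir) -> StudyBundle:
    """Load a study bundle previously written by :func:`write_bundle`."""
    from .synthetic import CohortSpec, ParticipantData, SurfaceSpec

    d = Path(in_dir)
    fix = _read(d / "fixations.csv", "fixations")
    sens = _read(d / "sensitivity.csv", "sensitivity")
    surf = _read(d / "surface.csv", "surface")
    tris = _read(d / "triangles.csv", "triangles")
    design = _read(d / "design.csv", "design").set_index("participant")

    participants: List[ParticipantData] = []
    for pid, row in design.iterrows():
        fixations = {
            eye: FixationCloud(eye=eye, points=sub[["x_deg", "y_deg"]].to_numpy())
            for eye, sub in fix[fix["participant"] == pid].groupby("eye")
        }
        sensitivity = {
            eye: SensitivityMap(
                eye=eye,
                xy=sub[["x_deg", "y_deg"]].to_numpy(),
                threshold_db=sub["threshold_db"].to_numpy(),
                seen=sub["seen"].to_numpy(dtype=bool),
            )
            for eye, sub in sens[sens["participant"] == pid].groupby("eye")
        }
        v = surf[surf["participant"] == pid].set_index("vertex_id")
        v = v.rename(columns={"v1_flag": "v1"}).drop(columns=["participant"])
        t = tris[tris["participant"] == pid][["v1", "v2", "v3"]].to_numpy()
        participants.append(
            ParticipantData(
                participant=pid,
                diagnosis=row["diagnosis"],
                onset=row["onset"],
                age=float(row["age"]),
                acuity_logmar=float(row["acuity_logmar"]),
                matched_id=row["matched_id"] or None,
                better_eye=row.get("better_eye", "left"),
                fixations=fixations,
                sensitivity=sensitivity,
                surface=RetinotopicSurface(v, t),
                scotoma_radius_deg=float("nan"),
            )
        )
    return StudyBundle(participants, design, CohortSpec(), SurfaceSpec())


def write_roi_labels(rois_by_participant: Dict[str, List[CorticalROI]], path) -> Path:
    rows = []
    for pid, rois in rois_by_participant.items():
        for roi in rois:
            for hemi, ids in sorted(roi.vertices.items()):
                for v in ids:
                    rows.append((pid, int(v), hemi, roi.label))
    df = pd.DataFrame(rows, columns=["participant", "vertex_id", "hemi", "label"])
    df.to_csv(path, index=False)
    return Path(path)


def write_json(obj, path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
    return path


# --------------------------------------------------------------------------
# validation
# --------------------------------------------------------------------------


@dataclass
class ValidationReport:
    violations: List[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, msg: str) -> None:
        self.violations.append(msg)


def validate_inputs(paths: Dict[str, str]) -> ValidationReport:
    """Schema and cross-file referential-integrity checks.

    ``paths`` maps kind (``fixations``, ``sensitivity``, ``surface``,
    ``triangles``, ``design``) to file paths. All violations are collected
    rather than failing fast.
    """
    report = ValidationReport()
    frames: Dict[str, pd.DataFrame] = {}
    for kind, path in paths.items():
        if kind not in _SCHEMAS:
            report.add(f"unknown input kind {kind!r}")
            continue
        try:
            frames[kind] = _read(path, kind)
        except ValidationError as exc:
            report.add(str(exc))
    design = frames.get("design")
    if design is not None:
        ids = set(design["participant"])
        for pid, m in zip(design["participant"], design["matched_id"]):
            if isinstance(m, str) and m and m not in ids:
                report.add(f"design: participant {pid} has unknown matched_id {m}")
        for kind in ("fixations", "sensitivity", "surface"):
            if kind in frames:
                extra = set(frames[kind]["participant"]) - ids
                for pid in sorted(extra):
                    report.add(f"{kind}: participant {pid} not present in design")
    if "fixations" in frames:
        counts = frames["fixations"].groupby(["participant", "eye"]).size()
        for (pid, eye), c in counts.items():
            if c < 3:
                report.add(
                    f"fixations: participant {pid} eye {eye} has {c} < 3 points"
                )
    return report
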