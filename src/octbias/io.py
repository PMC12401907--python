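"""Pullback JSON schema (versioned) and measurement CSV writers.

Schema, version 1::

    {"schema_version": 1, "patient_id": str, "phase": "pre"|"post",
     "landmark_z_mm": float|null, "analysis_span_mm": [lo, hi]|null,
     "seed": int|null,
     "frames": [{"frame_id": int, "z_mm": float,
                 "catheter": {"cx": float, "cy": float, "r": float},
                 "contours": {"intima": [[x, y], ...],
                              "media": [[x, y], ...]|null,
                              "eem": [[x, y], ...]|null},
                 "calcium_arcs": [[start_deg, end_deg], ...],
                 "dissection": {"present": bool, "arc": [s, e]|null,
                                "depth": str|null,
                                "catheter_subintimal": bool}|null}, ...]}
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .coregistration import PairedFrame, Pullback
from .errors import SchemaError
from .geometry import (
    CatheterPose,
    Contour,
    ContourRole,
    CrossSection,
    Dissection,
    MeasurementRecord,
)

SCHEMA_VERSION = 1

#: Stable measurement CSV column order.
MEASUREMENT_COLUMNS = [
    "patient_id", "phase", "frame_id", "z_mm",
    "d_cib", "d_cio", "d_cmb", "d_cmo",
    "touch_angle_deg", "la_mm2", "min_ld_mm", "max_ld_mm", "le",
    "eem_csa_mm2", "avd_mm", "bias_angle_deg", "dissection_present",
]


class _CatheterModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    cx: float
    cy: float
    r: float = Field(gt=0)


class _ContoursModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    intima: list[tuple[float, float]]
    media: Optional[list[tuple[float, float]]] = None
    eem: Optional[list[tuple[float, float]]] = None


class _DissectionModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    present: bool
    arc: Optional[tuple[float, float]] = None
    depth: Optional[str] = None
    catheter_subintimal: bool = False


class _FrameModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    frame_id: int
    z_mm: float = Field(ge=0)
    catheter: _CatheterModel
    contours: _ContoursModel
    calcium_arcs: list[tuple[float, float]] = Field(default_factory=list)
    dissection: Optional[_DissectionModel] = None


class PullbackModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    schema_version: int
    patient_id: str
    phase: str
    landmark_z_mm: Optional[float] = None
    analysis_span_mm: Optional[tuple[float, float]] = None
    seed: Optional[int] = None
    frames: list[_FrameModel]


def _frame_to_domain(fm: _FrameModel) -> CrossSection:
    contours = fm.contours
    return CrossSection(
        frame_id=fm.frame_id, z=fm.z_mm,
        intima=Contour(contours.intima, ContourRole.INTIMA),
        media=(None if contours.media is None
               else Contour(contours.media, ContourRole.MEDIA)),
        eem=None if contours.eem is None else Contour(contours.eem, ContourRole.EEM),
        catheter=CatheterPose(center=(fm.catheter.cx, fm.catheter.cy),
                              radius=fm.catheter.r),
        calcium_arcs=tuple(fm.calcium_arcs),
        dissection=None if fm.dissection is None else Dissection(
            present=fm.dissection.present, arc=fm.dissection.arc,
            depth=fm.dissection.depth,
            catheter_subintimal=fm.dissection.catheter_subintimal))


def read_pullback(path: str | Path) -> Pullback:
    """Load and validate one pullback JSON file."""
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise SchemaError(f"{path}: unreadable JSON ({exc})") from exc
    try:
        model = PullbackModel.model_validate(raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise SchemaError(f"{path}: {loc}: {first['msg']}") from exc
    if model.schema_version != SCHEMA_VERSION:
        raise SchemaError(f"{path}: unsupported schema_version {model.schema_version}")
    return Pullback(
        patient_id=model.patient_id, phase=model.phase,
        frames=tuple(_frame_to_domain(f) for f in model.frames),
        landmark_z=model.landmark_z_mm, analysis_span=model.analysis_span_mm)


def _round(x: float, ndigits: int = 6) -> float:
    return round(float(x), ndigits)


def pullback_to_dict(pullback: Pullback, seed: Optional[int] = None) -> dict:
    frames = []
    for cs in pullback.frames:
        dissection = None
        if cs.dissection is not None:
            dissection = {
                "present": cs.dissection.present,
                "arc": (None if cs.dissection.arc is None
                        else [_round(cs.dissection.arc[0]), _round(cs.dissection.arc[1])]),
                "depth": None if cs.dissection.depth is None else cs.dissection.depth.value,
                "catheter_subintimal": cs.dissection.catheter_subintimal,
            }
        frames.append({
            "frame_id": cs.frame_id,
            "z_mm": _round(cs.z),
            "catheter": {"cx": _round(cs.catheter.center[0]),
                         "cy": _round(cs.catheter.center[1]),
                         "r": _round(cs.catheter.radius)},
            "contours": {
                "intima": [[_round(x), _round(y)] for x, y in cs.intima.vertices],
                "media": (None if cs.media is None else
                          [[_round(x), _round(y)] for x, y in cs.media.vertices]),
                "eem": (None if cs.eem is None else
                        [[_round(x), _round(y)] for x, y in cs.eem.vertices]),
            },
            "calcium_arcs": [[_round(s), _round(e)] for s, e in cs.calcium_arcs],
            "dissection": dissection,
        })
    return {
        "schema_version": SCHEMA_VERSION,
        "patient_id": pullback.patient_id,
        "phase": pullback.phase,
        "landmark_z_mm": None if pullback.landmark_z is None else _round(pullback.landmark_z),
        "analysis_span_mm": (None if pullback.analysis_span is None else
                             [_round(pullback.analysis_span[0]),
                              _round(pullback.analysis_span[1])]),
        "seed": seed,
        "frames": frames,
    }


def write_pullback(pullback: Pullback, path: str | Path,
                   seed: Optional[int] = None) -> None:
    """Serialize a pullback to JSON (deterministic byte layout)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(pullback_to_dict(pullback, seed=seed),
                               sort_keys=True, separators=(",", ":")) + "\n")


def record_to_row(patient_id: str, phase: str, cs: CrossSection,
                  rec: MeasurementRecord) -> dict:
    """One measurement CSV row in the stable column order."""
    return {
        "patient_id": patient_id,
        "phase": phase,
        "frame_id": cs.frame_id,
        "z_mm": cs.z,
        "d_cib": rec.d_cib, "d_cio": rec.d_cio,
        "d_cmb": rec.d_cmb, "d_cmo": rec.d_cmo,
        "touch_angle_deg": rec.touch_angle,
        "la_mm2": rec.la,
        "min_ld_mm": rec.min_ld, "max_ld_mm": rec.max_ld, "le": rec.le,
        "eem_csa_mm2": rec.eem_csa, "avd_mm": rec.avd,
        "bias_angle_deg": None if rec.bias is None else rec.bias.bias_angle,
        "dissection_present": (None if cs.dissection is None
                               else bool(cs.dissection.present)),
    }


def measurements_frame(rows: list[dict]) -> pd.DataFrame:
    """Measurement rows as a DataFrame with the stable column order."""
    if not rows:
        return pd.DataFrame(columns=MEASUREMENT_COLUMNS)
    return pd.DataFrame(rows)[MEASUREMENT_COLUMNS]


PAIRED_COLUMNS = (["patient_id", "grid_z_mm", "pre_frame_id", "post_frame_id"]
                  + MEASUREMENT_COLUMNS[4:-1]
                  + ["post_dissection", "post_dissection_depth",
                     "post_dissection_arc_start", "post_dissection_arc_end",
                     "post_catheter_subintimal"])


def pairs_rows(patient_id: str, pairs: list[PairedFrame]) -> list[dict]:
    """Paired-frames rows: grid position, frame ids, pre measurements, post labels."""
    rows = []
    for p in pairs:
        row = record_to_row(patient_id, "pre", p.pre, p.pre_measure)
        row.update({
            "grid_z_mm": p.grid_z,
            "pre_frame_id": p.pre.frame_id,
            "post_frame_id": p.post.frame_id,
            "post_dissection": p.post_dissection.present,
            "post_dissection_depth": (None if p.post_dissection.depth is None
                                      else p.post_dissection.depth.value),
            "post_dissection_arc_start": (None if p.post_dissection.arc is None
                                          else p.post_dissection.arc[0]),
            "post_dissection_arc_end": (None if p.post_dissection.arc is None
                                        else p.post_dissection.arc[1]),
            "post_catheter_subintimal": p.post_dissection.catheter_subintimal,
        })
        rows.append(row)
    return rows


def pairs_to_frame(patient_id: str, pairs: list[PairedFrame]) -> pd.DataFrame:
    """Paired-frames table for one patient (stable column order)."""
    return pairs_frame(pairs_rows(patient_id, pairs))


def pairs_frame(rows: list[dict]) -> pd.DataFrame:
    if not rows:
        return pd.DataFrame(columns=PAIRED_COLUMNS)
    return pd.DataFrame(rows)[PAIRED_COLUMNS]
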