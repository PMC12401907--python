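"""Synthetic paired pre/post pullback generator.

Builds multi-patient studies with the structure the analysis stage assumes:
smooth noisy-elliptical lumen contours, concentric-offset media/EEM with
visibility probabilities, an eccentric catheter along a per-patient bias
direction, and a post-procedure dissection mechanism driven by the
catheter-to-media distance at the bias site (d_cmb) and the catheter-intima
contact arc (touch angle).  Dissection flaps are placed inside the pre-phase
bias quadrant; the catheter is flagged subintimal with a configurable
entrapment probability.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import geometry
from .angles import normalize_deg
from .coregistration import Pullback
from .errors import PreconditionError
from .geometry import (
    CatheterPose,
    Contour,
    ContourRole,
    CrossSection,
    Dissection,
    DissectionDepth,
    PatientMeta,
)


@dataclass(frozen=True)
class LumenModel:
    mean_radius_mm: float = 1.5
    radius_sd_mm: float = 0.3          # between-patient
    radius_bounds_mm: tuple[float, float] = (1.0, 2.2)
    frame_radius_jitter: float = 0.04  # relative, per frame
    ellipticity_range: tuple[float, float] = (0.0, 0.22)
    noise_amplitude_mm: float = 0.03   # Fourier harmonic SD


@dataclass(frozen=True)
class WallModel:
    intima_media_thickness_mm: float = 0.25
    thickness_jitter_sd_mm: float = 0.015
    media_eem_thickness_mm: float = 0.30
    p_media_visible: float = 0.85
    p_eem_visible: float = 0.6


@dataclass(frozen=True)
class CalciumModel:
    p_calcified_frame: float = 0.5
    arc_span_range_deg: tuple[float, float] = (30.0, 150.0)


@dataclass(frozen=True)
class BiasModel:
    """Catheter clearance (distance to intima along the bias ray) sampler.

    clearance = clearance_min + Exponential(clearance_scale * patient severity),
    clipped so the catheter stays off-center by at least ``min_offset_mm``.
    """

    clearance_min_mm: float = 0.32
    clearance_scale_mm: float = 0.95
    min_offset_mm: float = 0.08
    drift_sd_deg: float = 5.0
    patient_severity_sigma: float = 0.35  # lognormal sigma of per-patient scale
    concentric_prob: float = 0.0          # probability of an exactly centered catheter


@dataclass(frozen=True)
class DissectionModel:
    mode: str = "threshold"          # "threshold" | "logistic"
    tau_d_mm: float = 0.72           # dissect when d_cmb falls below
    tau_a_deg: float = 98.2          # dissect when touch angle exceeds
    logistic_slope_d: float = 25.0   # per mm of (tau_d - d_cmb)
    logistic_slope_a: float = 0.15   # per degree of (touch - tau_a)
    logistic_intercept: Optional[float] = None  # calibrated when None
    target_event_fraction: float = 56.0 / 388.0


@dataclass(frozen=True)
class FlapModel:
    arc_span_range_deg: tuple[float, float] = (25.0, 60.0)
    center_jitter_deg: float = 40.0  # flap center within bias_angle +/- this
    p_entrapment: float = 1.0


@dataclass(frozen=True)
class ObserverNoise:
    vertex_jitter_sd_mm: float = 0.01
    label_flip_prob: float = 0.0


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_patients: int = 21
    frames_per_patient: tuple[int, int] = (12, 25)  # inclusive range
    n_vertices: int = 128
    catheter_radius_mm: float = geometry.DEFAULT_CATHETER_RADIUS
    frame_spacing_mm: float = 1.0
    lumen: LumenModel = field(default_factory=LumenModel)
    wall: WallModel = field(default_factory=WallModel)
    calcium: CalciumModel = field(default_factory=CalciumModel)
    bias: BiasModel = field(default_factory=BiasModel)
    dissection: DissectionModel = field(default_factory=DissectionModel)
    flap: FlapModel = field(default_factory=FlapModel)
    observer: ObserverNoise = field(default_factory=ObserverNoise)
    post_enlargement_range: tuple[float, float] = (1.01, 1.05)


@dataclass(frozen=True)
class PatientState:
    """Per-patient latent parameters drawn once per study."""

    patient_id: str
    bias_direction_deg: float
    lumen_radius_mm: float
    severity: float
    meta: PatientMeta


@dataclass(frozen=True)
class FrameTruth:
    """Ground-truth mechanism record for one generated frame pair."""

    patient_id: str
    frame_id: int
    z_mm: float
    d_cib_true: Optional[float]
    d_cmb_true: Optional[float]
    touch_angle_true: float
    bias_angle_deg: Optional[float]
    dissection: bool
    mechanism: str  # d_cmb | touch | both | none | logistic | bias_undefined
    entrapped: bool
    flap_arc: Optional[tuple[float, float]]


@dataclass(frozen=True)
class StudyData:
    config: GeneratorConfig
    patients: tuple[PatientState, ...]
    pre_pullbacks: tuple[Pullback, ...]
    post_pullbacks: tuple[Pullback, ...]
    ground_truth: pd.DataFrame


# ---------------------------------------------------------------------------
# patient and frame construction

_BURR_SIZES = np.array([1.25, 1.5, 1.75, 2.0])
_BURR_PROBS = np.array([0.1, 0.25, 0.4, 0.25])  # mean 1.70, sd ~0.23


def _draw_patient(config: GeneratorConfig, index: int,
                  rng: np.random.Generator) -> PatientState:
    pid = f"P{index + 1:03d}"
    lm = config.lumen
    radius = float(np.clip(rng.normal(lm.mean_radius_mm, lm.radius_sd_mm),
                           *lm.radius_bounds_mm))
    burr = float(rng.choice(_BURR_SIZES, p=_BURR_PROBS))
    rvd = float(np.clip(rng.normal(3.18, 0.47), 2.25, 4.5))
    meta = PatientMeta(patient_id=pid, final_burr_size=burr,
                       reference_vessel_diameter=rvd)
    return PatientState(
        patient_id=pid,
        bias_direction_deg=float(rng.uniform(0.0, 360.0)),
        lumen_radius_mm=radius,
        severity=float(rng.lognormal(0.0, config.bias.patient_severity_sigma)),
        meta=meta)


def _lumen_radii(config: GeneratorConfig, patient: PatientState,
                 rng: np.random.Generator) -> np.ndarray:
    """Radial profile r(theta) of the intima on the vertex angle grid."""
    lm = config.lumen
    n = config.n_vertices
    theta = np.arange(n) * (2.0 * math.pi / n)
    r0 = patient.lumen_radius_mm * (1.0 + rng.normal(0.0, lm.frame_radius_jitter))
    ell = rng.uniform(*lm.ellipticity_range)
    phi_e = rng.uniform(0.0, math.pi)
    a = r0 * (1.0 + ell / 2.0)
    b = r0 * (1.0 - ell / 2.0)
    r = a * b / np.sqrt((b * np.cos(theta - phi_e)) ** 2
                        + (a * np.sin(theta - phi_e)) ** 2)
    for k in (3, 4, 5):
        amp = rng.normal(0.0, lm.noise_amplitude_mm)
        r += amp * np.cos(k * theta + rng.uniform(0.0, 2.0 * math.pi))
    return np.maximum(r, 0.55 * r0)


def _contour_from_radii(radii: np.ndarray, role: ContourRole) -> Contour:
    n = len(radii)
    theta = np.arange(n) * (2.0 * math.pi / n)
    verts = np.stack([radii * np.cos(theta), radii * np.sin(theta)], axis=1)
    return Contour(verts, role)


def generate_frame(config: GeneratorConfig, patient: PatientState,
                   rng: np.random.Generator, frame_id: int = 0,
                   z: float = 0.0) -> CrossSection:
    """One pre-phase cross-section with the catheter on the bias ray.

    Geometry violating the containment invariants is resampled (bounded
    retries).
    """
    wall = config.wall
    for _ in range(20):
        radii = _lumen_radii(config, patient, rng)
        intima = _contour_from_radii(radii, ContourRole.INTIMA)
        media = eem = None
        t_im = max(0.10, wall.intima_media_thickness_mm
                   + rng.normal(0.0, wall.thickness_jitter_sd_mm))
        media_visible = rng.uniform() < wall.p_media_visible
        eem_visible = media_visible and rng.uniform() < wall.p_eem_visible
        if media_visible:
            media = _contour_from_radii(radii + t_im, ContourRole.MEDIA)
        if eem_visible:
            eem = _contour_from_radii(
                radii + t_im + wall.media_eem_thickness_mm, ContourRole.EEM)

        c = geometry.centroid(intima)
        phi = normalize_deg(patient.bias_direction_deg
                            + rng.normal(0.0, config.bias.drift_sd_deg))
        if rng.uniform() < config.bias.concentric_prob:
            catheter = CatheterPose(center=c, radius=config.catheter_radius_mm)
        else:
            r_b = geometry.ray_contour_distance(c, phi, intima)
            clearance = (config.bias.clearance_min_mm
                         + rng.exponential(config.bias.clearance_scale_mm
                                           * patient.severity))
            clearance = float(np.clip(clearance, config.bias.clearance_min_mm,
                                      max(config.bias.clearance_min_mm,
                                          r_b - config.bias.min_offset_mm)))
            offset = r_b - clearance
            u = np.array([math.cos(math.radians(phi)), math.sin(math.radians(phi))])
            catheter = CatheterPose(center=tuple(np.asarray(c) + offset * u),
                                    radius=config.catheter_radius_mm)

        calcium = ()
        if rng.uniform() < config.calcium.p_calcified_frame:
            span = rng.uniform(*config.calcium.arc_span_range_deg)
            start = rng.uniform(0.0, 360.0)
            calcium = ((normalize_deg(start), normalize_deg(start + span)),)

        try:
            return CrossSection(frame_id=frame_id, z=z, intima=intima,
                                media=media, eem=eem, catheter=catheter,
                                calcium_arcs=calcium)
        except PreconditionError:
            continue
    raise PreconditionError("could not sample a valid frame in 20 retries")


# ---------------------------------------------------------------------------
# dissection mechanism


def _mechanism(pre: CrossSection) -> tuple[Optional[float], Optional[float],
                                           float, Optional[float]]:
    """(d_cib, d_cmb, touch_angle, bias_angle) measured on the pre frame."""
    rec = geometry.measure_frame(pre)
    bias_angle = rec.bias.bias_angle if rec.bias is not None else None
    return rec.d_cib, rec.d_cmb, rec.touch_angle, bias_angle


def _logistic_logit(d_cmb: Optional[float], touch: float,
                    model: DissectionModel, intercept: float) -> float:
    logit = intercept + model.logistic_slope_a * (touch - model.tau_a_deg)
    if d_cmb is not None:
        logit += model.logistic_slope_d * (model.tau_d_mm - d_cmb)
    return logit


def _decide(d_cmb: Optional[float], touch: float, bias_defined: bool,
            model: DissectionModel, rng: np.random.Generator,
            intercept: float = 0.0) -> tuple[bool, str]:
    """Dissection decision plus the mechanism label that fired."""
    if not bias_defined:
        return False, "bias_undefined"
    if model.mode == "threshold":
        hit_d = d_cmb is not None and d_cmb < model.tau_d_mm
        hit_a = touch > model.tau_a_deg
        if hit_d and hit_a:
            return True, "both"
        if hit_d:
            return True, "d_cmb"
        if hit_a:
            return True, "touch"
        return False, "none"
    if model.mode == "logistic":
        p = 1.0 / (1.0 + math.exp(-_logistic_logit(d_cmb, touch, model, intercept)))
        return bool(rng.uniform() < p), "logistic"
    raise PreconditionError(f"unknown dissection mode {model.mode!r}")


def _build_post(pre: CrossSection, dissected: bool, bias_angle: Optional[float],
                config: GeneratorConfig, rng: np.random.Generator,
                z_shift: float) -> tuple[CrossSection, bool, Optional[tuple[float, float]]]:
    """Post-phase frame: enlarged lumen, dissection annotation, entrapment flag."""
    scale = rng.uniform(*config.post_enlargement_range)

    def enlarge(contour: Optional[Contour]) -> Optional[Contour]:
        if contour is None:
            return None
        return Contour(contour.vertices * scale, contour.role)

    entrapped = False
    dissection = Dissection(present=False)
    flap = None
    if dissected:
        assert bias_angle is not None
        span = rng.uniform(*config.flap.arc_span_range_deg)
        center = bias_angle + rng.uniform(-config.flap.center_jitter_deg,
                                          config.flap.center_jitter_deg)
        flap = (normalize_deg(center - span / 2.0),
                normalize_deg(center + span / 2.0))
        entrapped = rng.uniform() < config.flap.p_entrapment
        dissection = Dissection(present=True, arc=flap,
                                depth=DissectionDepth.INTIMAL,
                                catheter_subintimal=entrapped)
    post = CrossSection(
        frame_id=pre.frame_id, z=pre.z + z_shift,
        intima=enlarge(pre.intima), media=enlarge(pre.media),
        eem=enlarge(pre.eem), catheter=pre.catheter,
        calcium_arcs=pre.calcium_arcs, dissection=dissection)
    return post, entrapped, flap


def apply_dissection_model(pre: CrossSection, config: GeneratorConfig,
                           rng: np.random.Generator, z_shift: float = 0.0
                           ) -> tuple[CrossSection, FrameTruth]:
    """Derive the post-procedure frame and its ground-truth record from a pre frame.

    Threshold mode dissects iff ``d_cmb < tau_d`` or ``touch_angle > tau_a``
    (touch-only when no media is visible); logistic mode draws a Bernoulli with
    logit linear in ``(tau_d - d_cmb)`` and ``(touch - tau_a)``.
    """
    d_cib, d_cmb, touch, bias_angle = _mechanism(pre)
    intercept = config.dissection.logistic_intercept or 0.0
    dissected, mechanism = _decide(d_cmb, touch, bias_angle is not None,
                                   config.dissection, rng, intercept)
    post, entrapped, flap = _build_post(pre, dissected, bias_angle, config,
                                        rng, z_shift)
    truth = FrameTruth(
        patient_id="", frame_id=pre.frame_id, z_mm=pre.z,
        d_cib_true=d_cib, d_cmb_true=d_cmb, touch_angle_true=touch,
        bias_angle_deg=bias_angle, dissection=dissected, mechanism=mechanism,
        entrapped=entrapped, flap_arc=flap)
    return post, truth


# ---------------------------------------------------------------------------
# study assembly


def _calibrate_intercept(logits_without_intercept: np.ndarray,
                         target: float) -> float:
    """Intercept making the mean logistic probability equal the target rate."""

    def mean_rate(b0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + logits_without_intercept)))))

    return float(brentq(lambda b0: mean_rate(b0) - target, -50.0, 50.0, xtol=1e-10))


def generate_study(config: GeneratorConfig) -> StudyData:
    """Full multi-patient paired study with ground truth, deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    patients = tuple(_draw_patient(config, i, rng)
                     for i in range(config.n_patients))

    # pass 1: pre frames and mechanism values
    pre_frames: dict[str, list[CrossSection]] = {}
    mech: dict[str, list[tuple]] = {}
    for patient in patients:
        lo, hi = config.frames_per_patient
        n_frames = int(rng.integers(lo, hi + 1))
        frames, values = [], []
        for i in range(n_frames):
            cs = generate_frame(config, patient, rng, frame_id=i,
                                z=i * config.frame_spacing_mm)
            frames.append(cs)
            values.append(_mechanism(cs))
        pre_frames[patient.patient_id] = frames
        mech[patient.patient_id] = values

    model = config.dissection
    intercept = model.logistic_intercept or 0.0
    if model.mode == "logistic" and model.logistic_intercept is None:
        raw = np.array([
            _logistic_logit(d_cmb, touch, model, 0.0)
            for vals in mech.values()
            for (_, d_cmb, touch, bias_angle) in vals if bias_angle is not None])
        intercept = _calibrate_intercept(raw, model.target_event_fraction)

    # pass 2: dissection decisions, post frames, pullback assembly
    pre_pullbacks, post_pullbacks, truths = [], [], []
    for patient in patients:
        frames = pre_frames[patient.patient_id]
        z_shift = float(rng.uniform(0.0, 2.0))
        post_frames = []
        for cs, (d_cib, d_cmb, touch, bias_angle) in zip(frames,
                                                         mech[patient.patient_id]):
            dissected, mechanism = _decide(d_cmb, touch, bias_angle is not None,
                                           model, rng, intercept)
            post, entrapped, flap = _build_post(cs, dissected, bias_angle,
                                                config, rng, z_shift)
            post_frames.append(post)
            truths.append(FrameTruth(
                patient_id=patient.patient_id, frame_id=cs.frame_id, z_mm=cs.z,
                d_cib_true=d_cib, d_cmb_true=d_cmb, touch_angle_true=touch,
                bias_angle_deg=bias_angle, dissection=dissected,
                mechanism=mechanism, entrapped=entrapped, flap_arc=flap))
        landmark = frames[len(frames) // 3].z
        span = (frames[0].z, frames[-1].z)
        pre_pullbacks.append(Pullback(
            patient_id=patient.patient_id, phase="pre", frames=tuple(frames),
            landmark_z=landmark, analysis_span=span))
        post_pullbacks.append(Pullback(
            patient_id=patient.patient_id, phase="post",
            frames=tuple(post_frames), landmark_z=landmark + z_shift,
            analysis_span=(span[0] + z_shift, span[1] + z_shift)))

    gt = pd.DataFrame([{
        "patient_id": t.patient_id, "frame_id": t.frame_id, "z_mm": t.z_mm,
        "d_cib_true": t.d_cib_true, "d_cmb_true": t.d_cmb_true,
        "touch_angle_true": t.touch_angle_true,
        "bias_angle_deg": t.bias_angle_deg, "dissection": t.dissection,
        "mechanism": t.mechanism, "entrapped": t.entrapped,
        "flap_start_deg": None if t.flap_arc is None else t.flap_arc[0],
        "flap_end_deg": None if t.flap_arc is None else t.flap_arc[1],
    } for t in truths])
    return StudyData(config=config, patients=patients,
                     pre_pullbacks=tuple(pre_pullbacks),
                     post_pullbacks=tuple(post_pullbacks), ground_truth=gt)


def perturb_pullback(pullback: Pullback, rng: np.random.Generator,
                     vertex_jitter_sd_mm: float = 0.01,
                     label_flip_prob: float = 0.0) -> Pullback:
    """Second-reader surrogate: jitter contour vertices, optionally flip labels."""

    def jitter(contour: Optional[Contour]) -> Optional[Contour]:
        if contour is None:
            return None
        noise = rng.normal(0.0, vertex_jitter_sd_mm, size=contour.vertices.shape)
        return Contour(contour.vertices + noise, contour.role)

    frames = []
    for cs in pullback.frames:
        dissection = cs.dissection
        if dissection is not None and rng.uniform() < label_flip_prob:
            dissection = dataclasses.replace(dissection,
                                             present=not dissection.present)
        frames.append(CrossSection(
            frame_id=cs.frame_id, z=cs.z, intima=jitter(cs.intima),
            media=jitter(cs.media), eem=jitter(cs.eem), catheter=cs.catheter,
            calcium_arcs=cs.calcium_arcs, dissection=dissection))
    return dataclasses.replace(pullback, frames=tuple(frames))
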