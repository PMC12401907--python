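"""Cross-section data model and per-frame measurement operators.

All coordinates are frame-local Cartesian millimetres.  Angles are degrees
counterclockwise from +x.  Contours are simple closed polygons stored
counterclockwise (normalized on construction).  Missing media/EEM quantities
are ``None``, never sentinel numbers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Point, Polygon

from .angles import Arc, normalize_deg
from .errors import (
    BiasUndefinedError,
    DomainError,
    InvalidContourError,
    PreconditionError,
)

logger = logging.getLogger(__name__)

#: OCT imaging catheter radius in mm.
DEFAULT_CATHETER_RADIUS = 0.45
#: Catheter-centroid offsets below this are treated as concentric (no bias).
DEFAULT_EPS_BIAS = 0.05
#: Radial gap below which the catheter is considered in contact with the intima.
DEFAULT_GAP_TOL = 0.02
#: Angular sampling step for touch angle and diameter sweeps.
DEFAULT_DTHETA = 0.5


class ContourRole(str, Enum):
    INTIMA = "intima"
    MEDIA = "media"
    EEM = "eem"


class DissectionDepth(str, Enum):
    INTIMAL = "intimal"
    MEDIAL = "medial"
    ADVENTITIAL = "adventitial"
    INTRAMURAL_HEMATOMA = "intramural_hematoma"


def _signed_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class Contour:
    """Simple closed polygon with a vessel-layer role.

    Vertices are normalized counterclockwise; the last vertex implicitly
    connects back to the first.
    """

    vertices: np.ndarray
    role: ContourRole = ContourRole.INTIMA

    def __post_init__(self) -> None:
        verts = np.asarray(self.vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2:
            raise InvalidContourError("vertices must be an (n, 2) array")
        # drop a duplicated closing vertex
        if verts.shape[0] >= 2 and np.allclose(verts[0], verts[-1]):
            verts = verts[:-1]
        if verts.shape[0] < 3:
            raise InvalidContourError("contour needs at least 3 vertices")
        if not np.all(np.isfinite(verts)):
            raise InvalidContourError("contour has non-finite coordinates")
        area = _signed_area(verts)
        if abs(area) < 1e-12:
            raise InvalidContourError("degenerate (zero-area) contour")
        if not Polygon(verts).is_valid:
            raise InvalidContourError("self-intersecting contour")
        if area < 0:
            verts = verts[::-1].copy()
        verts.setflags(write=False)
        object.__setattr__(self, "vertices", verts)
        object.__setattr__(self, "role", ContourRole(self.role))

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    def as_polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def transformed(self, angle_deg: float = 0.0,
                    translation: Sequence[float] = (0.0, 0.0)) -> "Contour":
        """Rigidly rotate (about origin) then translate the contour."""
        t = math.radians(angle_deg)
        rot = np.array([[math.cos(t), -math.sin(t)],
                        [math.sin(t), math.cos(t)]])
        verts = self.vertices @ rot.T + np.asarray(translation, dtype=float)
        return Contour(verts, self.role)


@dataclass(frozen=True)
class CatheterPose:
    """Imaging catheter cross-section: center and radius in mm."""

    center: tuple[float, float]
    radius: float = DEFAULT_CATHETER_RADIUS

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise DomainError("catheter radius must be > 0")
        object.__setattr__(self, "center",
                           (float(self.center[0]), float(self.center[1])))


@dataclass(frozen=True)
class Dissection:
    """Post-procedure dissection annotation for one frame."""

    present: bool
    arc: Optional[Arc] = None
    depth: Optional[DissectionDepth] = None
    catheter_subintimal: bool = False

    def __post_init__(self) -> None:
        if self.arc is not None:
            object.__setattr__(
                self, "arc",
                (normalize_deg(self.arc[0]), normalize_deg(self.arc[1])))
        if self.depth is not None:
            object.__setattr__(self, "depth", DissectionDepth(self.depth))


@dataclass(frozen=True)
class CrossSection:
    """One cross-sectional frame: contours, catheter pose, annotations."""

    frame_id: int
    z: float
    intima: Contour
    catheter: CatheterPose
    media: Optional[Contour] = None
    eem: Optional[Contour] = None
    calcium_arcs: tuple[Arc, ...] = ()
    dissection: Optional[Dissection] = None

    def __post_init__(self) -> None:
        if self.z < 0:
            raise DomainError("z must be >= 0")
        if self.intima.role != ContourRole.INTIMA:
            raise InvalidContourError("intima contour must carry role 'intima'")
        subintimal = self.dissection is not None and self.dissection.catheter_subintimal
        if not subintimal:
            if not self.intima.as_polygon().contains(Point(self.catheter.center)):
                raise PreconditionError(
                    f"frame {self.frame_id}: catheter center outside intima")
        object.__setattr__(
            self, "calcium_arcs",
            tuple((normalize_deg(s), normalize_deg(e)) for s, e in self.calcium_arcs))


@dataclass(frozen=True)
class BiasGeometry:
    """Catheter bias direction and quadrant about the vessel center."""

    vessel_center: tuple[float, float]
    bias_angle: float
    offset: float

    @property
    def quadrant(self) -> Arc:
        """Closed 90-degree sector centered on the bias ray."""
        return (normalize_deg(self.bias_angle - 45.0),
                normalize_deg(self.bias_angle + 45.0))


@dataclass(frozen=True)
class MeasurementRecord:
    """All per-frame indices; bias/media/EEM-dependent fields may be None."""

    d_cib: Optional[float]
    d_cio: Optional[float]
    d_cmb: Optional[float]
    d_cmo: Optional[float]
    touch_angle: float
    la: float
    min_ld: float
    max_ld: float
    le: float
    eem_csa: Optional[float] = None
    avd: Optional[float] = None
    bias: Optional[BiasGeometry] = None


@dataclass(frozen=True)
class PatientMeta:
    """Per-patient procedural metadata."""

    patient_id: str
    final_burr_size: float
    reference_vessel_diameter: float
    btv: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "btv",
            compute_btv(self.final_burr_size, self.reference_vessel_diameter))


# ---------------------------------------------------------------------------
# Operators


def polygon_area(contour: Contour) -> float:
    """Area (mm^2) enclosed by the contour, via the shoelace formula."""
    return abs(_signed_area(contour.vertices))


def centroid(contour: Contour) -> tuple[float, float]:
    """Area centroid of the polygon."""
    v = contour.vertices
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    cx = float(np.sum((x + xn) * cross) / (6.0 * a))
    cy = float(np.sum((y + yn) * cross) / (6.0 * a))
    return cx, cy


def _ray_distances(origin: Sequence[float], directions_deg: np.ndarray,
                   contour: Contour) -> np.ndarray:
    """First-intersection distance for rays from ``origin``, one per direction.

    Vectorized over directions and polygon edges; returns NaN where a ray never
    crosses the boundary (origin outside, numerically grazing geometry).
    """
    o = np.asarray(origin, dtype=float)
    theta = np.radians(np.asarray(directions_deg, dtype=float))
    u = np.stack([np.cos(theta), np.sin(theta)], axis=1)        # (d, 2)
    p = contour.vertices                                         # (e, 2)
    q = np.roll(p, -1, axis=0)
    v = q - p                                                    # edge vectors
    w = p - o                                                    # (e, 2)
    # solve t*u - s*v = w per (direction, edge) via 2x2 cross products
    denom = u[:, 0, None] * v[None, :, 1] - u[:, 1, None] * v[None, :, 0]
    wxv = w[:, 0] * v[:, 1] - w[:, 1] * v[:, 0]                  # (e,)
    wxu = w[None, :, 0] * u[:, 1, None] - w[None, :, 1] * u[:, 0, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = wxv[None, :] / denom
        s = wxu / denom
    # s-window widened by eps: a ray through a vertex junction must hit at
    # least one adjacent edge despite rounding; min-t makes overlap harmless
    valid = (np.abs(denom) > 1e-14) & (s >= -1e-9) & (s <= 1.0 + 1e-9) & (t > 1e-12)
    t = np.where(valid, t, np.inf)
    best = t.min(axis=1)
    return np.where(np.isfinite(best), best, np.nan)


def ray_contour_distance(origin: Sequence[float], direction_deg: float,
                         contour: Contour) -> float:
    """Distance from ``origin`` along ``direction_deg`` to the contour boundary.

    ``origin`` must lie strictly inside the contour.
    """
    if not contour.as_polygon().contains(Point(float(origin[0]), float(origin[1]))):
        raise PreconditionError("ray origin must lie strictly inside the contour")
    d = _ray_distances(origin, np.array([direction_deg]), contour)[0]
    if not np.isfinite(d):
        raise PreconditionError("ray does not intersect the contour boundary")
    return float(d)


def bias_geometry(cs: CrossSection, eps_bias: float = DEFAULT_EPS_BIAS) -> BiasGeometry:
    """Bias direction of the catheter relative to the vessel (lumen) center."""
    cx, cy = centroid(cs.intima)
    dx = cs.catheter.center[0] - cx
    dy = cs.catheter.center[1] - cy
    offset = math.hypot(dx, dy)
    if offset < eps_bias:
        raise BiasUndefinedError(
            f"catheter-centroid offset {offset:.4f} mm < eps_bias {eps_bias} mm")
    angle = normalize_deg(math.degrees(math.atan2(dy, dx)))
    return BiasGeometry(vessel_center=(cx, cy), bias_angle=angle, offset=offset)


def distance_indices(
    cs: CrossSection, bias: BiasGeometry
) -> tuple[float, float, Optional[float], Optional[float]]:
    """Catheter-center distances to intima/media along the bias ray and its opposite.

    Returns ``(d_cib, d_cio, d_cmb, d_cmo)``; the media-based pair is ``None``
    when no media contour is available.
    """
    origin = cs.catheter.center
    fwd, back = bias.bias_angle, bias.bias_angle + 180.0
    dirs = np.array([fwd, back])
    d_int = _ray_distances(origin, dirs, cs.intima)
    if not np.all(np.isfinite(d_int)):
        raise PreconditionError("bias ray does not intersect the intima")
    d_cib, d_cio = float(d_int[0]), float(d_int[1])
    d_cmb = d_cmo = None
    if cs.media is not None:
        d_med = _ray_distances(origin, dirs, cs.media)
        if not np.all(np.isfinite(d_med)):
            raise PreconditionError("bias ray does not intersect the media")
        d_cmb, d_cmo = float(d_med[0]), float(d_med[1])
    return d_cib, d_cio, d_cmb, d_cmo


def touch_angle(cs: CrossSection, gap_tol: float = DEFAULT_GAP_TOL,
                dtheta: float = DEFAULT_DTHETA, mode: str = "largest_run") -> float:
    """Arc of catheter-intima contact, in degrees, subtended at the catheter center.

    Rays from the catheter center are sampled every ``dtheta`` degrees; a ray is
    in contact where its distance to the intima is at most
    ``catheter.radius + gap_tol``.  ``mode='largest_run'`` (default) reports the
    longest contiguous contact run (wrap-around handled); ``mode='sum'`` reports
    the total contact measure over all runs.
    """
    if mode not in ("largest_run", "sum"):
        raise DomainError(f"unknown touch-angle mode {mode!r}")
    n = int(round(360.0 / dtheta))
    dirs = np.arange(n) * (360.0 / n)
    dist = _ray_distances(cs.catheter.center, dirs, cs.intima)
    # NaN rays (center outside on subintimal frames) count as contact: the
    # boundary is behind the ray origin, i.e. the catheter has crossed it.
    contact = ~np.isfinite(dist) | (dist <= cs.catheter.radius + gap_tol)
    if not contact.any():
        return 0.0
    if contact.all():
        return 360.0
    if mode == "sum":
        return float(contact.sum()) * (360.0 / n)
    # rotate so the scan starts on a non-contact sample, then take the max run
    start = int(np.argmin(contact))
    rolled = np.roll(contact, -start)
    edges = np.flatnonzero(np.diff(np.concatenate([[False], rolled, [False]])))
    runs = edges[1::2] - edges[::2]
    return float(runs.max()) * (360.0 / n)


def lumen_diameters(contour: Contour,
                    dtheta: float = DEFAULT_DTHETA) -> tuple[float, float]:
    """(min, max) chord length through the contour centroid over all directions."""
    c = centroid(contour)
    if not contour.as_polygon().contains(Point(c)):
        raise PreconditionError("contour centroid lies outside the contour")
    n = int(round(180.0 / dtheta))
    half = np.arange(n) * (180.0 / n)
    dirs = np.concatenate([half, half + 180.0])
    d = _ray_distances(c, dirs, contour)
    if not np.all(np.isfinite(d)):
        raise PreconditionError("diameter ray does not intersect the contour")
    chords = d[:n] + d[n:]
    return float(chords.min()), float(chords.max())


def eccentricity(min_ld: float, max_ld: float) -> float:
    """Lumen eccentricity (max - min) / max."""
    if max_ld <= 0 or min_ld <= 0 or min_ld > max_ld:
        raise DomainError("require 0 < min_ld <= max_ld")
    return (max_ld - min_ld) / max_ld


def eem_metrics(cs: CrossSection,
                dtheta: float = DEFAULT_DTHETA) -> tuple[Optional[float], Optional[float]]:
    """EEM cross-sectional area and average vessel diameter (min+max)/2.

    Both are ``None`` when the frame carries no EEM contour.
    """
    if cs.eem is None:
        return None, None
    csa = polygon_area(cs.eem)
    dmin, dmax = lumen_diameters(cs.eem, dtheta=dtheta)
    return csa, (dmin + dmax) / 2.0


def compute_btv(final_burr_size: float, reference_vessel_diameter: float) -> float:
    """Burr-to-vessel ratio."""
    if final_burr_size <= 0 or reference_vessel_diameter <= 0:
        raise DomainError("burr size and reference diameter must be > 0")
    return final_burr_size / reference_vessel_diameter


def measure_frame(cs: CrossSection, gap_tol: float = DEFAULT_GAP_TOL,
                  dtheta: float = DEFAULT_DTHETA,
                  eps_bias: float = DEFAULT_EPS_BIAS) -> MeasurementRecord:
    """Assemble every per-frame index into one record.

    Bias-undefined frames (concentric catheter) yield a record with the
    bias-dependent distances missing and a logged warning.
    """
    try:
        bias = bias_geometry(cs, eps_bias=eps_bias)
        d_cib, d_cio, d_cmb, d_cmo = distance_indices(cs, bias)
    except BiasUndefinedError:
        logger.warning("frame %d: bias undefined (concentric catheter)", cs.frame_id)
        bias = None
        d_cib = d_cio = d_cmb = d_cmo = None
    ta = touch_angle(cs, gap_tol=gap_tol, dtheta=dtheta)
    la = polygon_area(cs.intima)
    min_ld, max_ld = lumen_diameters(cs.intima, dtheta=dtheta)
    le = eccentricity(min_ld, max_ld)
    eem_csa, avd = eem_metrics(cs, dtheta=dtheta)
    return MeasurementRecord(
        d_cib=d_cib, d_cio=d_cio, d_cmb=d_cmb, d_cmo=d_cmo,
        touch_angle=ta, la=la, min_ld=min_ld, max_ld=max_ld, le=le,
        eem_csa=eem_csa, avd=avd, bias=bias)
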