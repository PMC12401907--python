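"""Pre/post pullback alignment, 1-mm frame pairing and coincidence statistics."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from . import geometry
from .angles import arcs_overlap, midpoint, point_in_arc
from .errors import NoOverlapError, PreconditionError, UnalignableError
from .geometry import CrossSection, Dissection, MeasurementRecord

logger = logging.getLogger(__name__)

#: Grid step for cross-sectional analysis (mm).
GRID_STEP = 1.0
#: A grid point adopts the nearest frame within this distance (mm).
NEAREST_TOL = 0.5


@dataclass(frozen=True)
class Pullback:
    """An ordered OCT pullback for one patient and phase."""

    patient_id: str
    phase: str  # "pre" | "post"
    frames: tuple[CrossSection, ...]
    landmark_z: Optional[float] = None
    analysis_span: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.phase not in ("pre", "post"):
            raise PreconditionError(f"phase must be 'pre' or 'post', got {self.phase!r}")
        zs = [f.z for f in self.frames]
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise PreconditionError("frames must be strictly increasing in z")
        if self.analysis_span is not None and self.analysis_span[1] <= self.analysis_span[0]:
            raise PreconditionError("analysis_span must be non-empty")
        if self.landmark_z is not None and self.frames:
            if not (zs[0] <= self.landmark_z <= zs[-1]):
                raise PreconditionError("landmark_z outside the pullback's frame range")
        object.__setattr__(self, "frames", tuple(self.frames))

    @property
    def z_range(self) -> tuple[float, float]:
        return self.frames[0].z, self.frames[-1].z


@dataclass(frozen=True)
class PairedFrame:
    """Coregistered pre/post frames at one shared grid position (pre coordinates)."""

    grid_z: float
    pre: CrossSection
    post: CrossSection
    pre_measure: MeasurementRecord
    post_dissection: Dissection


def align(pre: Pullback, post: Pullback) -> float:
    """Longitudinal offset mapping post z into pre coordinates.

    ``post.z + offset`` lives on the pre axis; computed from the fiduciary
    side-branch landmark recorded on each phase.
    """
    if pre.landmark_z is None or post.landmark_z is None:
        raise UnalignableError("both pullbacks need a fiduciary landmark_z")
    return pre.landmark_z - post.landmark_z


def _nearest(frames: Sequence[CrossSection], z: float) -> Optional[CrossSection]:
    """Nearest frame within NEAREST_TOL of z; ties go to the earlier frame."""
    best, best_d = None, NEAREST_TOL + 1e-12
    for f in frames:
        d = abs(f.z - z)
        if d < best_d - 1e-12:
            best, best_d = f, d
    return best


def resample_pairs(pre: Pullback, post: Pullback, offset: float,
                   gap_tol: float = geometry.DEFAULT_GAP_TOL,
                   dtheta: float = geometry.DEFAULT_DTHETA,
                   eps_bias: float = geometry.DEFAULT_EPS_BIAS) -> list[PairedFrame]:
    """Pair pre and post frames on a common 1-mm grid in pre coordinates.

    The grid covers the intersection of both phases' spans restricted to the
    pre-phase analysis span; grid points lacking a frame within 0.5 mm in
    either phase are dropped (with a logged count).
    """
    pre_lo, pre_hi = pre.z_range
    post_lo, post_hi = post.z_range[0] + offset, post.z_range[1] + offset
    lo = max(pre_lo, post_lo)
    hi = min(pre_hi, post_hi)
    if pre.analysis_span is not None:
        lo = max(lo, pre.analysis_span[0])
        hi = min(hi, pre.analysis_span[1])
    if hi < lo - 1e-9:
        raise NoOverlapError(
            f"{pre.patient_id}: no overlapping analyzable span between phases")
    pairs: list[PairedFrame] = []
    dropped = 0
    k = 0
    while lo + k * GRID_STEP <= hi + 1e-9:
        gz = lo + k * GRID_STEP
        k += 1
        pf = _nearest(pre.frames, gz)
        qf = _nearest(post.frames, gz - offset)
        if pf is None or qf is None:
            dropped += 1
            continue
        if qf.dissection is None:
            post_diss = Dissection(present=False)
        else:
            post_diss = qf.dissection
        pairs.append(PairedFrame(
            grid_z=gz, pre=pf, post=qf,
            pre_measure=geometry.measure_frame(
                pf, gap_tol=gap_tol, dtheta=dtheta, eps_bias=eps_bias),
            post_dissection=post_diss))
    if dropped:
        logger.info("%s: dropped %d grid points lacking a frame within %.1f mm",
                    pre.patient_id, dropped, NEAREST_TOL)
    return pairs


def quadrant_coincidence(pairs: Sequence[PairedFrame],
                         mode: str = "overlap") -> tuple[Optional[float], int]:
    """Fraction of dissection-positive pairs whose arc hits the pre bias quadrant.

    Returns ``(rate_percent, n_dissection)``; the rate is ``None`` when no pair
    carries a dissection.  ``mode='overlap'`` (default) counts any non-empty
    angular intersection; ``mode='midpoint'`` requires the arc midpoint to fall
    inside the quadrant.
    """
    if mode not in ("overlap", "midpoint"):
        raise PreconditionError(f"unknown coincidence mode {mode!r}")
    positive = [p for p in pairs if p.post_dissection.present]
    if not positive:
        return None, 0
    hits = 0
    for p in positive:
        if p.pre_measure.bias is None:
            raise PreconditionError(
                f"grid_z={p.grid_z}: bias undefined on a dissection-positive pair")
        if p.post_dissection.arc is None:
            raise PreconditionError(
                f"grid_z={p.grid_z}: dissection-positive pair lacks an arc")
        quad = p.pre_measure.bias.quadrant
        arc = p.post_dissection.arc
        if mode == "overlap":
            hit = arcs_overlap(arc, quad)
        else:
            hit = point_in_arc(midpoint(arc), quad)
        hits += int(hit)
    return 100.0 * hits / len(positive), len(positive)


def entrapment_rate(pairs: Sequence[PairedFrame]) -> Optional[float]:
    """Percent of dissection-positive pairs with the catheter flagged subintimal.

    ``None`` when no pair carries a dissection.
    """
    positive = [p for p in pairs if p.post_dissection.present]
    if not positive:
        return None
    trapped = sum(int(p.post_dissection.catheter_subintimal) for p in positive)
    return 100.0 * trapped / len(positive)
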