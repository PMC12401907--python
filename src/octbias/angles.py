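"""Angular-interval utilities.

Angles are degrees, measured counterclockwise from +x.  An arc ``(start, end)``
is the set swept counterclockwise from ``start`` to ``end`` with wrap-around at
360; intervals are half-open ``[start, end)``.  A zero-length pair denotes an
empty arc, never a full circle.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

Arc = tuple[float, float]

FULL_CIRCLE = 360.0


def normalize_deg(angle: float) -> float:
    """Map an angle to [0, 360)."""
    a = math.fmod(angle, FULL_CIRCLE)
    return a + FULL_CIRCLE if a < 0 else a


def arc_length(arc: Arc) -> float:
    """Counterclockwise sweep from start to end, in [0, 360)."""
    start, end = arc
    return normalize_deg(end - start)

def _segments(arc: Arc) -> list[tuple[float, float]]:
    """Split an arc into non-wrapping [lo, hi] intervals inside [0, 360)."""
    start = normalize_deg(arc[0])
    length = arc_length(arc)
    end = start + length
    if end <= FULL_CIRCLE:
        return [(start, end)]
    return [(start, FULL_CIRCLE), (0.0, end - FULL_CIRCLE)]


def point_in_arc(angle: float, arc: Arc) -> bool:
    """Membership test for the half-open arc [start, end)."""
    return normalize_deg(angle - arc[0]) < arc_length(arc)


def arc_intersection_length(a: Arc, b: Arc) -> float:
    """Total angular measure (degrees) of the intersection of two arcs."""
    total = 0.0
    for lo_a, hi_a in _segments(a):
        for lo_b, hi_b in _segments(b):
            total += max(0.0, min(hi_a, hi_b) - max(lo_a, lo_b))
    return total


def arcs_overlap(a: Arc, b: Arc, min_overlap: float = 1e-9) -> bool:
    """True when the two arcs share a set of positive angular measure."""
    return arc_intersection_length(a, b) > min_overlap


def midpoint(arc: Arc) -> float:
    """Angular midpoint of the arc, in [0, 360)."""
    return normalize_deg(arc[0] + arc_length(arc) / 2.0)


def validate_arcs(arcs: Iterable[Sequence[float]]) -> list[Arc]:
    """Normalize raw (start, end) pairs into canonical arcs in [0, 360)."""
    return [(normalize_deg(s), normalize_deg(e)) for s, e in arcs]
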