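"""Sub-apical branching.

A hypha is a polyline from its current *origin* (the most recent branch
point, initially the germination point) to its moving tip, with length
``L`` accumulated from the tip's Euler displacements.  At every Euler step
each actively growing tip may branch: the branching probability is the
experimentally derived cumulative normal ``Φ((L − (l1+l2)) / (l1_sd+l2_sd))``
compared against a fresh uniform draw.  When a branch fires, the branch
point is placed at arc length ``l2`` from the origin along the path, the
branch angle is drawn from the bimodal mixture ``N(±phi, phi_sd²)`` relative
to the local path tangent, and a daughter hypha emerges there at speed
``v_avg``.  The parent's origin moves to the branch point and its length is
reset to the straight-line distance from the branch point to its tip; the
daughter starts at length zero.

Branching succeeds only where the external substrate still supports active
growth: if the oxygen fraction at the branch point is below the
``maintenance_hi`` threshold the event is recorded as unsuccessful and no
daughter is created.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import ndtr

from .metabolism import MetabolicState
from .params import GrowthParams, MetabolicThresholds

__all__ = [
    "Hypha",
    "BranchEvent",
    "branch_probability",
    "should_branch",
    "sample_branch_angle",
    "locate_branch_point",
    "execute_branch",
]


@dataclass
class Hypha:
    """A polyline hypha with a growing tip.

    ``path`` is the ordered list of tip positions since creation (the first
    entry is the creation point).  ``origin`` is the start point from which
    branch placement is measured — the creation point until the first
    branch, then the latest branch point; ``origin_index`` is the index of
    the path vertex coinciding with it (branch points are spliced into the
    path).  ``length`` is the current hyphal length ``L``: arc length
    accumulated from tip displacements, reset on branching.
    """

    id: int
    origin: np.ndarray
    parent_id: Optional[int] = None
    path: list = field(default_factory=list)
    origin_index: int = 0
    length: float = 0.0

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        if not self.path:
            self.path = [self.origin.copy()]

    @property
    def tip_position(self) -> np.ndarray:
        return np.asarray(self.path[-1], dtype=float)

    def append_tip(self, position: np.ndarray) -> float:
        """Advance the tip; returns the step displacement added to ``length``."""
        step = float(np.linalg.norm(np.asarray(position, dtype=float) - self.tip_position))
        self.path.append(np.asarray(position, dtype=float).copy())
        self.length += step
        return step


@dataclass
class BranchEvent:
    """Record of one branching attempt (successful or not).

    ``parent_length`` is the hyphal length L of the parent at the moment
    the branching rule fired (before any reset)."""

    time: float
    parent_id: int
    branch_point: np.ndarray
    angle: float
    successful: bool
    daughter_id: Optional[int] = None
    parent_length: float = float("nan")


def branch_probability(L: float | np.ndarray, growth: GrowthParams) -> float | np.ndarray:
    """Per-step branching probability ``Φ((L − (l1+l2)) / (l1_sd+l2_sd))``.

    Monotone non-decreasing in the hyphal length ``L``; at defaults the CDF
    has mean 35.8 μm and standard deviation 12.4 μm.
    """
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise ValueError("hyphal length must be >= 0")
    p = ndtr((L - growth.branch_mean) / growth.branch_sd)
    return float(p) if p.ndim == 0 else p


def should_branch(
    L: float,
    local_state: MetabolicState,
    growth: GrowthParams,
    rng: np.random.Generator,
) -> bool:
    """One per-step branching decision: requires an actively growing tip and
    ``branch_probability(L)`` beating a fresh uniform draw."""
    u = rng.random()
    if local_state != MetabolicState.ACTIVE:
        return False
    return bool(branch_probability(L, growth) > u)


def sample_branch_angle(growth: GrowthParams, rng: np.random.Generator) -> float:
    """Draw a signed branch angle (degrees) from the mixture ``N(±phi, phi_sd²)``
    with equal-probability lobes."""
    sign = 1.0 if rng.random() < 0.5 else -1.0
    return float(rng.normal(sign * growth.phi, growth.phi_sd))


def locate_branch_point(
    h: Hypha, growth: GrowthParams
) -> Optional[tuple[np.ndarray, np.ndarray]]:
    """Walk the path from the hypha's origin to arc length ``l2``.

    Returns ``(position, unit tangent)`` of the branch point, or ``None``
    when the hypha is still shorter than ``l2`` (branching deferred).
    """
    if h.length < growth.l2:
        return None
    remaining = growth.l2
    pts = h.path
    for k in range(h.origin_index, len(pts) - 1):
        a = np.asarray(pts[k], dtype=float)
        b = np.asarray(pts[k + 1], dtype=float)
        seg = b - a
        seg_len = float(np.linalg.norm(seg))
        if seg_len == 0.0:
            continue
        if remaining <= seg_len:
            tangent = seg / seg_len
            return a + tangent * remaining, tangent
        remaining -= seg_len
    # length counter says >= l2 but the polyline from the origin is shorter
    # (possible after a reset, where length is straight-line): use the tip
    # direction at the end of the path.
    a = np.asarray(pts[-2], dtype=float) if len(pts) >= 2 else h.origin
    b = np.asarray(pts[-1], dtype=float)
    seg = b - a
    seg_len = float(np.linalg.norm(seg))
    if seg_len == 0.0:
        return None
    return b.copy(), seg / seg_len


def _rotate(vec: np.ndarray, angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([c * vec[0] - s * vec[1], s * vec[0] + c * vec[1]])


def execute_branch(
    h: Hypha,
    angle: float,
    point: np.ndarray,
    tangent: np.ndarray,
    growth: GrowthParams,
    *,
    oxygen_fraction: float = 1.0,
    thresholds: Optional[MetabolicThresholds] = None,
    time: float = 0.0,
    daughter_id: Optional[int] = None,
) -> tuple[Optional[Hypha], BranchEvent, Optional[np.ndarray]]:
    """Attempt a branch at ``point``.

    If the local ``oxygen_fraction`` meets the active-growth requirement
    (``thresholds.maintenance_hi``; always met when ``thresholds`` is None,
    the substrate-unlimited case), a daughter hypha is created at the branch
    point with length 0 and initial velocity ``v_avg`` along the tangent
    rotated by the signed ``angle``; the parent's origin is moved to the
    branch point and its length reset to the straight-line distance between
    branch point and parent tip.  Otherwise nothing changes and the event is
    recorded as unsuccessful.

    Returns ``(daughter or None, event, daughter_velocity or None)``.
    """
    point = np.asarray(point, dtype=float)
    L_at_branch = h.length
    ok = True
    if thresholds is not None:
        ok = oxygen_fraction >= thresholds.maintenance_hi
    if not ok:
        event = BranchEvent(time=time, parent_id=h.id, branch_point=point.copy(),
                            angle=float(angle), successful=False,
                            parent_length=L_at_branch)
        return None, event, None

    # splice the branch point into the parent path so later walks start there
    idx = _splice_point(h, point)
    h.origin = point.copy()
    h.origin_index = idx
    h.length = float(np.linalg.norm(h.tip_position - point))

    direction = _rotate(np.asarray(tangent, dtype=float), float(angle))
    velocity = growth.v_avg * direction
    did = daughter_id if daughter_id is not None else h.id + 1
    daughter = Hypha(id=did, origin=point.copy(), parent_id=h.id)
    event = BranchEvent(time=time, parent_id=h.id, branch_point=point.copy(),
                        angle=float(angle), successful=True, daughter_id=did,
                        parent_length=L_at_branch)
    return daughter, event, velocity


def _splice_point(h: Hypha, point: np.ndarray) -> int:
    """Insert ``point`` as a path vertex at its position along the path
    (after the current origin); returns its index."""
    pts = h.path
    best_k = len(pts) - 1
    for k in range(h.origin_index, len(pts) - 1):
        a = np.asarray(pts[k], dtype=float)
        b = np.asarray(pts[k + 1], dtype=float)
        seg = b - a
        denom = float(seg @ seg)
        if denom == 0.0:
            continue
        t = float((point - a) @ seg) / denom
        if -1e-9 <= t <= 1 + 1e-9:
            proj = a + np.clip(t, 0.0, 1.0) * seg
            if np.linalg.norm(proj - point) < 1e-6:
                if np.linalg.norm(point - a) < 1e-12:
                    return k
                if np.linalg.norm(point - b) < 1e-12:
                    return k + 1
                pts.insert(k + 1, point.copy())
                return k + 1
    return best_k
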