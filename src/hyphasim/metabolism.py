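"""Four-state metabolic machine driven by the local oxygen fraction.

States: ACTIVE (growing and branching), PRODUCING (secondary metabolism /
antibiotic production), MAINTENANCE (alive, non-growing, recoverable) and
DEAD (absorbing, non-consuming).  The local oxygen level, expressed as a
fraction of the cell-free bulk concentration, determines the state on each
re-evaluation:

=====================  ======================================================
oxygen fraction        outcome
=====================  ======================================================
≥ 0.90                 ACTIVE
0.60 – 0.90            ACTIVE with probability rising linearly 0 → 1,
                       otherwise PRODUCING
0.50 – 0.60            PRODUCING
0.40 – 0.50            PRODUCING with probability rising linearly 0 → 1,
                       otherwise MAINTENANCE
0.15 – 0.40            MAINTENANCE
< 0.15                 DEAD
=====================  ======================================================

Recovery is implicit: a MAINTENANCE or PRODUCING point re-evaluates like any
live point, so rising oxygen promotes it again.  DEAD never re-evaluates.
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np

from .params import MetabolicThresholds

__all__ = ["MetabolicState", "update_state", "update_states", "growth_permitted"]


class MetabolicState(IntEnum):
    ACTIVE = 0
    PRODUCING = 1
    MAINTENANCE = 2
    DEAD = 3


def update_state(
    current: MetabolicState,
    frac: float,
    thresholds: MetabolicThresholds,
    rng: np.random.Generator,
) -> MetabolicState:
    """Re-evaluate one point's metabolic state at oxygen fraction ``frac``."""
    if not 0.0 <= frac <= 1.0:
        raise ValueError(f"oxygen fraction must be in [0, 1], got {frac}")
    if current == MetabolicState.DEAD:
        return MetabolicState.DEAD
    t = thresholds
    if frac >= t.active_full:
        return MetabolicState.ACTIVE
    if frac >= t.producing_hi:
        p = (frac - t.producing_hi) / (t.active_full - t.producing_hi)
        return MetabolicState.ACTIVE if rng.random() < p else MetabolicState.PRODUCING
    if frac >= t.producing_lo:
        return MetabolicState.PRODUCING
    if frac >= t.production_stop:
        p = (frac - t.production_stop) / (t.producing_lo - t.production_stop)
        return MetabolicState.PRODUCING if rng.random() < p else MetabolicState.MAINTENANCE
    if frac >= t.death:
        return MetabolicState.MAINTENANCE
    return MetabolicState.DEAD


def update_states(
    states: np.ndarray,
    fracs: np.ndarray,
    thresholds: MetabolicThresholds,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised :func:`update_state` over arrays of states and fractions.

    Draws one uniform per point (dead points included, so the stream layout
    does not depend on how many points have died).  Returns a new array.
    """
    states = np.asarray(states)
    fracs = np.asarray(fracs, dtype=float)
    if fracs.min(initial=0.0) < 0.0 or fracs.max(initial=0.0) > 1.0 + 1e-12:
        raise ValueError("oxygen fractions must be in [0, 1]")
    t = thresholds
    u = rng.random(states.shape)
    out = np.empty_like(states)

    out[:] = MetabolicState.MAINTENANCE
    band_ap = (fracs >= t.producing_hi) & (fracs < t.active_full)
    p_active = np.zeros_like(fracs)
    p_active[band_ap] = (fracs[band_ap] - t.producing_hi) / (t.active_full - t.producing_hi)
    out[(fracs >= t.active_full) | (band_ap & (u < p_active))] = MetabolicState.ACTIVE
    band_pm = (fracs >= t.production_stop) & (fracs < t.producing_lo)
    p_prod = np.zeros_like(fracs)
    p_prod[band_pm] = (fracs[band_pm] - t.production_stop) / (t.producing_lo - t.production_stop)
    producing = (
        ((fracs >= t.producing_lo) & (fracs < t.producing_hi))
        | (band_pm & (u < p_prod))
        | (band_ap & (u >= p_active))
    )
    out[producing] = MetabolicState.PRODUCING
    out[fracs < t.death] = MetabolicState.DEAD
    out[states == MetabolicState.DEAD] = MetabolicState.DEAD  # absorbing
    return out


def growth_permitted(state: MetabolicState | np.ndarray) -> bool | np.ndarray:
    """Only ACTIVE hyphae elongate and branch; all other states freeze the
    tip (PRODUCING/MAINTENANCE tips keep their stored velocity and resume if
    re-promoted)."""
    if isinstance(state, np.ndarray):
        return state == MetabolicState.ACTIVE
    return state == MetabolicState.ACTIVE
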