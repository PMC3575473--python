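"""Stochastic tip elongation.

A hyphal tip is a point ``x ∈ ℝ²`` moving with velocity ``v ∈ ℝ²``:

    dx/dt = v
    dv    = β (v_avg · v/|v| − v) dt + α dW

The drift pulls the speed back towards the average elongation rate
``v_avg`` along the tip's current heading; the diffusion term ``α dW``
(``dW`` a 2-vector of independent Wiener increments) adds unbiased,
uncorrelated fluctuations in both speed and direction.  Both equations are
integrated with the explicit Euler / Euler–Maruyama scheme at step
``dt = t_interval / n_brownian_steps`` (0.04 h at defaults), which is fine
enough for the scheme to converge at the calibrated α, β.

The drift form is a mean-reverting reconstruction in the style of the
Stokes angiogenesis tip-migration model; see ``docs/methods.md`` for the
reasoning behind this choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import GrowthParams

__all__ = ["Tip", "velocity_step", "position_step", "init_germ_tips", "noise_increments"]


def noise_increments(
    growth: GrowthParams, dt: float, size: tuple, rng: np.random.Generator
) -> np.ndarray:
    """Draw the random increments ``dW`` fed to :func:`velocity_step`.

    Under the default ``noise_scaling="dt"`` each component is
    ``N(0, Δt²)`` so the per-step velocity kick is ``α·Δt``; under
    ``"sqrt_dt"`` it is the Wiener increment ``N(0, Δt)``.
    """
    sd = dt if growth.noise_scaling == "dt" else np.sqrt(dt)
    return rng.normal(0.0, sd, size=size)


@dataclass
class Tip:
    """A moving apical point.

    ``position`` (μm) and ``velocity`` (μm/h) are 2-vectors; ``hypha_id``
    links the tip to the hypha it extends.  A dead tip (``alive=False``)
    never moves again.
    """

    position: np.ndarray
    velocity: np.ndarray
    hypha_id: int
    alive: bool = True

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)


def velocity_step(
    v: np.ndarray, growth: GrowthParams, dt: float, dW: np.ndarray
) -> np.ndarray:
    """One Euler–Maruyama update of tip velocity.

    Parameters
    ----------
    v:
        Current velocity, shape ``(2,)`` or ``(n, 2)``, μm/h.  Every row
        must be non-zero (the relaxation direction ``v/|v|`` must exist).
    growth:
        Supplies ``v_avg``, ``alpha`` and ``beta``.
    dt:
        Time step, h.
    dW:
        Wiener increments of the same shape as ``v``; each component is
        ``N(0, dt)``-distributed.

    Returns
    -------
    The updated velocity ``v + β (v_avg v/|v| − v) dt + α dW``.
    """
    v = np.asarray(v, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be > 0")
    speed = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(speed == 0):
        raise ValueError("velocity_step: zero velocity has no relaxation direction")
    drift = growth.beta * (growth.v_avg * v / speed - v)
    out = v + drift * dt + growth.alpha * np.asarray(dW, dtype=float)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("velocity_step produced non-finite velocity")
    return out


def position_step(x: np.ndarray, v: np.ndarray, dt: float) -> np.ndarray:
    """Explicit Euler position update ``x + v dt``."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    return np.asarray(x, dtype=float) + np.asarray(v, dtype=float) * dt


def init_germ_tips(growth: GrowthParams, rng: np.random.Generator) -> tuple[Tip, Tip]:
    """Germinate: two tips at the origin, speed exactly ``v_avg``, headings
    drawn independently and uniformly on [0, 2π)."""
    tips = []
    for hypha_id in range(2):
        theta = rng.uniform(0.0, 2.0 * np.pi)
        vel = growth.v_avg * np.array([np.cos(theta), np.sin(theta)])
        tips.append(Tip(position=np.zeros(2), velocity=vel, hypha_id=hypha_id))
    return tips[0], tips[1]
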