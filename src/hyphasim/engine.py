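"""Full pellet simulation: germination → elongation → branching → oxygen
field → metabolic switching, with automatic domain management.

The run loop advances all actively growing tips by one Euler step, lets
each of them attempt a branch, and — on a configurable sub-interval
cadence — re-bins the network onto the oxygen grid, re-solves the
quasi-steady field and re-evaluates every recorded hyphal point's and
every tip's metabolic state against the local oxygen fraction.  Pellet
summary metrics are recorded at every reporting interval.

Biomass is recorded as *sample points*: as a tip advances, a new point is
dropped every ``resample_factor · grid_h`` of arc length (h/2 at
defaults, satisfying the rasterisation requirement by construction).
Points persist for the whole run and carry their own metabolic state, so
death is absorbing per point and the pellet interior ages realistically.

All randomness flows from one ``numpy`` Generator seeded by the run seed;
draws happen in a fixed order (velocity noise, then branching uniforms,
then branch angles, then state-update uniforms), so a run is bit-exactly
reproducible from (parameters, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .branching import (
    BranchEvent,
    Hypha,
    branch_probability,
    execute_branch,
    locate_branch_point,
    sample_branch_angle,
)
from .metabolism import MetabolicState, update_states
from .params import (
    GrowthParams,
    MetabolicThresholds,
    RunSettings,
    SubstrateParams,
    default_params,
)
from .substrate import (
    QuasiSteadySolver,
    SubstrateGrid,
    consumption_field,
    rasterise_points,
    sample_fraction,
)
from .tip_dynamics import init_germ_tips, noise_increments, position_step, velocity_step

__all__ = ["SimulationResult", "run", "enlarge_domain", "run_velocity_sweep"]


@dataclass
class SimulationResult:
    """Everything a finished run produced.

    ``metrics`` holds one row per reporting time (see
    :mod:`hyphasim.metrics` for column definitions); ``events`` one row per
    branching attempt.  ``points`` are the persistent biomass sample points
    (``position`` (n,2) μm, ``state`` ints, ``hypha_id``); ``tips`` the final
    tip table.  ``grid`` is the final oxygen grid (field + occupancy
    counts), and ``provenance`` records parameters, seed and code version —
    enough for a bit-exact replay.
    """

    growth: GrowthParams
    substrate: SubstrateParams
    thresholds: MetabolicThresholds
    settings: RunSettings
    seed: int
    metrics: pd.DataFrame
    events: pd.DataFrame
    hyphae: list
    points: dict
    tips: dict
    grid: SubstrateGrid
    first_producing_time: Optional[float]
    provenance: dict


def enlarge_domain(grid: SubstrateGrid, new_domain: float) -> SubstrateGrid:
    """Grow the (origin-centred) domain, preserving spacing ``h``.

    The previous field is embedded in the centre of the new grid as the
    initial state, with ``c_bulk`` outside; hyphal coordinates are
    unaffected.  ``new_domain − domain`` must be an even multiple of ``h``
    so the old cells land exactly on new cells.
    """
    if new_domain <= grid.domain:
        raise ValueError("new_domain must exceed the current domain")
    h = grid.h
    grow = (new_domain - grid.domain) / (2.0 * h)
    if abs(grow - round(grow)) > 1e-9:
        raise ValueError("domain growth must be an even multiple of the spacing")
    pad = int(round(grow))
    new_n = grid.N + 2 * pad
    out = SubstrateGrid(N=new_n, domain=float(new_domain), c_bulk=grid.c_bulk)
    out.c[pad : pad + grid.N, pad : pad + grid.N] = grid.c
    out.counts[:, pad : pad + grid.N, pad : pad + grid.N] = grid.counts
    return out


class _PointStore:
    """Growable arrays of biomass sample points."""

    def __init__(self) -> None:
        self.xy = np.empty((1024, 2), dtype=float)
        self.state = np.empty(1024, dtype=np.int64)
        self.hypha = np.empty(1024, dtype=np.int64)
        self.n = 0

    def _grow(self, need: int) -> None:
        cap = len(self.state)
        if self.n + need <= cap:
            return
        new_cap = max(cap * 2, self.n + need)
        self.xy = np.resize(self.xy, (new_cap, 2))
        self.state = np.resize(self.state, new_cap)
        self.hypha = np.resize(self.hypha, new_cap)

    def add(self, xy: np.ndarray, hypha_ids: np.ndarray) -> None:
        xy = np.atleast_2d(xy)
        k = len(xy)
        if k == 0:
            return
        self._grow(k)
        self.xy[self.n : self.n + k] = xy
        self.state[self.n : self.n + k] = int(MetabolicState.ACTIVE)
        self.hypha[self.n : self.n + k] = hypha_ids
        self.n += k

    @property
    def positions(self) -> np.ndarray:
        return self.xy[: self.n]

    @property
    def states(self) -> np.ndarray:
        return self.state[: self.n]

    @property
    def hypha_ids(self) -> np.ndarray:
        return self.hypha[: self.n]


class Engine:
    """Mutable run state; :func:`run` is the public entry point."""

    def __init__(
        self,
        growth: GrowthParams,
        substrate: Optional[SubstrateParams],
        thresholds: MetabolicThresholds,
        settings: RunSettings,
        seed: int,
    ) -> None:
        self.growth = growth
        self.substrate = substrate
        self.thresholds = thresholds
        self.settings = settings
        self.seed = int(seed)
        self.rng = np.random.default_rng(self.seed)
        self.field_on = substrate is not None and substrate.dbar_a > 0

        self.grid = SubstrateGrid(
            N=settings.grid_n,
            domain=settings.domain,
            c_bulk=(substrate.c_bulk if substrate is not None else 1.0),
        )
        self.solver = QuasiSteadySolver(rtol=settings.solver_rtol)
        self.spacing = settings.resample_factor * settings.grid_h

        t1, t2 = init_germ_tips(growth, self.rng)
        self.hyphae: list[Hypha] = [
            Hypha(id=0, origin=np.zeros(2)),
            Hypha(id=1, origin=np.zeros(2)),
        ]
        self.tip_pos = np.vstack([t1.position, t2.position])
        self.tip_vel = np.vstack([t1.velocity, t2.velocity])
        self.tip_state = np.full(2, int(MetabolicState.ACTIVE), dtype=np.int64)
        self.accum = np.zeros(2)  # arc length since last emitted point, per tip
        self.lengths = np.zeros(2)  # current hyphal length L per hypha

        self.points = _PointStore()
        self.points.add(np.zeros((2, 2)), np.array([0, 1]))

        self.events: list[BranchEvent] = []
        self.total_length = 0.0
        self.first_producing_time: Optional[float] = None
        self.last_dbar = np.zeros((self.grid.N, self.grid.N))
        self.time = 0.0

    # ------------------------------------------------------------------ step
    def step(self) -> None:
        growth, dt = self.growth, self.growth.dt
        active = np.flatnonzero(self.tip_state == int(MetabolicState.ACTIVE))
        n = len(active)
        if n:
            dW = noise_increments(growth, dt, (n, 2), self.rng)
            new_vel = velocity_step(self.tip_vel[active], growth, dt, dW)
            new_pos = position_step(self.tip_pos[active], new_vel, dt)
            self._ensure_domain(new_pos)

            old_pos = self.tip_pos[active]
            step_len = np.linalg.norm(new_pos - old_pos, axis=1)
            self.tip_vel[active] = new_vel
            self.tip_pos[active] = new_pos
            self.lengths[active] += step_len
            self.total_length += float(step_len.sum())
            for k, idx in enumerate(active):
                self.hyphae[idx].path.append(new_pos[k].copy())
                self.hyphae[idx].length = self.lengths[idx]
            self._emit_points(active, old_pos, new_pos, step_len)
            self._branch_attempts(active)
        self.time += dt

    def _emit_points(self, active, old_pos, new_pos, step_len) -> None:
        accum = self.accum[active] + step_len
        # drop a sample point every `spacing` of arc length along each path
        while True:
            over = accum >= self.spacing
            if not np.any(over):
                break
            behind = accum[over] - self.spacing
            direction = np.zeros_like(new_pos[over])
            nz = step_len[over] > 0
            direction[nz] = (new_pos[over][nz] - old_pos[over][nz]) / step_len[over][nz, None]
            pts = new_pos[over] - direction * behind[:, None]
            self.points.add(pts, active[over])
            accum[over] -= self.spacing
        self.accum[active] = accum

    def _branch_attempts(self, active: np.ndarray) -> None:
        growth = self.growth
        u = self.rng.random(len(active))
        p = branch_probability(self.lengths[active], growth)
        for k in np.flatnonzero(p > u):
            idx = int(active[k])
            h = self.hyphae[idx]
            if h.length < growth.l2:
                continue  # branching deferred: no admissible branch point yet
            located = locate_branch_point(h, growth)
            if located is None:
                continue
            point, tangent = located
            angle = sample_branch_angle(growth, self.rng)
            frac = 1.0
            if self.field_on:
                frac = min(float(sample_fraction(self.grid, point)), 1.0)
            daughter, event, dvel = execute_branch(
                h, angle, point, tangent, growth,
                oxygen_fraction=frac,
                thresholds=self.thresholds if self.field_on else None,
                time=self.time, daughter_id=len(self.hyphae),
            )
            self.events.append(event)
            if daughter is None:
                continue
            self.lengths[idx] = h.length
            self.hyphae.append(daughter)
            self.tip_pos = np.vstack([self.tip_pos, point])
            self.tip_vel = np.vstack([self.tip_vel, dvel])
            self.tip_state = np.append(self.tip_state, int(MetabolicState.ACTIVE))
            self.accum = np.append(self.accum, 0.0)
            self.lengths = np.append(self.lengths, 0.0)
            self.points.add(point[None, :], np.array([daughter.id]))

    def _ensure_domain(self, new_pos: np.ndarray) -> None:
        need = float(np.abs(new_pos).max(initial=0.0)) + self.settings.enlarge_margin
        while self.grid.domain / 2.0 <= need:
            self.grid = enlarge_domain(self.grid, self.grid.domain + self.settings.enlarge_step)
            self.solver.reset()
            self.last_dbar = np.zeros((self.grid.N, self.grid.N))

    # ----------------------------------------------------------- field/state
    def update_field_and_states(self) -> None:
        if not self.field_on:
            return
        rasterise_points(self.points.positions, self.points.states, self.grid)
        self.last_dbar = consumption_field(self.grid, self.substrate)
        self.solver.solve(self.grid, self.last_dbar)

        fr_pts = np.clip(sample_fraction(self.grid, self.points.positions), 0.0, 1.0)
        new_states = update_states(self.points.states, fr_pts, self.thresholds, self.rng)
        self.points.state[: self.points.n] = new_states
        fr_tips = np.clip(sample_fraction(self.grid, self.tip_pos), 0.0, 1.0)
        self.tip_state = update_states(self.tip_state, fr_tips, self.thresholds, self.rng)

        if self.first_producing_time is None and (
            np.any(new_states == int(MetabolicState.PRODUCING))
            or np.any(self.tip_state == int(MetabolicState.PRODUCING))
        ):
            self.first_producing_time = round(self.time, 9)

    # ---------------------------------------------------------------- output
    def snapshot_metrics(self) -> dict:
        from .metrics import compute_metrics

        return compute_metrics(
            time=round(self.time, 9),
            points=self.points.positions,
            point_states=self.points.states,
            tip_states=self.tip_state,
            total_length=self.total_length,
            grid=self.grid,
            events=self.events,
            dbar=self.last_dbar,
            closing_radius=self.settings.closing_radius,
            render_threshold=self.thresholds.live_dead_render,
            field_on=self.field_on,
            mask_h=self.settings.mask_h,
        )

    def result(self, metrics_rows: list[dict]) -> SimulationResult:
        events = pd.DataFrame(
            [
                {
                    "time": e.time,
                    "parent_id": e.parent_id,
                    "x": e.branch_point[0],
                    "y": e.branch_point[1],
                    "angle": e.angle,
                    "successful": e.successful,
                    "daughter_id": -1 if e.daughter_id is None else e.daughter_id,
                    "parent_length": e.parent_length,
                }
                for e in self.events
            ],
            columns=[
                "time", "parent_id", "x", "y", "angle",
                "successful", "daughter_id", "parent_length",
            ],
        )
        provenance = {
            "version": _version,
            "seed": self.seed,
            "growth": dataclasses.asdict(self.growth),
            "substrate": None if self.substrate is None else dataclasses.asdict(self.substrate),
            "thresholds": dataclasses.asdict(self.thresholds),
            "settings": {
                **dataclasses.asdict(self.settings),
                "extra_report_times": list(self.settings.extra_report_times),
            },
        }
        return SimulationResult(
            growth=self.growth,
            substrate=self.substrate,
            thresholds=self.thresholds,
            settings=self.settings,
            seed=self.seed,
            metrics=pd.DataFrame(metrics_rows),
            events=events,
            hyphae=self.hyphae,
            points={
                "position": self.points.positions.copy(),
                "state": self.points.states.copy(),
                "hypha_id": self.points.hypha_ids.copy(),
            },
            tips={
                "position": self.tip_pos.copy(),
                "velocity": self.tip_vel.copy(),
                "state": self.tip_state.copy(),
                "hypha_id": np.arange(len(self.hyphae)),
            },
            grid=self.grid,
            first_producing_time=self.first_producing_time,
            provenance=provenance,
        )


def run(
    growth: Optional[GrowthParams] = None,
    substrate: Optional[SubstrateParams] = None,
    thresholds: Optional[MetabolicThresholds] = None,
    settings: Optional[RunSettings] = None,
    seed: int = 0,
    *,
    field_free: bool = False,
    progress: bool = False,
) -> SimulationResult:
    """Simulate pellet growth from germination to ``settings.t_end``.

    Time zero is germination: two tips emerge from the origin at speed
    ``v_avg`` with independent uniform headings.  ``field_free=True`` (or a
    zero consumption rate) disables the oxygen field entirely: every tip
    stays ACTIVE and the run reduces to the unconstrained early-growth
    model, drawing exactly the same random numbers for tips and branches.

    Returns a :class:`SimulationResult` with metrics recorded at every
    reporting interval (``t_interval``, default 4 h), at any
    ``extra_report_times`` and at ``t_end``.
    """
    defaults = default_params()
    growth = growth or defaults[0]
    substrate = substrate or defaults[1]
    thresholds = thresholds or defaults[2]
    settings = settings or defaults[3]
    if field_free:
        substrate = None

    eng = Engine(growth, substrate, thresholds, settings, seed)
    dt = growth.dt
    n_steps = int(round(settings.t_end / dt))
    report_times = _report_times(growth, settings)
    report_steps = {int(round(t / dt)) for t in report_times}

    rows = [eng.snapshot_metrics()] if 0 in report_steps else []
    for s in range(1, n_steps + 1):
        eng.step()
        eng.time = s * dt  # index-derived time avoids accumulation drift
        if s % settings.field_update_every == 0 or s in report_steps:
            eng.update_field_and_states()
        if s in report_steps:
            rows.append(eng.snapshot_metrics())
        if progress and s % growth.n_brownian_steps == 0:
            print(
                f"t={eng.time:6.2f} h  tips={len(eng.hyphae):6d} "
                f"length={eng.total_length:10.1f} μm", flush=True,
            )
    return eng.result(rows)


def _report_times(growth: GrowthParams, settings: RunSettings) -> list[float]:
    times = {0.0, settings.t_end}
    t = growth.t_interval
    while t < settings.t_end:
        times.add(round(t, 9))
        t += growth.t_interval
    times.update(settings.extra_report_times)
    return sorted(times)


def run_velocity_sweep(
    velocities: Sequence[float],
    seeds: Sequence[int],
    growth: Optional[GrowthParams] = None,
    substrate: Optional[SubstrateParams] = None,
    thresholds: Optional[MetabolicThresholds] = None,
    settings: Optional[RunSettings] = None,
) -> pd.DataFrame:
    """Run the simulator over a grid of average tip velocities.

    One run per (velocity, seed), with automatic domain enlargement for the
    fast cases.  Returns a summary table with, per run: end-of-run HGU, the
    time of maximum successful branching (per reporting interval), first
    antibiotic-production time, end diameter, total and per-state areas,
    and the maximum rescaled oxygen consumption rate.
    """
    defaults = default_params()
    growth = growth or defaults[0]
    rows = []
    for v in velocities:
        if v <= 0:
            raise ValueError("velocities must be positive")
        g = dataclasses.replace(growth, v_avg=float(v))
        for seed in seeds:
            res = run(g, substrate, thresholds, settings, seed=int(seed))
            m = res.metrics.iloc[-1]
            succ = res.events[res.events["successful"]]
            if len(succ):
                interval = g.t_interval
                bins = np.floor(succ["time"].to_numpy() / interval).astype(int)
                counts = np.bincount(bins)
                t_max_branch = (int(np.argmax(counts)) + 0.5) * interval
            else:
                t_max_branch = np.nan
            rows.append(
                {
                    "v_avg": float(v),
                    "seed": int(seed),
                    "hgu_end": m["hgu"],
                    "t_max_successful_branching": t_max_branch,
                    "first_producing_time": np.nan
                    if res.first_producing_time is None
                    else res.first_producing_time,
                    "max_diameter": m["max_diameter"],
                    "area": m["area"],
                    "area_active": m["area_active"],
                    "area_producing": m["area_producing"],
                    "area_maintenance": m["area_maintenance"],
                    "area_dead": m["area_dead"],
                    "max_consumption": m["max_consumption"],
                    "n_tips_total": m["n_tips_total"],
                }
            )
    return pd.DataFrame(rows)
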