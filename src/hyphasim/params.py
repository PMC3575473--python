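"""Model parameters and configuration loading.

All tunable constants of the simulator live in four small dataclasses:

* :class:`GrowthParams` — tip elongation and branching statistics of early,
  substrate-unlimited hyphal growth (speeds in μm/h, lengths in μm, angles
  in degrees, times in hours).
* :class:`SubstrateParams` — oxygen diffusion/consumption constants and the
  default grid geometry used for the quasi-steady reaction–diffusion field.
* :class:`MetabolicThresholds` — the oxygen fractions (of the cell-free bulk
  concentration) at which hyphae switch between metabolic states.
* :class:`RunSettings` — everything about *how* a run is executed rather
  than *what* is simulated: domain size, solver cadence, output cadence.

Defaults reproduce the calibrated Streptomyces coelicolor parameterisation;
:func:`load_config` reads overrides from a YAML file whose four top-level
sections mirror the dataclasses.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Tuple

import yaml

__all__ = [
    "GrowthParams",
    "SubstrateParams",
    "MetabolicThresholds",
    "RunSettings",
    "ConfigError",
    "load_config",
    "save_config",
]


class ConfigError(ValueError):
    """Raised for unparseable configuration files or invalid parameter values."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass
class GrowthParams:
    """Early-growth (substrate-unlimited) elongation and branching parameters.

    Attributes
    ----------
    v_avg:
        Average hyphal tip elongation speed, μm/h.
    alpha:
        Diffusion coefficient of the tip-velocity stochastic differential
        equation (amplitude of the white-noise term), dimensionless as swept.
    beta:
        Drift coefficient — rate of relaxation of the tip speed back towards
        ``v_avg``, dimensionless as swept.
    l1, l1_sd:
        Mean and standard deviation of the apical length (tip to first
        branch point), μm.
    l2, l2_sd:
        Mean and standard deviation of the interbranch length, μm.
    phi, phi_sd:
        Mean absolute branching angle and its standard deviation, degrees.
        Branch angles are drawn from the symmetric two-lobe mixture
        ``N(±phi, phi_sd²)``.
    t_interval:
        Reporting interval, h.
    n_brownian_steps:
        Euler–Maruyama steps per reporting interval; the integration step is
        ``dt = t_interval / n_brownian_steps``.
    noise_scaling:
        How the per-step velocity noise increment scales with the step:
        ``"dt"`` (default) draws each component as ``N(0, (α·Δt)²)`` — the
        per-step-amplitude reading under which the calibrated model
        reproduces the observed 31 h pellet diameters; ``"sqrt_dt"`` is the
        textbook Euler–Maruyama convention ``N(0, α²·Δt)``, which at the
        calibrated α decorrelates tip directions within the hour.  See
        docs/methods.md.
    """

    v_avg: float = 6.3
    alpha: float = 10.0
    beta: float = 10.0
    l1: float = 28.5
    l1_sd: float = 8.5
    l2: float = 7.3
    l2_sd: float = 3.9
    phi: float = 84.0
    phi_sd: float = 23.0
    t_interval: float = 4.0
    n_brownian_steps: int = 100
    noise_scaling: str = "dt"

    def __post_init__(self) -> None:
        for name in ("v_avg", "l1", "l1_sd", "l2", "l2_sd", "phi_sd", "t_interval"):
            _require(getattr(self, name) > 0, f"growth.{name} must be > 0")
        _require(self.alpha >= 0, "growth.alpha must be >= 0")
        _require(self.beta >= 0, "growth.beta must be >= 0")
        _require(0 < abs(self.phi) < 180, "growth.phi must satisfy 0 < |phi| < 180")
        _require(
            int(self.n_brownian_steps) == self.n_brownian_steps
            and self.n_brownian_steps > 0,
            "growth.n_brownian_steps must be a positive integer",
        )
        self.n_brownian_steps = int(self.n_brownian_steps)
        _require(
            self.noise_scaling in ("dt", "sqrt_dt"),
            "growth.noise_scaling must be 'dt' or 'sqrt_dt'",
        )

    @property
    def dt(self) -> float:
        """Euler time step, h (``t_interval / n_brownian_steps``)."""
        return self.t_interval / self.n_brownian_steps

    @property
    def branch_mean(self) -> float:
        """Mean of the branching-length CDF, ``l1 + l2`` (μm)."""
        return self.l1 + self.l2

    @property
    def branch_sd(self) -> float:
        """Standard deviation of the branching-length CDF, ``l1_sd + l2_sd`` (μm)."""
        return self.l1_sd + self.l2_sd


@dataclass
class SubstrateParams:
    """Oxygen field constants.

    ``dbar_a`` is the *rescaled* consumption rate (consumption divided by
    the diffusion coefficient), units μm⁻², of actively growing hyphae;
    the other states consume the fractions ``frac_p`` (antibiotic
    production), ``frac_m`` (maintenance) and ``frac_e`` (dead) of it.
    ``N`` and ``domain`` give the default grid (spacing ``h = domain/N``);
    ``voxel_depth`` is the effective third dimension of a grid voxel, μm.
    """

    D_c: float = 9.216e6
    c_bulk: float = 0.1975
    dbar_a: float = 1e-5
    frac_p: float = 0.70
    frac_m: float = 0.50
    frac_e: float = 0.0
    N: int = 200
    domain: float = 200.0
    voxel_depth: float = 8.0

    def __post_init__(self) -> None:
        _require(self.D_c > 0, "substrate.D_c must be > 0")
        _require(self.c_bulk > 0, "substrate.c_bulk must be > 0")
        _require(self.dbar_a >= 0, "substrate.dbar_a must be >= 0")
        _require(
            0 <= self.frac_e <= self.frac_m <= self.frac_p <= 1,
            "substrate fractions must satisfy 0 <= frac_e <= frac_m <= frac_p <= 1",
        )
        _require(int(self.N) == self.N and self.N >= 3, "substrate.N must be an integer >= 3")
        self.N = int(self.N)
        _require(self.domain > 0, "substrate.domain must be > 0")
        _require(self.voxel_depth > 0, "substrate.voxel_depth must be > 0")

    @property
    def h(self) -> float:
        """Grid spacing, μm."""
        return self.domain / self.N


@dataclass
class MetabolicThresholds:
    """Oxygen-fraction thresholds (fractions of ``c_bulk``) for state switching.

    Above ``active_full`` every live hypha grows actively; between
    ``producing_lo`` and ``producing_hi`` every live hypha produces
    antibiotic; below ``production_stop`` production ceases; below ``death``
    hyphae die irreversibly.  Between bands the switching probability is
    interpolated linearly.  ``maintenance_hi`` is the upper edge of the
    non-growing band and acts as the oxygen level a prospective branch point
    must exceed for a branching event to succeed.  ``live_dead_render`` is
    the default green/red rendering threshold.
    """

    active_full: float = 0.90
    producing_hi: float = 0.60
    producing_lo: float = 0.50
    production_stop: float = 0.40
    maintenance_hi: float = 0.46
    death: float = 0.15
    live_dead_render: float = 0.50

    def __post_init__(self) -> None:
        _require(
            0
            <= self.death
            < self.production_stop
            <= self.maintenance_hi
            < self.producing_lo
            <= self.producing_hi
            < self.active_full
            <= 1,
            "thresholds must satisfy 0 <= death < production_stop <= maintenance_hi"
            " < producing_lo <= producing_hi < active_full <= 1",
        )
        _require(0 < self.live_dead_render < 1, "thresholds.live_dead_render must be in (0,1)")


@dataclass
class RunSettings:
    """Execution settings for a full pellet run.

    Attributes
    ----------
    t_end:
        Simulated time after germination, h.
    domain:
        Side length of the (square, origin-centred) simulation domain, μm.
        Pellet-scale runs need 400 μm; the domain auto-enlarges whenever a
        tip approaches the boundary.
    grid_h:
        Oxygen-grid spacing, μm.  The default 2 μm puts an N=200 grid over
        the 400 μm pellet domain (voxel volume 2·2·2 = 8 μm³).
    mask_h:
        Raster spacing (μm) for morphometric masks (pellet area, perimeter,
        live/dead rendering); 1 μm matches the measurement convention and is
        independent of the oxygen-grid spacing.
    field_update_every:
        Euler steps between quasi-steady field solves and metabolic state
        updates.  The default equals ``n_brownian_steps``: the field and
        states refresh once per reporting interval (4 h), the cadence at
        which the interval-structured integration scheme is organised;
        growth within an interval sees the field from its start.
    resample_factor:
        Hyphal sample-point spacing as a fraction of ``grid_h`` (occupancy
        counts are per sample point at spacing ``resample_factor * grid_h``).
    closing_radius:
        Radius (μm) of the disk structuring element used to close the
        occupied raster into a filled pellet mask.  The default was
        calibrated once, jointly against the printed end-of-run pellet area
        and perimeter (see docs/methods.md); it is a mask-definition
        choice, not a biological parameter.
    enlarge_margin:
        Distance (μm) from the boundary at which domain enlargement triggers.
    enlarge_step:
        Increment (μm) added to the domain side on enlargement.
    solver_rtol:
        Relative residual tolerance of the field solver.
    extra_report_times:
        Additional report times (h) on top of the ``t_interval`` cadence.
    """

    t_end: float = 31.0
    domain: float = 400.0
    grid_h: float = 2.0
    mask_h: float = 1.0
    field_update_every: int = 100
    resample_factor: float = 0.5
    closing_radius: float = 10.0
    enlarge_margin: float = 10.0
    enlarge_step: float = 100.0
    solver_rtol: float = 1e-10
    extra_report_times: Tuple[float, ...] = ()

    def __post_init__(self) -> None:
        _require(self.t_end > 0, "run.t_end must be > 0")
        _require(self.domain > 0, "run.domain must be > 0")
        _require(self.grid_h > 0, "run.grid_h must be > 0")
        _require(self.mask_h > 0, "run.mask_h must be > 0")
        _require(
            int(self.field_update_every) == self.field_update_every
            and self.field_update_every >= 1,
            "run.field_update_every must be a positive integer",
        )
        self.field_update_every = int(self.field_update_every)
        _require(0 < self.resample_factor <= 0.5, "run.resample_factor must be in (0, 0.5]")
        _require(self.closing_radius >= 0, "run.closing_radius must be >= 0")
        _require(self.enlarge_margin > 0, "run.enlarge_margin must be > 0")
        _require(self.enlarge_step > 0, "run.enlarge_step must be > 0")
        _require(self.solver_rtol > 0, "run.solver_rtol must be > 0")
        self.extra_report_times = tuple(float(t) for t in self.extra_report_times)

    @property
    def grid_n(self) -> int:
        n = round(self.domain / self.grid_h)
        _require(abs(n * self.grid_h - self.domain) < 1e-9, "run.domain must be a multiple of run.grid_h")
        return int(n)


_SECTIONS = {
    "growth": GrowthParams,
    "substrate": SubstrateParams,
    "thresholds": MetabolicThresholds,
    "run": RunSettings,
}

ParamBundle = Tuple[GrowthParams, SubstrateParams, MetabolicThresholds, RunSettings]


def load_config(path: str | Path) -> ParamBundle:
    """Load a YAML configuration file into validated parameter objects.

    The file holds up to four mappings — ``growth``, ``substrate``,
    ``thresholds``, ``run`` — whose keys are exactly the dataclass field
    names.  Omitted keys (or sections) take the defaults; unknown sections
    or keys are rejected.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping of sections")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
    out = []
    for name, cls in _SECTIONS.items():
        section = raw.get(name) or {}
        if not isinstance(section, dict):
            raise ConfigError(f"config section '{name}' must be a mapping")
        valid = {f.name for f in dataclasses.fields(cls)}
        bad = set(section) - valid
        if bad:
            raise ConfigError(f"unknown key(s) in section '{name}': {sorted(bad)}")
        try:
            out.append(cls(**section))
        except TypeError as exc:
            raise ConfigError(f"invalid section '{name}': {exc}") from exc
    return tuple(out)  # type: ignore[return-value]


def _as_dict(obj: Any) -> dict:
    d = dataclasses.asdict(obj)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def save_config(bundle: ParamBundle, path: str | Path) -> None:
    """Serialise a parameter bundle back to YAML (round-trips with load_config)."""
    growth, substrate, thresholds, run = bundle
    doc = {
        "growth": _as_dict(growth),
        "substrate": _as_dict(substrate),
        "thresholds": _as_dict(thresholds),
        "run": _as_dict(run),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def default_params() -> ParamBundle:
    """The calibrated default parameterisation."""
    return GrowthParams(), SubstrateParams(), MetabolicThresholds(), RunSettings()
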