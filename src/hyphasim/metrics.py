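"""Pellet morphometrics and calibration procedures.

Summary quantities computed from a network + field snapshot:

* **max pellet diameter** — largest pairwise distance between hyphal sample
  points (the convex-hull diameter).
* **pellet area / perimeter** — the occupied raster is closed with a
  disk-shaped structuring element (default radius 5 μm) and holes are
  filled, emulating the solid fluorescent blob that pellet image analysis
  segments; area is mask pixels × h², perimeter a standard boundary-length
  estimator on the mask.
* **HGU** — hyphal growth unit: total hyphal length / total tip count.
* **live/dead rendering** — occupied-mask pixels split green/red by local
  oxygen fraction against a threshold (Table-5-style calibration selects
  the threshold whose mean red area best matches a measured
  propidium-iodide area).
* **α/β calibration sweep** and **branching-pattern report** — the
  early-growth calibration and the branching-frequency comparison.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import perimeter_crofton as _mask_perimeter
from skimage.morphology import closing as _closing, disk

from .metabolism import MetabolicState
from .params import GrowthParams, RunSettings, SubstrateParams
from .substrate import SubstrateGrid, sample_fraction

__all__ = [
    "max_pellet_diameter",
    "occupancy_mask",
    "pellet_mask",
    "live_dead_render",
    "calibrate_interface_threshold",
    "sweep_alpha_beta",
    "branching_pattern_report",
    "compute_metrics",
    "recompute_metrics",
]


def max_pellet_diameter(points: np.ndarray) -> float:
    """Maximum Euclidean distance between any two hyphal sample points.

    Uses the convex hull (the diameter is attained on hull vertices) with a
    brute-force fallback for tiny or degenerate (collinear) networks.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise ValueError("need a non-empty (n, 2) point array")
    if len(pts) > 50:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate geometry: brute-force below
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def occupancy_mask(points: np.ndarray, grid: SubstrateGrid) -> np.ndarray:
    """Boolean N×N raster of cells containing at least one sample point."""
    mask = np.zeros((grid.N, grid.N), dtype=bool)
    pts = np.asarray(points, dtype=float)
    if pts.size:
        i, j = grid.cell_index(pts)
        mask[i, j] = True
    return mask


def pellet_mask(
    points: np.ndarray,
    h: float,
    closing_radius: float = 5.0,
    grid: Optional[SubstrateGrid] = None,
) -> tuple[np.ndarray, float, float]:
    """Filled pellet mask with area (μm²) and perimeter (μm).

    The occupied raster (spacing ``h``) is morphologically closed with a
    disk of the given radius and enclosed holes are filled.  When ``grid``
    is given the mask shares its geometry (needed to overlay the oxygen
    field); otherwise a padded bounding-box raster is used.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("cannot compute a pellet mask for an empty network")
    if grid is None:
        half = float(np.abs(pts).max()) + closing_radius + 4 * h
        n = max(int(np.ceil(2 * half / h)), 8)
        grid = SubstrateGrid(N=n, domain=n * h, c_bulk=1.0)
    occ = occupancy_mask(pts, grid)
    r_px = int(round(closing_radius / grid.h))
    mask = _closing(occ, disk(r_px)).astype(bool) if r_px > 0 else occ
    mask = ndimage.binary_fill_holes(mask)
    mask |= occ  # closing never removes occupied pixels
    area = float(mask.sum()) * grid.h**2
    # Crofton (4-direction) boundary length: unbiased on smooth digitised
    # blobs, the regime the closing operation produces
    perim = float(_mask_perimeter(mask, directions=4)) * grid.h
    return mask, area, perim


def _mask_geometry(domain: float, mask_h: float) -> SubstrateGrid:
    """Raster geometry for morphometric masks (field values unused)."""
    n = max(int(round(domain / mask_h)), 4)
    return SubstrateGrid(N=n, domain=n * mask_h, c_bulk=1.0)


def _fraction_raster(grid: SubstrateGrid, geom: SubstrateGrid) -> np.ndarray:
    """Oxygen fraction of ``grid`` sampled at the pixel centres of ``geom``."""
    coords = (np.arange(geom.N) + 0.5) * geom.h - geom.domain / 2.0
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    frac = np.asarray(sample_fraction(grid, pts)).reshape(geom.N, geom.N)
    return np.clip(frac, 0.0, 1.0)


def live_dead_render(
    grid: SubstrateGrid,
    points: np.ndarray,
    threshold_frac: float,
    closing_radius: float = 5.0,
    mask_h: Optional[float] = None,
) -> dict:
    """Split the filled pellet mask into green (live) and red (dead-stain)
    regions by local oxygen fraction.

    The mask is rasterised at ``mask_h`` (default: the oxygen-grid spacing)
    and oxygen is interpolated onto mask pixels; pixels where
    ``c/c_bulk < threshold_frac`` render red — the simulated analogue of
    propidium-iodide staining of the hypoxic pellet core.  Returns masks
    and areas (μm²).
    """
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError("threshold_frac must be in (0, 1)")
    geom = _mask_geometry(grid.domain, mask_h if mask_h is not None else grid.h)
    mask, area, perim = pellet_mask(points, geom.h, closing_radius, grid=geom)
    frac = _fraction_raster(grid, geom)
    red = mask & (frac < threshold_frac)
    green = mask & ~red
    h2 = geom.h**2
    return {
        "mask": mask,
        "red": red,
        "green": green,
        "red_area": float(red.sum()) * h2,
        "green_area": float(green.sum()) * h2,
        "area": area,
        "perimeter": perim,
    }


def calibrate_interface_threshold(
    results: Iterable,
    target_red_area: float,
    threshold_grid: Sequence[float],
) -> tuple[float, pd.DataFrame]:
    """Select the live/dead oxygen threshold matching a measured stain area.

    For every candidate threshold the mean red area over the replicate
    end-of-run snapshots is computed; the threshold whose mean is closest
    to ``target_red_area`` wins (ties go to the lower threshold).  Returns
    ``(best_threshold, table)`` where the table lists threshold → mean red
    area (the Table-5-style output).
    """
    results = list(results)
    thresholds = sorted(float(t) for t in threshold_grid)
    if not all(0.0 < t < 1.0 for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1)")
    rows = []
    for thr in thresholds:
        areas = []
        for res in results:
            rd = live_dead_render(
                res.grid,
                res.points["position"],
                thr,
                res.settings.closing_radius,
                mask_h=res.settings.mask_h,
            )
            areas.append(rd["red_area"])
        rows.append({"threshold": thr, "mean_red_area": float(np.mean(areas))})
    table = pd.DataFrame(rows)
    err = np.abs(table["mean_red_area"].to_numpy() - target_red_area)
    best = float(table["threshold"].iloc[int(np.argmin(err))])
    return best, table


def sweep_alpha_beta(
    alphas: Sequence[float],
    betas: Sequence[float],
    seeds: Sequence[int],
    experimental: dict,
    growth: Optional[GrowthParams] = None,
    t_end: float = 4.0,
) -> pd.DataFrame:
    """Early-growth calibration sweep of the velocity-SDE coefficients.

    Runs the substrate-unlimited model for ``t_end`` hours per (α, β, seed)
    and summarises max pellet diameter and tip count (min/mean/max over
    seeds).  A combination is flagged when both spreads lie within the
    experimental mean ± sd supplied in ``experimental`` (keys
    ``diameter_mean``, ``diameter_sd``, ``tips_mean``, ``tips_sd``).
    """
    from .engine import run
    from .params import default_params

    growth = growth or default_params()[0]
    needed = {"diameter_mean", "diameter_sd", "tips_mean", "tips_sd"}
    if not needed <= set(experimental):
        raise ValueError(f"experimental summary needs keys {sorted(needed)}")
    rows = []
    for a in alphas:
        for b in betas:
            g = dataclasses.replace(growth, alpha=float(a), beta=float(b))
            settings = RunSettings(t_end=t_end, domain=400.0)
            diams, tips = [], []
            for seed in seeds:
                res = run(g, None, None, settings, seed=int(seed), field_free=True)
                m = res.metrics.iloc[-1]
                diams.append(float(m["max_diameter"]))
                tips.append(int(m["n_tips_total"]))
            diams = np.asarray(diams)
            tips = np.asarray(tips)
            d_lo = experimental["diameter_mean"] - experimental["diameter_sd"]
            d_hi = experimental["diameter_mean"] + experimental["diameter_sd"]
            t_lo = experimental["tips_mean"] - experimental["tips_sd"]
            t_hi = experimental["tips_mean"] + experimental["tips_sd"]
            flagged = bool(
                d_lo <= diams.min() and diams.max() <= d_hi
                and t_lo <= tips.min() and tips.max() <= t_hi
            )
            rows.append(
                {
                    "alpha": float(a),
                    "beta": float(b),
                    "diameter_min": diams.min(),
                    "diameter_mean": diams.mean(),
                    "diameter_max": diams.max(),
                    "tips_min": tips.min(),
                    "tips_mean": tips.mean(),
                    "tips_max": tips.max(),
                    "flagged": flagged,
                }
            )
    return pd.DataFrame(rows)


def branching_pattern_report(
    results_by_set: dict[str, Sequence],
    strict: bool = False,
) -> pd.DataFrame:
    """Compare branching-frequency parameter sets (I = less frequent,
    II = standard, III = frequent).

    Returns one row per set with mean end-of-run HGU and mean
    antibiotic-producing area over replicates.  With ``strict=True`` an
    AssertionError is raised unless mean HGU decreases with branching
    frequency (HGU(III) < HGU(II) < HGU(I))."""
    rows = []
    for name, results in results_by_set.items():
        hgus, prod_areas = [], []
        for res in results:
            m = res.metrics.iloc[-1]
            hgus.append(float(m["hgu"]))
            prod_areas.append(float(m["area_producing"]))
        rows.append(
            {
                "set": name,
                "hgu_mean": float(np.mean(hgus)),
                "producing_area_mean": float(np.mean(prod_areas)),
                "n": len(results),
            }
        )
    table = pd.DataFrame(rows).set_index("set")
    if strict and {"I", "II", "III"} <= set(table.index):
        assert (
            table.loc["III", "hgu_mean"]
            < table.loc["II", "hgu_mean"]
            < table.loc["I", "hgu_mean"]
        ), "HGU should decrease with branching frequency"
    return table


def recompute_metrics(result) -> dict:
    """Recompute the full metrics row from a (possibly re-loaded) result.

    All metrics are pure functions of the snapshot, so this must reproduce
    the values the engine recorded at the final reporting time.
    """
    from .substrate import consumption_field, rasterise_points

    grid = result.grid
    rasterise_points(result.points["position"], result.points["state"], grid)
    field_on = result.substrate is not None and result.substrate.dbar_a > 0
    dbar = (
        consumption_field(grid, result.substrate)
        if field_on
        else np.zeros_like(grid.c)
    )

    class _Ev:
        __slots__ = ("successful",)

        def __init__(self, s):
            self.successful = bool(s)

    events = [_Ev(s) for s in result.events.get("successful", [])]
    return compute_metrics(
        time=float(result.metrics["time"].iloc[-1]) if len(result.metrics) else 0.0,
        points=result.points["position"],
        point_states=result.points["state"],
        tip_states=result.tips["state"],
        total_length=float(result.metrics["total_length"].iloc[-1]),
        grid=grid,
        events=events,
        dbar=dbar,
        closing_radius=result.settings.closing_radius,
        render_threshold=result.thresholds.live_dead_render,
        field_on=field_on,
        mask_h=result.settings.mask_h,
    )


# --------------------------------------------------------------------------
def compute_metrics(
    time: float,
    points: np.ndarray,
    point_states: np.ndarray,
    tip_states: np.ndarray,
    total_length: float,
    grid: SubstrateGrid,
    events: Sequence,
    dbar: np.ndarray,
    closing_radius: float,
    render_threshold: float,
    field_on: bool,
    mask_h: float = 1.0,
) -> dict:
    """One PelletMetrics row (used by the engine at each reporting time and
    by snapshot re-analysis)."""
    n_tips = len(tip_states)
    n_dead = int(np.sum(tip_states == int(MetabolicState.DEAD)))
    succ = sum(1 for e in events if e.successful)
    fail = len(events) - succ

    geom = _mask_geometry(grid.domain, mask_h)
    if len(points):
        diameter = max_pellet_diameter(points)
        mask, area, perim = pellet_mask(points, geom.h, closing_radius, grid=geom)
    else:  # pragma: no cover - a run always has germ points
        diameter, area, perim = 0.0, 0.0, 0.0
        mask = np.zeros((geom.N, geom.N), dtype=bool)

    # state-resolved areas: each occupied cell classified by its dominant
    # state (ties resolved towards the more active state)
    from .substrate import rasterise_points

    counts = rasterise_points(points, point_states, grid)
    occupied = counts.sum(axis=0) > 0
    dominant = np.argmax(counts, axis=0)
    h2 = grid.h**2
    area_by_state = {
        s: float(np.sum(occupied & (dominant == int(s)))) * h2 for s in MetabolicState
    }

    mh2 = geom.h**2
    if field_on:
        frac = _fraction_raster(grid, geom)
        red = mask & (frac < render_threshold)
        red_area = float(red.sum()) * mh2
        green_area = float(mask.sum() - red.sum()) * mh2
        max_cons = float(dbar.max()) if dbar.size else 0.0
    else:
        red_area, green_area = 0.0, float(mask.sum()) * mh2
        max_cons = 0.0

    return {
        "time": float(time),
        "max_diameter": diameter,
        "area": area,
        "perimeter": perim,
        "total_length": float(total_length),
        "hgu": float(total_length) / n_tips if n_tips else 0.0,
        "n_tips_total": n_tips,
        "n_tips_live": n_tips - n_dead,
        "n_tips_dead": n_dead,
        "n_branch_success": succ,
        "n_branch_fail": fail,
        "area_active": area_by_state[MetabolicState.ACTIVE],
        "area_producing": area_by_state[MetabolicState.PRODUCING],
        "area_maintenance": area_by_state[MetabolicState.MAINTENANCE],
        "area_dead": area_by_state[MetabolicState.DEAD],
        "red_area": red_area,
        "green_area": green_area,
        "max_consumption": max_cons,
    }
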