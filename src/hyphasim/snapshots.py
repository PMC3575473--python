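"""Snapshot persistence and synthetic test fixtures.

A snapshot archive is a single ``.npz`` file (compressed structured numpy
arrays) holding the full network (polylines, lengths, lineage), tips,
biomass sample points with states, the oxygen raster with its geometry,
the metrics and event tables, and a YAML provenance block (parameters +
seed + code version).  Loading then re-saving is lossless for the numeric
payload, and a loaded snapshot can be re-analysed by every metrics
function exactly like a live run's result.

:func:`generate_fixture` builds small synthetic snapshots with known
ground truth (straight hyphae, radial stars, analytic disk consumption
fields, tiny seeded pellets) for tests and examples.
"""

from __future__ import annotations

import dataclasses
import io
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .branching import Hypha
from .engine import SimulationResult, run
from .metabolism import MetabolicState
from .params import (
    GrowthParams,
    MetabolicThresholds,
    RunSettings,
    SubstrateParams,
    default_params,
)
from .substrate import SubstrateGrid, resample_polyline, solve_quasi_steady
from . import __version__

__all__ = ["save_snapshot", "load_snapshot", "generate_fixture", "SnapshotError"]

FORMAT_VERSION = 1


class SnapshotError(RuntimeError):
    """Unreadable, truncated, or version-incompatible snapshot file."""


def save_snapshot(result: SimulationResult, path: str | Path) -> None:
    """Write a :class:`SimulationResult` to a single-file ``.npz`` archive."""
    path = Path(path)
    paths = [np.asarray(h.path, dtype=float) for h in result.hyphae]
    offsets = np.concatenate([[0], np.cumsum([len(p) for p in paths])]).astype(np.int64)
    flat = np.concatenate(paths) if paths else np.empty((0, 2))
    header = {
        "format_version": FORMAT_VERSION,
        "package_version": result.provenance.get("version", __version__),
        "seed": result.seed,
        "first_producing_time": result.first_producing_time,
        "time": float(result.metrics["time"].iloc[-1]) if len(result.metrics) else 0.0,
        "units": {"length": "um", "time": "h", "concentration": "mmol/l"},
        "provenance": result.provenance,
    }
    np.savez_compressed(
        path,
        header=np.frombuffer(yaml.safe_dump(header).encode(), dtype=np.uint8),
        hypha_id=np.array([h.id for h in result.hyphae], dtype=np.int64),
        hypha_parent=np.array(
            [-1 if h.parent_id is None else h.parent_id for h in result.hyphae],
            dtype=np.int64,
        ),
        hypha_origin=np.array([h.origin for h in result.hyphae], dtype=float).reshape(-1, 2),
        hypha_origin_index=np.array([h.origin_index for h in result.hyphae], dtype=np.int64),
        hypha_length=np.array([h.length for h in result.hyphae], dtype=float),
        path_offsets=offsets,
        path_points=flat,
        tip_position=result.tips["position"],
        tip_velocity=result.tips["velocity"],
        tip_state=result.tips["state"],
        point_position=result.points["position"],
        point_state=result.points["state"],
        point_hypha=result.points["hypha_id"],
        grid_c=result.grid.c,
        grid_counts=result.grid.counts,
        grid_meta=np.array([result.grid.N, result.grid.domain, result.grid.c_bulk]),
        metrics=np.frombuffer(result.metrics.to_json(orient="split").encode(), dtype=np.uint8),
        events=np.frombuffer(result.events.to_json(orient="split").encode(), dtype=np.uint8),
    )


def load_snapshot(path: str | Path) -> SimulationResult:
    """Load a snapshot archive back into a :class:`SimulationResult`."""
    path = Path(path)
    try:
        with np.load(path, allow_pickle=False) as z:
            data = {k: z[k] for k in z.files}
    except Exception as exc:
        raise SnapshotError(f"cannot read snapshot {path}: {exc}") from exc
    required = {"header", "path_offsets", "path_points", "grid_meta"}
    if not required <= set(data):
        raise SnapshotError(f"snapshot {path} is missing required fields")
    header = yaml.safe_load(bytes(data["header"]).decode())
    if header.get("format_version") != FORMAT_VERSION:
        raise SnapshotError(
            f"snapshot format version {header.get('format_version')} "
            f"is not supported (expected {FORMAT_VERSION})"
        )
    prov = header["provenance"]
    growth = GrowthParams(**prov["growth"])
    substrate = None if prov.get("substrate") is None else SubstrateParams(**prov["substrate"])
    thresholds = MetabolicThresholds(**prov["thresholds"])
    settings = RunSettings(**prov["settings"])

    offsets = data["path_offsets"]
    hyphae = []
    for k in range(len(data["hypha_id"])):
        pts = data["path_points"][offsets[k] : offsets[k + 1]]
        h = Hypha(
            id=int(data["hypha_id"][k]),
            origin=data["hypha_origin"][k],
            parent_id=None if data["hypha_parent"][k] < 0 else int(data["hypha_parent"][k]),
            path=[p.copy() for p in pts],
            origin_index=int(data["hypha_origin_index"][k]),
            length=float(data["hypha_length"][k]),
        )
        hyphae.append(h)

    n, domain, c_bulk = data["grid_meta"]
    grid = SubstrateGrid(N=int(n), domain=float(domain), c_bulk=float(c_bulk))
    grid.c = data["grid_c"]
    grid.counts = data["grid_counts"]

    metrics = pd.read_json(io.StringIO(bytes(data["metrics"]).decode()), orient="split")
    events = pd.read_json(io.StringIO(bytes(data["events"]).decode()), orient="split")
    return SimulationResult(
        growth=growth,
        substrate=substrate,
        thresholds=thresholds,
        settings=settings,
        seed=int(header["seed"]),
        metrics=metrics,
        events=events,
        hyphae=hyphae,
        points={
            "position": data["point_position"],
            "state": data["point_state"],
            "hypha_id": data["point_hypha"],
        },
        tips={
            "position": data["tip_position"],
            "velocity": data["tip_velocity"],
            "state": data["tip_state"],
            "hypha_id": data["hypha_id"],
        },
        grid=grid,
        first_producing_time=header.get("first_producing_time"),
        provenance=prov,
    )


def _synthetic_result(
    paths: list[np.ndarray],
    settings: RunSettings,
    seed: int = 0,
    grid: Optional[SubstrateGrid] = None,
) -> SimulationResult:
    """Wrap bare polylines into a SimulationResult with uniform oxygen and
    all-ACTIVE states (synthetic snapshot; no dynamics were run)."""
    growth, substrate, thresholds, _ = default_params()
    if grid is None:
        grid = SubstrateGrid(N=settings.grid_n, domain=settings.domain, c_bulk=substrate.c_bulk)
    hyphae = []
    pts = []
    spacing = settings.resample_factor * settings.grid_h
    for k, p in enumerate(paths):
        p = np.asarray(p, dtype=float)
        seg = np.diff(p, axis=0)
        length = float(np.linalg.norm(seg, axis=1).sum())
        hyphae.append(Hypha(id=k, origin=p[0], path=[q.copy() for q in p], length=length))
        pts.append(resample_polyline(p, spacing))
    points = np.concatenate(pts) if pts else np.empty((0, 2))
    hypha_ids = np.concatenate(
        [np.full(len(s), k, dtype=np.int64) for k, s in enumerate(pts)]
    ) if pts else np.empty(0, dtype=np.int64)
    states = np.full(len(points), int(MetabolicState.ACTIVE), dtype=np.int64)
    tip_pos = np.array([h.tip_position for h in hyphae]).reshape(-1, 2)
    tip_vel = np.zeros_like(tip_pos)
    provenance = {
        "version": __version__,
        "seed": seed,
        "synthetic": True,
        "growth": dataclasses.asdict(growth),
        "substrate": dataclasses.asdict(substrate),
        "thresholds": dataclasses.asdict(thresholds),
        "settings": {
            **dataclasses.asdict(settings),
            "extra_report_times": list(settings.extra_report_times),
        },
    }
    total_length = float(sum(h.length for h in hyphae))
    metrics = pd.DataFrame(
        [{"time": 0.0, "total_length": total_length, "n_tips_total": len(hyphae)}]
    )
    return SimulationResult(
        growth=growth,
        substrate=substrate,
        thresholds=thresholds,
        settings=settings,
        seed=seed,
        metrics=metrics,
        events=pd.DataFrame(
            columns=[
                "time", "parent_id", "x", "y", "angle",
                "successful", "daughter_id", "parent_length",
            ]
        ),
        hyphae=hyphae,
        points={"position": points, "state": states, "hypha_id": hypha_ids},
        tips={
            "position": tip_pos,
            "velocity": tip_vel,
            "state": np.full(len(hyphae), int(MetabolicState.ACTIVE), dtype=np.int64),
            "hypha_id": np.arange(len(hyphae)),
        },
        grid=grid,
        first_producing_time=None,
        provenance=provenance,
    )


def generate_fixture(kind: str, seed: int = 0, **kw) -> SimulationResult:
    """Deterministic synthetic snapshots with known ground truth.

    Kinds
    -----
    ``straight_hypha``
        One straight hypha of ``length`` (default 50 μm) along +x starting
        slightly off the cell boundary; known diameter = length, HGU = length.
    ``radial_star``
        ``k`` arms (default 4) of radius ``r`` (default 30 μm) at equal
        angles from the origin; for even ``k`` the max diameter is exactly
        ``2 r`` and the HGU is ``r``.
    ``disk_field``
        Uniform consumption ``dbar`` (default 1e-4 μm⁻²) on a centred disk
        of ``radius`` (default 30 μm) on an ``N``×``N`` grid, field solved;
        the radial profile has a closed-form modified-Bessel solution.
    ``tiny_pellet``
        A real (short) default-parameter run: ``t_end`` (default 4 h) at
        the given seed; bit-reproducible.
    """
    if kind == "straight_hypha":
        length = float(kw.pop("length", 50.0))
        settings = RunSettings(domain=4 * max(length, 50.0), **kw)
        start = np.array([0.25, 0.25])  # off cell corners: unambiguous binning
        path = np.array([start, start + [length, 0.0]])
        return _synthetic_result([path], settings, seed)
    if kind == "radial_star":
        k = int(kw.pop("k", 4))
        r = float(kw.pop("r", 30.0))
        settings = RunSettings(domain=8 * np.ceil(max(r, 25.0) / 2), **kw)
        angles = 2 * np.pi * np.arange(k) / k
        paths = [
            np.array([[0.0, 0.0], [r * np.cos(a), r * np.sin(a)]]) for a in angles
        ]
        return _synthetic_result(paths, settings, seed)
    if kind == "disk_field":
        radius = float(kw.pop("radius", 30.0))
        dbar_val = float(kw.pop("dbar", 1e-4))
        N = int(kw.pop("N", 100))
        domain = float(kw.pop("domain", 200.0))
        settings = RunSettings(domain=domain, grid_h=domain / N, **kw)
        _, substrate, _, _ = default_params()
        grid = SubstrateGrid(N=N, domain=domain, c_bulk=substrate.c_bulk)
        coords = (np.arange(N) + 0.5) * grid.h - domain / 2
        xx, yy = np.meshgrid(coords, coords, indexing="ij")
        dbar = np.where(xx**2 + yy**2 <= radius**2, dbar_val, 0.0)
        solve_quasi_steady(grid, dbar)
        res = _synthetic_result([], settings, seed, grid=grid)
        res.provenance["disk_field"] = {"radius": radius, "dbar": dbar_val}
        return res
    if kind == "tiny_pellet":
        t_end = float(kw.pop("t_end", 4.0))
        settings = RunSettings(t_end=t_end, **kw)
        return run(settings=settings, seed=seed)
    raise ValueError(f"unknown fixture kind: {kind!r}")


def export_field_text(grid: SubstrateGrid, path: str | Path) -> None:
    """Plain-matrix text export of the oxygen field (row = y index
    increasing upward, columns = x) with a geometry header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# N={grid.N} domain_um={grid.domain} c_bulk={grid.c_bulk}\n")
        fh.write("# rows: y increasing upward; columns: x increasing right\n")
        np.savetxt(fh, grid.c.T[::-1], fmt="%.10g")


def write_manifest(result: SimulationResult, path: str | Path, command: str = "") -> None:
    """JSON manifest sufficient to reproduce the run bit-exactly."""
    doc = {"command": command, **result.provenance}
    Path(path).write_text(json.dumps(doc, indent=2, default=float))
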