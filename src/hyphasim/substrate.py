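"""Quasi-steady oxygen reaction–diffusion field.

Oxygen obeys a reaction–diffusion equation whose consumption and diffusion
act on a seconds timescale, far faster than the hours timescale of hyphal
growth.  To leading order the field is therefore quasi-steady,

    ∇²c = d̄ c,        c = c_bulk on the boundary,

where ``d̄`` (μm⁻²) is the consumption rate rescaled by the diffusion
coefficient, assembled per grid cell from the number of hyphal sample
points in each metabolic state:

    d̄_ij = d̄_a (A_ij + frac_p P_ij + frac_m M_ij + frac_e E_ij).

The Laplacian is discretised with the standard 5-point stencil on an N×N
grid of square cells (spacing ``h``), giving a sparse symmetric
positive-definite system solved to a fixed relative residual.  Repeated
solves during a simulation reuse an LU factorisation of a recent matrix as
a preconditioner for BiCGSTAB, warm-started from the previous field;
the factorisation is refreshed whenever convergence degrades, so results
are independent of the update cadence to within the solver tolerance.

Grid convention: the domain is a square of side ``domain`` centred on the
biological origin; cell ``(i, j)`` spans ``[i·h, (i+1)·h) × [j·h, (j+1)·h)``
in corner-based coordinates (half-open, so points are never double
counted), with index ``i`` along x and ``j`` along y.  Arrays are indexed
``[i, j]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .metabolism import MetabolicState
from .params import SubstrateParams

__all__ = [
    "SubstrateGrid",
    "OutOfDomainError",
    "SolverError",
    "resample_polyline",
    "rasterise_points",
    "rasterise_network",
    "consumption_field",
    "solve_quasi_steady",
    "sample_fraction",
]

_N_STATES = 4


class OutOfDomainError(ValueError):
    """A hyphal point fell outside the grid (the engine reacts by enlarging
    the domain)."""


class SolverError(RuntimeError):
    """The quasi-steady solver failed to reach the requested residual."""


@dataclass
class SubstrateGrid:
    """N×N oxygen field with per-cell, state-resolved occupancy counts."""

    N: int
    domain: float
    c_bulk: float
    c: np.ndarray = None  # type: ignore[assignment]
    counts: np.ndarray = None  # type: ignore[assignment]  # (4, N, N) per state

    def __post_init__(self) -> None:
        if self.c is None:
            self.c = np.full((self.N, self.N), float(self.c_bulk))
        if self.counts is None:
            self.counts = np.zeros((_N_STATES, self.N, self.N), dtype=np.int64)

    @property
    def h(self) -> float:
        """Grid spacing, μm."""
        return self.domain / self.N

    # per-state views, named after the occupancy symbols
    @property
    def A(self) -> np.ndarray:
        return self.counts[MetabolicState.ACTIVE]

    @property
    def P(self) -> np.ndarray:
        return self.counts[MetabolicState.PRODUCING]

    @property
    def M(self) -> np.ndarray:
        return self.counts[MetabolicState.MAINTENANCE]

    @property
    def E(self) -> np.ndarray:
        return self.counts[MetabolicState.DEAD]

    def cell_index(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map world coordinates (origin at domain centre) to cell indices."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        ij = np.floor((xy + self.domain / 2.0) / self.h).astype(np.int64)
        if ij.min(initial=0) < 0 or ij.max(initial=0) >= self.N:
            raise OutOfDomainError("hyphal point outside the substrate domain")
        return ij[:, 0], ij[:, 1]

    def contains(self, xy: np.ndarray, margin: float = 0.0) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        half = self.domain / 2.0 - margin
        return np.all(np.abs(xy) < half, axis=1)


def resample_polyline(path: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a polyline at uniform arc-length ``spacing`` (includes the
    start point; sample k sits at arc length k·spacing)."""
    path = np.asarray(path, dtype=float)
    if path.ndim != 2 or path.shape[1] != 2:
        raise ValueError("path must be an (n, 2) array")
    if len(path) == 1:
        return path.copy()
    seg = np.diff(path, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = arc[-1]
    s = np.arange(0.0, total + 1e-12, spacing)
    x = np.interp(s, arc, path[:, 0])
    y = np.interp(s, arc, path[:, 1])
    return np.column_stack([x, y])


def rasterise_points(
    positions: np.ndarray, states: np.ndarray, grid: SubstrateGrid
) -> np.ndarray:
    """Bin sample points into per-cell, per-state occupancy counts.

    Overwrites ``grid.counts``; overlapping paths stack freely (the 2D+
    convention — crossing paths live in different 3-D planes, so a cell may
    hold any number of hyphae).
    """
    counts = np.zeros((_N_STATES, grid.N, grid.N), dtype=np.int64)
    positions = np.asarray(positions, dtype=float)
    if positions.size:
        i, j = grid.cell_index(positions)
        flat = (np.asarray(states, dtype=np.int64) * grid.N * grid.N) + i * grid.N + j
        binned = np.bincount(flat, minlength=_N_STATES * grid.N * grid.N)
        counts = binned.reshape(_N_STATES, grid.N, grid.N)
    grid.counts = counts
    return counts


def rasterise_network(
    hyphae: Iterable,
    grid: SubstrateGrid,
    states: Optional[Sequence[int]] = None,
    spacing: Optional[float] = None,
) -> np.ndarray:
    """Rasterise whole hyphal polylines onto the grid.

    Each hypha's path is resampled at arc spacing ≤ h/2 and every sample
    point increments the count of its containing cell.  ``states`` gives one
    state per hypha (default ACTIVE).  This is the snapshot-level interface;
    during a live run the engine bins its persistent per-point state records
    with :func:`rasterise_points` instead.
    """
    hyphae = list(hyphae)
    if spacing is None:
        spacing = grid.h / 2.0
    if spacing > grid.h / 2.0:
        raise ValueError("resampling spacing must be <= h/2")
    pts = []
    sts = []
    for k, h in enumerate(hyphae):
        path = np.asarray(getattr(h, "path", h), dtype=float)
        samples = resample_polyline(path, spacing)
        pts.append(samples)
        state = MetabolicState.ACTIVE if states is None else states[k]
        sts.append(np.full(len(samples), int(state), dtype=np.int64))
    if pts:
        return rasterise_points(np.concatenate(pts), np.concatenate(sts), grid)
    return rasterise_points(np.empty((0, 2)), np.empty(0, dtype=np.int64), grid)


def consumption_field(grid: SubstrateGrid, sub: SubstrateParams) -> np.ndarray:
    """Per-cell rescaled consumption rate d̄ (μm⁻²) from occupancy counts."""
    return sub.dbar_a * (
        grid.A + sub.frac_p * grid.P + sub.frac_m * grid.M + sub.frac_e * grid.E
    )


class QuasiSteadySolver:
    """Solves ∇²c = d̄ c with Dirichlet boundary c_bulk, reusing an LU
    factorisation as a preconditioner across consecutive solves."""

    def __init__(self, rtol: float = 1e-10, max_precond_age: int = 25):
        self.rtol = rtol
        self.max_precond_age = max_precond_age
        self._lu = None
        self._lu_shape: Optional[int] = None
        self._x_prev: Optional[np.ndarray] = None
        self._lap_key: Optional[tuple[int, float]] = None
        self._lap: Optional[sp.csr_matrix] = None

    def _assemble(self, N: int, h: float, dbar: np.ndarray) -> sp.csc_matrix:
        if self._lap_key != (N, h):
            n = N - 2
            ones = np.ones(n)
            T = sp.diags([ones[:-1], -2.0 * ones, ones[:-1]], [-1, 0, 1], format="csr")
            eye = sp.identity(n, format="csr")
            self._lap = ((sp.kron(eye, T) + sp.kron(T, eye)) / h**2).tocsr()
            self._lap_key = (N, h)
        A = (self._lap - sp.diags(dbar[1:-1, 1:-1].ravel())).tocsc()
        return A

    def solve(self, grid: SubstrateGrid, dbar: np.ndarray) -> np.ndarray:
        N, h, cb = grid.N, grid.h, grid.c_bulk
        dbar = np.asarray(dbar, dtype=float)
        if np.any(dbar < 0):
            raise ValueError("consumption field must be non-negative")
        if not np.any(dbar):
            grid.c = np.full((N, N), cb)
            self._x_prev = None
            return grid.c

        A = self._assemble(N, h, dbar)
        b = np.zeros((N - 2, N - 2))
        b[0, :] -= cb / h**2
        b[-1, :] -= cb / h**2
        b[:, 0] -= cb / h**2
        b[:, -1] -= cb / h**2
        rhs = b.ravel()

        if self._lu is None or self._lu_shape != A.shape[0]:
            self._refactor(A)
        x0 = self._x_prev if self._x_prev is not None and self._x_prev.size == rhs.size else None
        M = spla.LinearOperator(A.shape, matvec=self._lu.solve)
        x, info = spla.bicgstab(A, rhs, x0=x0, M=M, rtol=self.rtol, atol=0.0, maxiter=200)
        res = np.linalg.norm(A @ x - rhs) / np.linalg.norm(rhs)
        if info != 0 or res > 10 * self.rtol:
            # stale preconditioner: refactor the current matrix and retry
            self._refactor(A)
            x = self._lu.solve(rhs)
            res = np.linalg.norm(A @ x - rhs) / np.linalg.norm(rhs)
            if res > 10 * self.rtol:
                x, info = spla.bicgstab(
                    A, rhs, x0=x,
                    M=spla.LinearOperator(A.shape, matvec=self._lu.solve),
                    rtol=self.rtol, atol=0.0, maxiter=500,
                )
                res = np.linalg.norm(A @ x - rhs) / np.linalg.norm(rhs)
                if info != 0 or res > 10 * self.rtol:
                    raise SolverError(f"quasi-steady solve failed: relative residual {res:.3e}")
        self._x_prev = x
        c = np.full((N, N), cb)
        c[1:-1, 1:-1] = x.reshape(N - 2, N - 2)
        np.clip(c, 0.0, cb, out=c)
        grid.c = c
        return c

    def _refactor(self, A: sp.csc_matrix) -> None:
        self._lu = spla.splu(A)
        self._lu_shape = A.shape[0]

    def reset(self) -> None:
        self._lu = None
        self._lu_shape = None
        self._x_prev = None
        self._lap_key = None
        self._lap = None


def solve_quasi_steady(
    grid: SubstrateGrid, dbar: np.ndarray, rtol: float = 1e-10
) -> np.ndarray:
    """One-shot quasi-steady solve (see :class:`QuasiSteadySolver`).

    Updates and returns ``grid.c``; the solution obeys the maximum
    principle 0 ≤ c ≤ c_bulk, with boundary cells at exactly c_bulk.
    """
    return QuasiSteadySolver(rtol=rtol).solve(grid, dbar)


def sample_fraction(grid: SubstrateGrid, x: np.ndarray) -> float | np.ndarray:
    """Oxygen fraction c/c_bulk at world position(s) ``x`` by bilinear
    interpolation between cell-centre nodes (clamped at the rim so the
    boundary value extends half a cell outward)."""
    xy = np.atleast_2d(np.asarray(x, dtype=float))
    half = grid.domain / 2.0
    if np.any(np.abs(xy) > half + 1e-9):
        raise OutOfDomainError("sample position outside the substrate domain")
    # node i sits at world coordinate (i + 0.5) h − domain/2
    g = (xy + half) / grid.h - 0.5
    g = np.clip(g, 0.0, grid.N - 1.0)
    i0 = np.floor(g).astype(np.int64)
    i0 = np.minimum(i0, grid.N - 2)
    f = g - i0
    c = grid.c
    vals = (
        c[i0[:, 0], i0[:, 1]] * (1 - f[:, 0]) * (1 - f[:, 1])
        + c[i0[:, 0] + 1, i0[:, 1]] * f[:, 0] * (1 - f[:, 1])
        + c[i0[:, 0], i0[:, 1] + 1] * (1 - f[:, 0]) * f[:, 1]
        + c[i0[:, 0] + 1, i0[:, 1] + 1] * f[:, 0] * f[:, 1]
    )
    frac = vals / grid.c_bulk
    if np.asarray(x).ndim == 1:
        return float(frac[0])
    return frac
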