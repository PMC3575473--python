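import numpy as np
import pytest
from scipy.special import i0

import hyphasim as hs
from hyphasim.metabolism import MetabolicState
from hyphasim.substrate import (
    OutOfDomainError,
    SubstrateGrid,
    consumption_field,
    rasterise_network,
    rasterise_points,
    resample_polyline,
    sample_fraction,
    solve_quasi_steady,
)


def _grid(N=40, domain=40.0, c_bulk=0.1975):
    return SubstrateGrid(N=N, domain=domain, c_bulk=c_bulk)


class TestRasterisation:
    def test_straight_hypha_occupies_exactly_traversed_cells(self):
        grid = _grid()
        # 9 um hypha crossing cell interiors only: occupies 10 cells
        path = np.array([[0.5, 0.5], [9.5, 0.5]])
        rasterise_network([path], grid)
        occupied = np.argwhere(grid.A > 0)
        assert len(occupied) == 10
        assert set(map(tuple, occupied)) == {(20 + i, 20) for i in range(10)}
        assert grid.P.sum() == grid.M.sum() == grid.E.sum() == 0

    def test_no_hyphae_all_zero(self):
        grid = _grid()
        rasterise_network([], grid)
        assert grid.counts.sum() == 0

    def test_overlapping_paths_stack(self):
        grid = _grid()
        path = np.array([[0.5, 0.5], [9.5, 0.5]])
        single = rasterise_network([path], grid)[0].copy()
        double = rasterise_network([path, path.copy()], grid)[0]
        # 2D+ stacking, no cap: identical overlapping paths double every count
        assert np.array_equal(double, 2 * single)
        assert double.max() >= 2

    def test_counts_conserved_against_sample_points(self):
        grid = _grid()
        rng = np.random.default_rng(3)
        paths = [np.cumsum(rng.normal(0, 1, size=(30, 2)), axis=0) for _ in range(5)]
        states = [MetabolicState.ACTIVE, MetabolicState.PRODUCING,
                  MetabolicState.MAINTENANCE, MetabolicState.DEAD,
                  MetabolicState.ACTIVE]
        rasterise_network(paths, grid, states=states)
        n_samples = sum(
            len(resample_polyline(np.asarray(p), grid.h / 2)) for p in paths
        )
        assert grid.counts.sum() == n_samples

    def test_point_outside_domain_raises(self):
        grid = _grid()
        with pytest.raises(OutOfDomainError):
            rasterise_points(np.array([[100.0, 0.0]]),
                             np.array([0]), grid)

    def test_spacing_above_half_cell_rejected(self):
        grid = _grid()
        with pytest.raises(ValueError):
            rasterise_network([np.array([[0.0, 0.0], [5.0, 0.0]])], grid,
                              spacing=0.9)


class TestConsumptionField:
    def test_hand_evaluated_cell(self):
        grid = _grid(N=4, domain=4.0)
        grid.counts[MetabolicState.ACTIVE, 1, 1] = 2
        grid.counts[MetabolicState.PRODUCING, 1, 1] = 1
        grid.counts[MetabolicState.MAINTENANCE, 1, 1] = 1
        grid.counts[MetabolicState.DEAD, 1, 1] = 3
        d = consumption_field(grid, hs.SubstrateParams())
        assert d[1, 1] == pytest.approx(3.2e-5)
        assert d.sum() == pytest.approx(d[1, 1])

    def test_dead_only_cell_consumes_nothing(self):
        grid = _grid(N=4, domain=4.0)
        grid.counts[MetabolicState.DEAD, 2, 2] = 10
        d = consumption_field(grid, hs.SubstrateParams())
        assert np.all(d == 0)


class TestQuasiSteadySolve:
    def test_no_consumption_gives_uniform_bulk(self):
        grid = _grid()
        c = solve_quasi_steady(grid, np.zeros((40, 40)))
        assert np.all(c == 0.1975)

    def test_single_consumer_against_dense_oracle(self):
        N, h = 20, 1.0
        grid = _grid(N=N, domain=N * h)
        dbar = np.zeros((N, N))
        dbar[8, 11] = 5e-3
        c = solve_quasi_steady(grid, dbar)
        # global minimum at the consuming cell; depression strictly interior
        assert np.unravel_index(np.argmin(c), c.shape) == (8, 11)
        assert np.all(c[0, :] == grid.c_bulk) and np.all(c[:, -1] == grid.c_bulk)
        assert np.all(c <= grid.c_bulk) and np.all(c > 0)
        # dense from-scratch oracle on the same 5-point stencil
        n = N - 2
        A = np.zeros((n * n, n * n))
        b = np.zeros(n * n)
        for i in range(n):
            for j in range(n):
                k = i * n + j
                A[k, k] = -4.0 / h**2 - dbar[i + 1, j + 1]
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < n and 0 <= jj < n:
                        A[k, ii * n + jj] = 1.0 / h**2
                    else:
                        b[k] -= grid.c_bulk / h**2
        oracle = np.linalg.solve(A, b).reshape(n, n)
        assert np.allclose(c[1:-1, 1:-1], oracle, rtol=1e-8, atol=1e-12)

    def test_disk_profile_matches_modified_bessel(self):
        """Uniform consumption on a centred disk: inside the disk the
        radial profile is proportional to I0(sqrt(dbar) r)."""
        N, domain, radius, dval = 100, 200.0, 40.0, 2e-3
        grid = _grid(N=N, domain=domain)
        h = grid.h
        coords = (np.arange(N) + 0.5) * h - domain / 2
        xx, yy = np.meshgrid(coords, coords, indexing="ij")
        rr = np.sqrt(xx**2 + yy**2)
        dbar = np.where(rr <= radius, dval, 0.0)
        c = solve_quasi_steady(grid, dbar)
        k = np.sqrt(dval)
        inside = rr <= radius * 0.9
        analytic = i0(k * rr[inside]) / i0(0.0)
        numeric = c[inside] / c[np.unravel_index(np.argmin(rr), rr.shape)]
        assert np.all(np.abs(numeric / analytic - 1.0) < 0.02)

    def test_maximum_principle_monotone_in_consumption(self):
        rng = np.random.default_rng(8)
        grid1, grid2 = _grid(), _grid()
        base = rng.uniform(0, 1e-3, size=(40, 40))
        extra = base.copy()
        extra[15:25, 15:25] += 5e-3
        c1 = solve_quasi_steady(grid1, base)
        c2 = solve_quasi_steady(grid2, extra)
        assert np.all(c2 <= c1 + 1e-12)

    def test_negative_consumption_rejected(self):
        grid = _grid()
        with pytest.raises(ValueError):
            solve_quasi_steady(grid, -np.ones((40, 40)))

    def test_grid_refinement_consistency(self):
        """Halving the spacing changes the disk solution by less than a
        first-order discretisation estimate."""
        vals = {}
        for N in (50, 100):
            grid = _grid(N=N, domain=100.0)
            h = grid.h
            coords = (np.arange(N) + 0.5) * h - 50.0
            xx, yy = np.meshgrid(coords, coords, indexing="ij")
            dbar = np.where(xx**2 + yy**2 <= 20.0**2, 2e-3, 0.0)
            c = solve_quasi_steady(grid, dbar)
            vals[N] = sample_fraction(grid, np.array([0.0, 0.0]))
        assert abs(vals[100] - vals[50]) < 0.02


class TestSampleFraction:
    def test_uniform_field_is_one_everywhere(self):
        grid = _grid()
        for p in ([0.0, 0.0], [10.3, -7.9], [19.99, 19.99]):
            assert sample_fraction(grid, np.array(p)) == pytest.approx(1.0)

    def test_node_values_reproduced(self):
        grid = _grid(N=10, domain=10.0)
        grid.c = np.arange(100, dtype=float).reshape(10, 10) / 100 * grid.c_bulk
        # node (3, 4) sits at world (-1.5, -0.5)
        assert sample_fraction(grid, np.array([-1.5, -0.5])) == pytest.approx(
            grid.c[3, 4] / grid.c_bulk
        )

    def test_mid_edge_bilinear(self):
        grid = _grid(N=10, domain=10.0)
        grid.c = np.full((10, 10), 0.2 * grid.c_bulk)
        grid.c[6, :] = 0.4 * grid.c_bulk
        # halfway between nodes (5, j) and (6, j): 0.3
        x_mid = (5.5 + 0.5) * 1.0 - 5.0
        assert sample_fraction(grid, np.array([x_mid, 0.0])) == pytest.approx(0.3)

    def test_outside_domain_raises(self):
        grid = _grid()
        with pytest.raises(OutOfDomainError):
            sample_fraction(grid, np.array([30.0, 0.0]))


class TestEnlargeDomain:
    def test_n_scales_with_domain(self):
        grid = _grid(N=200, domain=200.0)
        big = hs.enlarge_domain(grid, 400.0)
        assert big.N == 400 and big.h == grid.h

    def test_no_hyphae_enlarged_field_is_bulk(self):
        grid = _grid(N=20, domain=20.0)
        big = hs.enlarge_domain(grid, 40.0)
        assert np.all(big.c == grid.c_bulk)

    def test_previous_interior_embedded(self):
        grid = _grid(N=20, domain=20.0)
        grid.c = np.random.default_rng(0).uniform(0.1, 0.19, (20, 20))
        big = hs.enlarge_domain(grid, 40.0)
        assert np.array_equal(big.c[10:30, 10:30], grid.c)
        assert np.all(big.c[:10, :] == grid.c_bulk)

    def test_shrinking_rejected(self):
        grid = _grid()
        with pytest.raises(ValueError):
            hs.enlarge_domain(grid, 20.0)
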