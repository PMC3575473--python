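import math

import numpy as np
import pytest

import hyphasim as hs
from hyphasim.branching import (
    Hypha,
    branch_probability,
    execute_branch,
    locate_branch_point,
    sample_branch_angle,
    should_branch,
)
from hyphasim.metabolism import MetabolicState


def _phi(z):
    """Standard normal CDF via erf — oracle independent of the implementation."""
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


class TestBranchProbability:
    def test_half_at_mean_length(self, growth):
        assert branch_probability(35.8, growth) == pytest.approx(0.5)

    def test_value_at_zero_length(self, growth):
        assert branch_probability(0.0, growth) == pytest.approx(
            _phi(-35.8 / 12.4), rel=1e-9
        )

    def test_monotone_in_length(self, growth):
        L = np.linspace(0, 120, 400)
        p = branch_probability(L, growth)
        assert np.all(np.diff(p) >= 0)
        assert np.all((p >= 0) & (p <= 1))

    def test_negative_length_rejected(self, growth):
        with pytest.raises(ValueError):
            branch_probability(-1.0, growth)


class TestShouldBranch:
    def test_non_active_state_never_branches(self, growth, rng):
        for state in (MetabolicState.PRODUCING, MetabolicState.MAINTENANCE,
                      MetabolicState.DEAD):
            assert not should_branch(1e4, state, growth, rng)

    def test_far_above_mean_always_fires(self, growth, rng):
        fires = [should_branch(1000.0, MetabolicState.ACTIVE, growth, rng)
                 for _ in range(200)]
        assert all(fires)

    def test_acceptance_frequency_at_mean(self, growth):
        rng = np.random.default_rng(7)
        n = 100_000
        hits = sum(should_branch(35.8, MetabolicState.ACTIVE, growth, rng)
                   for _ in range(n))
        se = math.sqrt(0.25 / n)
        assert hits / n == pytest.approx(0.5, abs=3 * se)


class TestBranchAngle:
    def test_bimodal_mixture_moments(self, growth):
        rng = np.random.default_rng(11)
        draws = np.array([sample_branch_angle(growth, rng) for _ in range(100_000)])
        assert abs(draws.mean()) < 0.5  # lobes symmetric about zero
        assert np.abs(draws).mean() == pytest.approx(
            84.0 * _mix_abs_correction(), rel=0.01
        )
        pos = draws[draws > 0]
        assert pos.mean() == pytest.approx(84.0, rel=0.01)
        assert pos.std(ddof=1) == pytest.approx(23.0, rel=0.05)


def _mix_abs_correction():
    """E|N(84, 23²)| / 84 — the folded-normal correction to the naive mean
    (computed in closed form as the independent oracle)."""
    mu, sd = 84.0, 23.0
    z = mu / sd
    return (
        sd * math.sqrt(2 / math.pi) * math.exp(-z * z / 2) + mu * (2 * _phi(z) - 1)
    ) / mu


class TestBranchPointLocation:
    def test_straight_path(self, growth):
        h = Hypha(id=0, origin=np.zeros(2),
                  path=[np.array([0.0, 0.0]), np.array([20.0, 0.0])], length=20.0)
        point, tangent = locate_branch_point(h, growth)
        assert point == pytest.approx([7.3, 0.0])
        assert tangent == pytest.approx([1.0, 0.0])

    def test_short_hypha_defers(self, growth):
        h = Hypha(id=0, origin=np.zeros(2),
                  path=[np.zeros(2), np.array([5.0, 0.0])], length=5.0)
        assert locate_branch_point(h, growth) is None

    def test_elbow_path_against_fine_resampling_oracle(self, growth):
        # 10 um along +x then 10 um along +y; branch point at arc 7.3
        h = Hypha(id=0, origin=np.zeros(2),
                  path=[np.zeros(2), np.array([10.0, 0.0]), np.array([10.0, 10.0])],
                  length=20.0)
        point, tangent = locate_branch_point(h, growth)
        # oracle: walk a 1e-4-resampled polyline and take the nearest vertex
        fine = hs.resample_polyline(np.array(h.path, dtype=float), 1e-4)
        oracle = fine[int(round(7.3 / 1e-4))]
        assert point == pytest.approx(oracle, abs=1e-3)
        assert tangent == pytest.approx([1.0, 0.0])

    def test_branch_point_beyond_elbow(self, growth):
        g = hs.GrowthParams(l2=12.0)
        h = Hypha(id=0, origin=np.zeros(2),
                  path=[np.zeros(2), np.array([10.0, 0.0]), np.array([10.0, 10.0])],
                  length=20.0)
        point, tangent = locate_branch_point(h, g)
        assert point == pytest.approx([10.0, 2.0])
        assert tangent == pytest.approx([0.0, 1.0])


class TestExecuteBranch:
    def _parent(self):
        return Hypha(id=0, origin=np.zeros(2),
                     path=[np.zeros(2), np.array([20.0, 0.0])], length=20.0)

    def test_successful_branch_geometry(self, growth):
        h = self._parent()
        point, tangent = locate_branch_point(h, growth)
        daughter, event, vel = execute_branch(
            h, 84.0, point, tangent, growth, daughter_id=1
        )
        assert event.successful
        assert daughter.length == 0.0
        assert daughter.origin == pytest.approx([7.3, 0.0])
        assert daughter.parent_id == 0
        # parent length resets to straight-line tip-to-branch-point distance
        assert h.length == pytest.approx(20.0 - 7.3)
        assert h.origin == pytest.approx([7.3, 0.0])
        # daughter speed is exactly v_avg, heading rotated +84 degrees CCW
        assert np.linalg.norm(vel) == pytest.approx(6.3)
        ang = math.degrees(math.atan2(vel[1], vel[0]))
        assert ang == pytest.approx(84.0)

    def test_low_oxygen_branch_fails(self, growth, thresholds):
        h = self._parent()
        point, tangent = locate_branch_point(h, growth)
        daughter, event, vel = execute_branch(
            h, 84.0, point, tangent, growth,
            oxygen_fraction=0.30, thresholds=thresholds,
        )
        assert daughter is None and vel is None
        assert not event.successful
        assert h.length == 20.0  # parent untouched
        assert h.origin == pytest.approx([0.0, 0.0])

    def test_oxygen_at_gate_threshold_succeeds(self, growth, thresholds):
        h = self._parent()
        point, tangent = locate_branch_point(h, growth)
        daughter, event, _ = execute_branch(
            h, -84.0, point, tangent, growth,
            oxygen_fraction=thresholds.maintenance_hi, thresholds=thresholds,
        )
        assert event.successful and daughter is not None


class TestRealisedDistributions:
    def test_branch_length_distribution_matches_hazard_oracle(self, growth):
        """Growing a hypha at v_avg and applying the per-step rule, the
        realised branch-length distribution must match the discrete hazard
        chain built independently from the same CDF."""
        dt, v = growth.dt, growth.v_avg
        step = v * dt
        # oracle: exact survival chain S_k = prod(1 - p(L_j))
        kmax = 4000
        L_grid = step * np.arange(1, kmax + 1)
        p_grid = np.array([_phi((L - 35.8) / 12.4) for L in L_grid])
        surv = np.concatenate([[1.0], np.cumprod(1 - p_grid)])
        fire_prob = surv[:-1] * p_grid
        oracle_mean = float((fire_prob * L_grid).sum() / fire_prob.sum())
        oracle_q90 = float(L_grid[np.searchsorted(
            np.cumsum(fire_prob) / fire_prob.sum(), 0.9)])

        rng = np.random.default_rng(5)
        fired = []
        for _ in range(2000):
            L = 0.0
            while True:
                L += step
                if should_branch(L, MetabolicState.ACTIVE, growth, rng):
                    fired.append(L)
                    break
        fired = np.asarray(fired)
        se = fired.std(ddof=1) / np.sqrt(len(fired))
        assert fired.mean() == pytest.approx(oracle_mean, abs=3 * se)
        assert np.quantile(fired, 0.9) == pytest.approx(oracle_q90, rel=0.05)

    def test_pooled_run_angles_form_two_lobes(self, short_run):
        ev = short_run.events
        angles = ev["angle"].to_numpy()
        assert len(angles) >= 20
        pos, neg = angles[angles > 0], angles[angles < 0]
        assert len(pos) > 0 and len(neg) > 0
        assert pos.mean() == pytest.approx(84.0, abs=3 * 23.0 / np.sqrt(len(pos)) + 2.0)
        assert neg.mean() == pytest.approx(-84.0, abs=3 * 23.0 / np.sqrt(len(neg)) + 2.0)


def test_lineage_forms_a_tree(short_run):
    ids = {h.id for h in short_run.hyphae}
    for h in short_run.hyphae:
        if h.parent_id is not None:
            assert h.parent_id in ids
            assert h.parent_id < h.id  # parents precede daughters: no cycles
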