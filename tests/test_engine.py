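import dataclasses

import numpy as np
import pytest

import hyphasim as hs


class TestReproducibility:
    def test_same_seed_bit_identical(self):
        s = hs.RunSettings(t_end=6.0)
        a = hs.run(settings=s, seed=11)
        b = hs.run(settings=s, seed=11)
        assert np.array_equal(a.points["position"], b.points["position"])
        assert np.array_equal(a.tips["velocity"], b.tips["velocity"])
        assert np.array_equal(a.grid.c, b.grid.c)
        assert a.events.equals(b.events)
        assert a.metrics.equals(b.metrics)

    def test_different_seeds_differ(self):
        s = hs.RunSettings(t_end=4.0)
        a = hs.run(settings=s, seed=1)
        b = hs.run(settings=s, seed=2)
        assert not np.array_equal(a.points["position"], b.points["position"])


class TestDecouplingLimit:
    def test_zero_consumption_equals_field_free_run(self):
        """With consumption off, the full engine must reproduce the bare
        elongation+branching model draw for draw."""
        s = hs.RunSettings(t_end=4.0)
        sub0 = hs.SubstrateParams(dbar_a=0.0)
        with_field = hs.run(substrate=sub0, settings=s, seed=5)
        without = hs.run(settings=s, seed=5, field_free=True)
        assert np.array_equal(with_field.points["position"],
                              without.points["position"])
        assert np.array_equal(with_field.tips["position"],
                              without.tips["position"])
        assert with_field.events.equals(without.events)

    def test_unlimited_oxygen_keeps_everything_active(self):
        sub = hs.SubstrateParams(dbar_a=1e-12)
        res = hs.run(substrate=sub, settings=hs.RunSettings(t_end=6.0), seed=3)
        assert np.all(res.points["state"] == 0)
        assert res.first_producing_time is None


class TestMonotoneGrowth:
    def test_length_and_tips_nondecreasing(self, short_run):
        m = short_run.metrics
        assert np.all(np.diff(m["total_length"]) >= 0)
        assert np.all(np.diff(m["n_tips_total"]) >= 0)

    def test_tip_count_equals_two_plus_successful_branches(self, short_run):
        m = short_run.metrics.iloc[-1]
        assert m["n_tips_total"] == 2 + m["n_branch_success"]
        assert len(short_run.hyphae) == m["n_tips_total"]

    def test_exponential_tip_growth_rate_matches_hgu(self):
        """Unlimited substrate: tips grow exponentially at rate ≈ v_avg/HGU
        (balanced growth: total length = HGU × tips and dL/dt = v × tips)."""
        rates, hgus = [], []
        s = hs.RunSettings(t_end=12.0)
        for seed in (1, 2, 3):
            res = hs.run(settings=s, seed=seed, field_free=True)
            m = res.metrics.set_index("time")
            rate = (np.log(m.loc[12.0, "n_tips_total"])
                    - np.log(m.loc[4.0, "n_tips_total"])) / 8.0
            rates.append(rate)
            hgus.append(m.loc[12.0, "hgu"])
        predicted = 6.3 / np.mean(hgus)
        assert np.mean(rates) == pytest.approx(predicted, rel=0.30)


class TestDomainManagement:
    def test_fast_tips_trigger_enlargement(self):
        g = hs.GrowthParams(v_avg=12.6)
        s = hs.RunSettings(t_end=31.0, domain=400.0)
        res = hs.run(g, settings=s, seed=1)
        assert res.grid.domain > 400.0
        assert res.grid.h == pytest.approx(s.grid_h)  # spacing preserved
        # all biomass inside the final domain
        assert np.all(np.abs(res.points["position"]) < res.grid.domain / 2)

    def test_default_run_fits_default_domain(self, short_run):
        assert short_run.grid.domain == 400.0


class TestVelocitySweep:
    def test_single_velocity_reduces_to_run(self):
        s = hs.RunSettings(t_end=6.0)
        table = hs.run_velocity_sweep([6.3], [9], settings=s)
        direct = hs.run(settings=s, seed=9)
        assert len(table) == 1
        row = table.iloc[0]
        last = direct.metrics.iloc[-1]
        assert row["hgu_end"] == last["hgu"]
        assert row["max_diameter"] == last["max_diameter"]
        assert row["n_tips_total"] == last["n_tips_total"]

    def test_velocity_rows_and_onset_trend(self):
        s = hs.RunSettings(t_end=20.0)
        table = hs.run_velocity_sweep([4.4, 12.6], [1], settings=s)
        assert len(table) == 2
        slow = table[table.v_avg == 4.4].iloc[0]
        fast = table[table.v_avg == 12.6].iloc[0]
        # slower tips delay (or miss) antibiotic onset
        slow_onset = slow["first_producing_time"]
        fast_onset = fast["first_producing_time"]
        assert np.isnan(slow_onset) or fast_onset <= slow_onset

    def test_rejects_nonpositive_velocity(self):
        with pytest.raises(ValueError):
            hs.run_velocity_sweep([0.0], [1])


class TestProvenance:
    def test_provenance_replays(self, short_run):
        prov = short_run.provenance
        growth = hs.GrowthParams(**prov["growth"])
        substrate = hs.SubstrateParams(**prov["substrate"])
        thresholds = hs.MetabolicThresholds(**prov["thresholds"])
        settings = hs.RunSettings(**prov["settings"])
        replay = hs.run(growth, substrate, thresholds, settings,
                        seed=prov["seed"])
        assert np.array_equal(replay.points["position"],
                              short_run.points["position"])
        assert np.array_equal(replay.grid.c, short_run.grid.c)


def test_branching_pattern_report_ordering():
    """More frequent branching lowers the hyphal growth unit."""
    s = hs.RunSettings(t_end=12.0)
    _, substrate, thresholds, _ = hs.default_params()
    results = {
        name: [hs.run(g, substrate, thresholds, s, seed=k) for k in (1, 2)]
        for name, g in hs.BRANCHING_PATTERNS.items()
    }
    table = hs.branching_pattern_report(results, strict=True)
    assert table.loc["III", "hgu_mean"] < table.loc["II", "hgu_mean"]
    assert table.loc["II", "hgu_mean"] < table.loc["I", "hgu_mean"]
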