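"""Cell agents: cycle graphs, stochastic/fixed transitions, volume ODEs,
division conservation and death cycles."""

import numpy as np
import pytest
from scipy import stats

from hepasim.cycles import (CycleModel, Phase, REGULATED, build_death_models,
                            build_ki67_cycle, build_phase_table)
from hepasim.population import CellPopulation, HEPATOCYTE, VolumeParams


@pytest.fixture
def table():
    return build_phase_table()


def make_pop(table, n, phase="Ki67-", rng=None, spread=100.0):
    rng = rng or np.random.default_rng(0)
    pop = CellPopulation(table, n_substrates=0)
    pop.add_cells(rng.uniform(0, spread, size=(n, 3)), phase=phase)
    return pop


# ------------------------------------------------------------------- cycles
class TestCycleModels:
    def test_ki67_structure(self, table):
        cyc = build_ki67_cycle(total_cycle=2016.0)
        assert [p.name for p in cyc.phases] == ["Ki67-", "Ki67+pre", "Ki67+post"]
        assert cyc.phases[1].division_at_exit
        assert cyc.phases[0].rate == REGULATED

    def test_saturated_cycle_time_consistent(self):
        # mean total period at maximal entry = t_Kneg + t_pre + t_post
        cyc = build_ki67_cycle(t_pre=780.0, t_post=150.0, total_cycle=2016.0)
        assert cyc.t_Kneg_mean == pytest.approx(2016.0 - 780.0 - 150.0)
        assert cyc.t_Kneg_mean + 780.0 + 150.0 == pytest.approx(33.6 * 60.0)

    def test_post_mitotic_phase_two_half_lives(self):
        # two Ki-67 half-lives at the 75-min midpoint of 60-90 min
        cyc = build_ki67_cycle(t_post=2 * 75.0, total_cycle=2016.0)
        assert cyc.phases[2].duration == 150.0

    def test_invalid_durations_rejected(self):
        with pytest.raises(ValueError):
            build_ki67_cycle(t_pre=-5.0)
        with pytest.raises(ValueError):
            build_ki67_cycle(t_pre=1500.0, t_post=600.0, total_cycle=2016.0)

    def test_unreachable_phase_rejected(self):
        with pytest.raises(ValueError, match="unreachable"):
            CycleModel("bad", (Phase("a", duration=1.0, next_phase="a"),
                               Phase("orphan", duration=1.0)))

    def test_division_and_removal_exclusive(self):
        with pytest.raises(ValueError):
            Phase("x", duration=1.0, division_at_exit=True, removal_at_exit=True)


class TestAdvancePhase:
    def test_zero_rate_never_transitions(self, table, rng):
        pop = make_pop(table, 50)
        pop.entry_rate[:] = 0.0
        for _ in range(100):
            pop.advance_phase(6.0, rng)
        assert np.all(pop.phase == table.index("Ki67-"))

    def test_fixed_duration_fires_on_exact_step(self, rng):
        # 600-min phase at dt=6 fires on exactly the 100th step
        table = build_phase_table()
        pop = CellPopulation(table, 0)
        pop.add_cells([[0, 0, 0]], phase="Ki67+post")
        # Ki67+post duration is 150 min; use apoptotic with custom duration
        apo_table = build_phase_table(apoptosis_duration=600.0)
        pop = CellPopulation(apo_table, 0)
        pop.add_cells([[0, 0, 0]], phase="apoptotic")
        for step in range(99):
            pop.advance_phase(6.0, rng)
            assert len(pop) == 1, f"removed early at step {step}"
        pop.advance_phase(6.0, rng)
        assert len(pop) == 0  # removal fired exactly at step 100

    def test_stochastic_dwell_time_exponential(self, table):
        """Per-step Bernoulli with p = 1-exp(-r dt) gives exponential dwell."""
        rng = np.random.default_rng(99)
        n = 100_000
        r, dt = 0.001, 1.0
        remaining = np.full(n, True)
        exit_step = np.zeros(n, dtype=int)
        # simulate the same rule the population uses, in bulk
        for step in range(1, 12_000):
            u = rng.random(remaining.sum())
            fired = u < -np.expm1(-r * dt)
            idx = np.flatnonzero(remaining)[fired]
            exit_step[idx] = step
            remaining[idx] = False
            if not remaining.any():
                break
        dwell = exit_step[exit_step > 0] * dt
        assert abs(dwell.mean() - 1000.0) / 1000.0 < 0.02
        ks = stats.kstest(dwell, "expon", args=(0, 1000.0))
        assert ks.statistic < 1.63 / np.sqrt(len(dwell)) + dt / 2000.0

    def test_population_first_passage_survival(self, table):
        # quiescent survival after t = 1/r is exp(-1) (first passage only;
        # the cycle cannot return anyone within t_pre = 780 min)
        rng = np.random.default_rng(5)
        pop = make_pop(table, 20_000)
        pop.entry_rate[:] = 0.001
        dt = 6.0
        n0 = int((pop.phase == 0).sum())
        for _ in range(int(780 / dt)):
            pop.advance_phase(dt, rng)
        surv = int((pop.phase == 0).sum()) / n0
        assert abs(surv - np.exp(-0.001 * 780)) < 0.02


# ------------------------------------------------------------------ volumes
class TestVolume:
    def test_zero_rates_identity(self, table):
        pop = make_pop(table, 5)
        for f in ("r_F", "r_N", "r_C"):
            getattr(pop, f)[:] = 0.0
        v0 = pop.V.copy()
        for _ in range(50):
            pop.update_volume(6.0)
        np.testing.assert_array_equal(pop.V, v0)

    def test_nuclear_relaxation_closed_form(self, table):
        # V_NS(t) = V* + (V0 - V*) exp(-r t), matched within 0.5% at dt=6
        pop = make_pop(table, 1)
        pop.r_N[:] = 0.0033
        pop.r_F[:] = 0.0
        pop.r_C[:] = 0.0
        pop.V_NS[:] = 50.0
        pop.V_NS_star[:] = 200.0
        t_end = 600.0
        for _ in range(int(t_end / 6.0)):
            pop.update_volume(6.0)
        expected = 200.0 + (50.0 - 200.0) * np.exp(-0.0033 * t_end)
        assert abs(pop.V_NS[0] - expected) / expected < 0.005

    def test_volume_additivity(self, table, rng):
        pop = make_pop(table, 100)
        pop.V_NS_star *= rng.uniform(0.5, 2.0, len(pop))
        for _ in range(200):
            pop.update_volume(6.0)
            np.testing.assert_allclose(pop.V, pop.V_F + pop.V_NS + pop.V_CS,
                                       rtol=1e-9)

    def test_doubling_targets_doubles_steady_state(self, table):
        pop = make_pop(table, 1)
        v_ss = pop.V[0]  # starts at the fixed point
        pop.set_hypertrophy(2.0)
        for _ in range(5000):
            pop.update_volume(6.0)
        assert pop.V[0] / v_ss == pytest.approx(2.0, rel=0.01)

    def test_radius_consistent_with_volume(self, table):
        pop = make_pop(table, 10)
        np.testing.assert_allclose(
            4.0 / 3.0 * np.pi * pop.radius**3, pop.V, rtol=1e-9
        )


# ----------------------------------------------------------------- division
class TestDivision:
    def test_division_conserves_compartments(self, table, rng):
        pop = make_pop(table, 20)
        totals = {f: getattr(pop, f).sum() for f in ("V_F", "V_NS", "V_CS")}
        n0 = len(pop)
        pop.divide(np.arange(10), rng)
        assert len(pop) == n0 + 10
        for f, t in totals.items():
            assert getattr(pop, f).sum() == pytest.approx(t, rel=1e-12)

    def test_parent_volume_split_exactly_half(self, table, rng):
        pop = make_pop(table, 1)
        v_parent = pop.V[0]
        pop.divide(np.array([0]), rng)
        np.testing.assert_allclose(pop.V, v_parent / 2.0)

    def test_daughter_separation_equals_parent_radius(self, table, rng):
        pop = make_pop(table, 1)
        r_parent = pop.radius[0]
        pop.divide(np.array([0]), rng)
        d = np.linalg.norm(pop.position[0] - pop.position[1])
        assert d == pytest.approx(r_parent, rel=1e-9)

    def test_generation_increments_and_post_mitotic_entry(self, table, rng):
        pop = make_pop(table, 1, phase="Ki67+pre")
        pop.divide(np.array([0]), rng)
        assert np.all(pop.generation == 1)
        assert np.all(pop.phase == table.index("Ki67+post"))
        assert np.all(pop.t_phase == 0.0)

    def test_division_directions_uniform_on_sphere(self, table):
        """Rayleigh test of daughter displacement directions at alpha=0.01."""
        rng = np.random.default_rng(2024)
        pop = make_pop(table, 10_000, spread=1e6)
        parents = pop.position[:10_000].copy()
        pop.divide(np.arange(10_000), rng)
        u = pop.position[:10_000] - parents
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        n = len(u)
        rayleigh = 3.0 * np.linalg.norm(u.sum(axis=0)) ** 2 / n
        # under uniformity the statistic is ~ chi2(3)
        assert rayleigh < stats.chi2.ppf(0.99, df=3)


# -------------------------------------------------------------------- death
class TestDeathCycles:
    def test_models_build(self):
        apo, nec = build_death_models()
        assert apo.phases[0].removal_at_exit
        assert nec.phases[0].next_phase == "necrotic_lysed"
        assert nec.phases[1].removal_at_exit

    def test_apoptotic_volume_monotone_nonincreasing(self, table, rng):
        pop = make_pop(table, 20)
        pop.start_death(np.arange(20), "apoptotic")
        prev = pop.V.copy()
        for _ in range(50):
            pop.update_volume(6.0)
            assert np.all(pop.V <= prev + 1e-9)
            prev = pop.V.copy()

    def test_necrotic_swelling_fluid_fraction_rises(self, table, rng):
        pop = make_pop(table, 10)
        f0 = (pop.V_F / pop.V).copy()
        pop.start_death(np.arange(10), "necrotic_swelling")
        for _ in range(200):
            pop.update_volume(6.0)
        assert np.all(pop.V_F / pop.V > f0)

    def test_apoptotic_cohort_removed_at_duration(self, rng):
        table = build_phase_table(apoptosis_duration=516.0)
        pop = make_pop(table, 1000)
        pop.start_death(np.arange(1000), "apoptotic")
        steps_to_clear = 0
        dt = 6.0
        while len(pop) and steps_to_clear < 200:
            pop.advance_phase(dt, rng)
            steps_to_clear += 1
        assert steps_to_clear == int(np.ceil(516.0 / dt))
        assert len(pop) == 0
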