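"""Per-individual rules: movement decisions, reproduction, energy priorities."""

import numpy as np
import pytest
from scipy import stats

from allosim import agents
from allosim.agents import Individual, MUTATION_RATE, N_EGGS
from allosim.allometry import (
    AllometryConstants,
    SECONDS_PER_DAY,
    basal_metabolic_power,
    clutch_mass,
)
from allosim.landscape import LandscapeConfig, generate_landscape

CONSTS = AllometryConstants()


def make_adult(W_max=1e-4, E_r=1e4, cell=(0, 0)):
    return Individual(id=0, stage="adult", W=W_max, W_max=W_max, E_r=E_r, location=cell)


class TestMoveProbability:
    def test_abundant_resources_mean_no_move(self):
        assert agents.move_probability(1_000.0, 1_000.0) == 0.0
        assert agents.move_probability(2_000.0, 1_000.0) == 0.0

    def test_empty_cell_forces_move(self):
        assert agents.move_probability(0.0, 500.0) == 1.0

    def test_linear_form(self):
        assert agents.move_probability(500.0, 1_000.0) == 0.5

    def test_no_demand_convention(self):
        assert agents.move_probability(500.0, 0.0) == 0.0

    def test_vectorised_over_cells(self):
        p = agents.move_probability([0.0, 500.0, 2_000.0], [100.0, 1_000.0, 100.0])
        assert list(p) == [1.0, 0.5, 0.0]


class TestPlanMovement:
    def test_largest_adult_with_ample_reserve(self):
        ind = make_adult(W_max=3e-3, E_r=1e6)
        plan = agents.plan_movement(ind, "coupled")
        assert plan.t_m == 3_600.0
        assert plan.v == pytest.approx(0.05565272300684766)
        assert plan.d_max == pytest.approx(200.3498028246516)
        assert plan.cost == pytest.approx(3_600.0 * 1.2379163732620794e-02)

    def test_empty_reserve_gives_stationary_search(self):
        ind = make_adult(W_max=1e-4, E_r=0.0)
        plan = agents.plan_movement(ind, "coupled")
        assert plan.t_m == 0.0
        assert plan.d_max == 0.0
        assert plan.rad == pytest.approx(plan.d_per)

    def test_reserve_limits_movement_time(self):
        ind = make_adult(W_max=1e-4, E_r=0.01)
        plan = agents.plan_movement(ind, "coupled")
        assert plan.t_m < 3_600.0
        assert plan.cost == pytest.approx(0.01)

    def test_decoupled_draws_stay_within_published_bounds(self):
        rng = np.random.default_rng(0)
        ind = make_adult(W_max=1e-5, E_r=1e6)
        for _ in range(200):
            plan = agents.plan_movement(ind, "decoupled", rng)
            assert 0.0106 <= plan.v <= 0.0557
            assert 0.1 <= plan.d_per <= 1.0

    def test_decoupled_requires_rng(self):
        with pytest.raises(ValueError):
            agents.plan_movement(make_adult(), "decoupled")


class TestChooseDestination:
    @pytest.fixture()
    def land(self):
        return generate_landscape(LandscapeConfig(nnd=1, n_suitable_target=100))

    def test_stays_when_origin_richest(self, land):
        rng = np.random.default_rng(1)
        land.resource[:] = 100.0
        land.resource[44] = 500.0
        dest = agents.choose_destination(land, land.coords[44], 2.0, rng)
        assert dest == tuple(land.coords[44])

    def test_moves_to_unique_richest_neighbour(self, land):
        rng = np.random.default_rng(1)
        land.resource[:] = 100.0
        land.resource[45] = 900.0
        dest = agents.choose_destination(land, land.coords[44], 2.0, rng)
        assert dest == tuple(land.coords[45])

    def test_out_of_range_riches_ignored(self, land):
        rng = np.random.default_rng(1)
        land.resource[:] = 100.0
        land.resource[0] = 2_000.0
        dest = agents.choose_destination(land, land.coords[55], 0.6, rng)
        assert dest == tuple(land.coords[55])

    def test_equal_ties_split_evenly(self, land):
        """Two equally rich cells in range are chosen ~50/50 (chi-square)."""
        rng = np.random.default_rng(7)
        land.resource[:] = 10.0
        left, right = 43, 45  # both 0.5 m from origin 44
        land.resource[left] = land.resource[right] = 1_500.0
        counts = {left: 0, right: 0}
        origin = land.coords[44]
        for _ in range(2_000):
            dest = agents.choose_destination(land, origin, 0.6, rng)
            counts[next(k for k in counts if dest == tuple(land.coords[k]))] += 1
        chi2 = sum((c - 1_000) ** 2 / 1_000 for c in counts.values())
        assert chi2 < stats.chi2.ppf(0.999, df=1)


class TestReproduction:
    def test_clutch_size_is_fifteen(self):
        ind = make_adult(W_max=1e-4, E_r=1e9)
        kids = agents.reproduce(ind, np.random.default_rng(0))
        assert len(kids) == N_EGGS
        assert ind.repro_done

    def test_below_threshold_no_clutch(self):
        ind = make_adult(W_max=1e-4, E_r=0.0)
        assert agents.reproduce(ind, np.random.default_rng(0)) == []
        assert not ind.repro_done

    def test_juveniles_cannot_reproduce(self):
        ind = make_adult()
        ind.stage = "juvenile"
        with pytest.raises(ValueError):
            agents.reproduce(ind, np.random.default_rng(0))

    def test_offspring_state(self):
        ind = make_adult(W_max=1e-4, E_r=1e9, cell=(3, 9))
        kids = agents.reproduce(ind, np.random.default_rng(0))
        egg_mass = clutch_mass(1e-4) / N_EGGS
        for kid in kids:
            assert kid.stage == "juvenile"
            assert kid.W == pytest.approx(egg_mass)
            assert kid.location == (3, 9)
            assert kid.E_r == pytest.approx(agents.starter_reserve(egg_mass))

    def test_threshold_increases_with_body_size(self):
        thresholds = agents.reproduction_threshold(np.array([1e-5, 1e-4, 1e-3, 3e-3]))
        assert np.all(np.diff(thresholds) > 0)

    def test_mutation_rate_and_bounds(self):
        """Across 10^6 births, ~0.1% mutate, all within the allowed interval."""
        rng = np.random.default_rng(42)
        parent = 1e-4
        kids = agents.mutate_genotypes(np.full(1_000_000, parent), rng)
        mutated = kids != parent
        # binomial(1e6, 0.001): mean 1000, sd ~31.6; allow 5 sigma
        assert abs(mutated.sum() - MUTATION_RATE * 1_000_000) < 160
        assert np.all(kids[mutated] >= parent / 2)
        assert np.all(kids[mutated] <= 1.5 * parent)

    def test_mutation_rejection_respects_physiological_limits(self):
        rng = np.random.default_rng(3)
        kids = agents.mutate_genotypes(np.full(50_000, 1e-5), rng, rate=1.0)
        assert np.all(kids >= 1e-5)
        assert np.all(kids <= 1.5e-5)
        kids = agents.mutate_genotypes(np.full(50_000, 3e-3), rng, rate=1.0)
        assert np.all(kids <= 3e-3)


class TestEnergyPriorities:
    def test_bmr_survival_and_starvation(self):
        W = 1e-4
        daily = SECONDS_PER_DAY * basal_metabolic_power(W)
        E_after, alive = agents.pay_bmr(2 * daily, W)
        assert alive and E_after == pytest.approx(daily)
        _, alive = agents.pay_bmr(0.5 * daily, W)
        assert not alive

    def test_intake_counts_toward_survival(self):
        W = 1e-4
        daily = SECONDS_PER_DAY * basal_metabolic_power(W)
        _, alive = agents.pay_bmr(0.0, W, intake=daily)
        assert alive

    def test_no_growth_without_energy(self):
        W_after, E_after, matured = agents.grow_and_mature(5e-5, 1e-4, 0.0)
        assert W_after == 5e-5
        assert E_after == 0.0
        assert not matured

    def test_maturation_at_99_percent(self):
        W_after, _, matured = agents.grow_and_mature(0.995e-4, 1e-4, 0.0)
        assert matured
        _, _, not_yet = agents.grow_and_mature(0.9e-4, 1e-4, 0.0)
        assert not not_yet

    def test_growth_energy_conservation(self):
        """Invested reserve equals tissue energy of the mass gained."""
        W, E = 2e-5, 50.0
        total_in = E
        for _ in range(200):
            W_new, E, _ = agents.grow_and_mature(W, 1e-4, E)
            W = W_new
        assert total_in - E == pytest.approx(
            CONSTS.tissue_energy_density * (W - 2e-5), rel=1e-9
        )

    def test_energy_limited_growth_is_partial(self):
        budget = CONSTS.tissue_energy_density * 1e-9  # pays for 1e-9 kg only
        W_after, E_after, _ = agents.grow_and_mature(2e-5, 1e-4, budget)
        assert W_after == pytest.approx(2e-5 + 1e-9)
        assert E_after == pytest.approx(0.0, abs=1e-12)
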