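"""Metapopulation demography: initialization, metabolism coupling,
spreading, quiescence, death, colonization and Kawasaki mixing."""

import math

import numpy as np
import pytest

from gutlattice.fba_core import FbaProblem, solve
from gutlattice.lattice_env import LatticeGeometry, MetaboliteField, fixture_geometry
from gutlattice.population_dynamics import (
    INITIAL_POPULATION_SIZE,
    MAX_POPULATION_SIZE,
    CommunityState,
    Population,
    colonize,
    die,
    initialize_community,
    metabolize_all,
    mix_populations,
    spread,
    update_quiescence,
    well_mixed_relocate,
)


@pytest.fixture
def small_state(consortium):
    g = fixture_geometry(10, 4)
    return CommunityState(g, consortium, np.random.default_rng(7))


class TestInitialization:
    def test_seeded_means_match_expectation(self, consortium):
        """Mean population count 540 and load 2.7e10 on the default lattice
        (sample means over seeded initializations within 3 standard errors)."""
        g = LatticeGeometry()  # 225x8
        n_init = 200
        counts = np.empty(n_init)
        for i in range(n_init):
            state = initialize_community(
                consortium, g, np.random.default_rng(1000 + i)
            )
            counts[i] = len(state.populations)
        expected = 0.3 * 1800
        se = math.sqrt(1800 * 0.3 * 0.7 / n_init)
        assert abs(counts.mean() - expected) < 3 * se
        # every population starts at 5e7 cells, so load = count * 5e7
        assert counts.mean() * INITIAL_POPULATION_SIZE == pytest.approx(
            2.7e10, rel=3 * se / expected
        )

    def test_single_species_roster(self, consortium):
        roster = {"bifido": consortium["bifido"]}
        state = initialize_community(
            roster, fixture_geometry(), np.random.default_rng(0)
        )
        assert state.populations
        assert all(p.species_id == "bifido" for p in state.populations)
        state.check_invariants()

    def test_empty_roster_rejected(self):
        with pytest.raises(ValueError):
            initialize_community({}, fixture_geometry(), np.random.default_rng(0))


class TestMetabolism:
    def test_site_pools_close_against_hand_solved_vertex(self, small_state):
        """One population on a lactose site: the site loses F_in * B_u
        lactose, gains the secreted products, and grows by the ATP yield."""
        state = small_state
        pop = Population("bifido", 1e10, col=2, row=1)  # one unit
        state.add_population(pop)
        f = MetaboliteField(state.geometry)
        f.amount("lcts_e")[1, 2] = 100.0
        ledger = metabolize_all(state, f, a=2.0)
        # bifido on plentiful lactose: ATP = 2 * 5/7, uptake = 2/7
        assert f.amount("lcts_e")[1, 2] == pytest.approx(100.0 - 2 / 7, rel=1e-8)
        assert f.amount("ac_e")[1, 2] == pytest.approx(3 * 2 / 7, rel=1e-8)
        assert f.amount("lac_L_e")[1, 2] == pytest.approx(2 * 2 / 7, rel=1e-8)
        expected_growth = (2 * 5 / 7) * 1e-6 / 1e-15  # umol ATP -> cells
        assert ledger.growth == pytest.approx(expected_growth, rel=1e-8)
        assert pop.B == pytest.approx(1e10 + expected_growth, rel=1e-8)

    def test_quiescent_population_touches_nothing(self, small_state):
        state = small_state
        state.add_population(
            Population("bifido", 2e10, col=2, row=1, quiescent=True)
        )
        f = MetaboliteField(state.geometry)
        f.amount("lcts_e")[1, 2] = 100.0
        ledger = metabolize_all(state, f, a=2.0)
        assert f.amount("lcts_e")[1, 2] == 100.0
        assert ledger.growth == 0.0
        assert ledger.quiescent_count == 1

    def test_empty_lattice_is_noop(self, small_state):
        f = MetaboliteField(small_state.geometry)
        ledger = metabolize_all(small_state, f)
        assert ledger.growth == 0.0

    def test_growth_is_capped_at_max_size(self, small_state):
        state = small_state
        pop = Population("bifido", 1.99e10, col=2, row=1)
        state.add_population(pop)
        f = MetaboliteField(state.geometry)
        f.amount("lcts_e")[1, 2] = 1e6
        metabolize_all(state, f, a=100.0)
        assert pop.B <= MAX_POPULATION_SIZE


class TestSpreadAndQuiescence:
    def test_halving_into_an_empty_neighbour(self, small_state):
        state = small_state
        state.add_population(Population("bifido", 1.2e10, col=3, row=1))
        spread(state)
        assert len(state.populations) == 2
        assert all(p.B == pytest.approx(6e9) for p in state.populations)
        state.check_invariants()

    def test_below_threshold_never_splits(self, small_state):
        state = small_state
        state.add_population(Population("bifido", 9e9, col=3, row=1))
        spread(state)
        assert len(state.populations) == 1

    def test_no_empty_neighbour_blocks_spread(self, consortium):
        g = fixture_geometry(3, 1)
        state = CommunityState(g, consortium, np.random.default_rng(0))
        for c in range(3):
            state.add_population(Population("bifido", 1.5e10, col=c, row=0))
        spread(state)
        assert len(state.populations) == 3

    def test_quiescence_flag_follows_the_cap(self, small_state):
        state = small_state
        p1 = Population("bifido", 2e10, col=1, row=1)
        p2 = Population("bifido", 1.9e10, col=3, row=1)
        state.add_population(p1)
        state.add_population(p2)
        update_quiescence(state)
        assert p1.quiescent and not p2.quiescent
        update_quiescence(state, enabled=False)
        assert not p1.quiescent


class TestDeathAndColonization:
    def test_death_is_binomial(self, consortium):
        g = fixture_geometry(20, 4)
        survivors = []
        for seed in range(300):
            state = CommunityState(g, consortium, np.random.default_rng(seed))
            for i in range(80):
                state.add_population(
                    Population("bifido", 1e9, col=i % 20, row=i // 20)
                )
            die(state, p=0.0075)
            survivors.append(len(state.populations))
        mean = np.mean(survivors)
        se = math.sqrt(80 * 0.0075 * 0.9925 / 300)
        assert abs(mean - 80 * 0.9925) < 3 * se

    def test_zero_probability_kills_nothing(self, small_state):
        state = small_state
        state.add_population(Population("bifido", 1e9, col=0, row=0))
        assert die(state, p=0.0) == 0.0
        assert len(state.populations) == 1

    def test_median_lifetime_matches_geometric_closed_form(self, consortium):
        """Simulated population lifetimes vs ln2/p (~92 steps at p=0.0075)."""
        rng = np.random.default_rng(99)
        n = 4000
        lifetimes = rng.geometric(0.0075, size=n)
        expected_median = math.log(2) / 0.0075
        assert np.median(lifetimes) == pytest.approx(expected_median, rel=0.08)

    def test_colonization_rate_and_disabling(self, consortium):
        g = fixture_geometry(20, 4)
        added = 0
        for seed in range(200):
            state = CommunityState(g, consortium, np.random.default_rng(seed))
            colonize(state, p=0.01, enabled=True)
            added += len(state.populations)
        # 80 empty sites, p=0.01 -> 0.8 expected per pass
        se = math.sqrt(80 * 0.01 * 0.99 / 200)
        assert abs(added / 200 - 0.8) < 3 * se

        state = CommunityState(g, consortium, np.random.default_rng(0))
        colonize(state, p=0.5, enabled=False)
        assert not state.populations

    def test_full_lattice_cannot_be_colonized(self, consortium):
        g = fixture_geometry(3, 1)
        state = CommunityState(g, consortium, np.random.default_rng(0))
        for c in range(3):
            state.add_population(Population("bifido", 1e9, col=c, row=0))
        colonize(state, p=1.0)
        assert len(state.populations) == 3


class TestMixing:
    def test_population_count_conserved_away_from_the_outlet(self, consortium):
        g = fixture_geometry(30, 4)
        state = CommunityState(g, consortium, np.random.default_rng(3))
        for i in range(10):
            state.add_population(
                Population("bifido", 1e9, col=2 + i % 5, row=i // 5)
            )
        for _ in range(5):
            mix_populations(state)
            state.check_invariants()
        assert len(state.populations) <= 10  # washout can only remove
        assert all(p.col < g.width - 1 for p in state.populations)

    def test_distal_populations_wash_out(self, consortium):
        g = fixture_geometry(5, 1)
        state = CommunityState(g, consortium, np.random.default_rng(0))
        state.add_population(Population("bifido", 1e9, col=4, row=0))
        removed = mix_populations(state, repeats=0)
        assert removed == 1e9
        assert not state.populations

    def test_single_walker_msd_is_linear_with_calibrated_variance(self, consortium):
        """The mixing walk's per-step displacement variance matches the
        metabolite kernel (0.57 L^2 per axis), i.e. D = 6.3e-5 cm^2/s."""
        g = LatticeGeometry(width=41, height=41)
        steps, walks = 15, 3000
        sq = 0.0
        for seed in range(walks):
            state = CommunityState(g, consortium, np.random.default_rng(seed))
            state.add_population(Population("bifido", 1e9, col=20, row=20))
            for _ in range(steps):
                mix_populations(state)
            p = state.populations[0]
            sq += (p.col - 20) ** 2 + (p.row - 20) ** 2
        msd = sq / walks  # sites^2, both axes
        expected = 2 * 0.57 * steps
        assert msd == pytest.approx(expected, rel=0.05)

    def test_well_mixed_relocation_keeps_one_population_per_site(self, consortium):
        g = fixture_geometry(10, 4)
        state = CommunityState(g, consortium, np.random.default_rng(5))
        for i in range(20):
            state.add_population(
                Population("bifido", 1e9, col=i % 8, row=i // 8)
            )
        well_mixed_relocate(state)
        state.check_invariants()
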