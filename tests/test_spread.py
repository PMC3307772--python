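import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from invadecon.landscape import NEVER, build_neighbor_index
from invadecon.spread import (
    DEFAULT_X_COLONIZE,
    KernelParams,
    SpreadState,
    kernel_cell_mass,
    logistic_increment,
    step_year,
)

from conftest import make_lattice


def run_years(land, params, years, seed=0, x_colonize=DEFAULT_X_COLONIZE):
    state = SpreadState.from_landscape(land)
    for year in range(1, years + 1):
        rng = np.random.default_rng([seed, year])
        state = step_year(state, land, params, rng, x_colonize=x_colonize)
    return state


class TestLogisticIncrement:
    def test_zero_is_absorbing(self):
        assert logistic_increment(0.0, 1.3) == 0.0

    def test_carrying_capacity_stops_growth(self):
        assert logistic_increment(100.0, 2.0) == 0.0

    def test_direct_evaluation(self):
        assert logistic_increment(50.0, 0.4) == pytest.approx(10.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            logistic_increment(-1.0, 0.5)
        with pytest.raises(ValueError):
            logistic_increment(101.0, 0.5)
        with pytest.raises(ValueError):
            logistic_increment(50.0, -0.1)

    @given(
        x=st.floats(0.0, 100.0),
        r=st.floats(0.0, 2.0),
    )
    def test_never_negative(self, x, r):
        assert logistic_increment(x, r) >= 0.0


class TestKernelCellMass:
    def test_diffuse_limit(self):
        d = 5_000.0
        masses = [
            kernel_cell_mass(d, 4927.0, KernelParams(mu=math.log(1200), sigma=s))
            for s in (1.0, 10.0, 100.0, 1000.0)
        ]
        assert all(a > b for a, b in zip(masses, masses[1:]))
        assert masses[-1] < 1e-3

    @pytest.mark.parametrize(
        "mu,sigma", [(math.log(1200), 1.0), (math.log(600), 0.7), (math.log(2400), 1.3)]
    )
    def test_global_tiling_mass_is_one(self, mu, sigma):
        # oracle: the radial lognormal density integrates to 1, so a fine
        # tiling of the plane by small cells must capture ~all the mass
        params = KernelParams(mu=mu, sigma=sigma)
        h, extent = 50.0, 120_000.0
        ax = np.arange(-extent, extent, h) + h / 2.0
        X, Y = np.meshgrid(ax, ax)
        d = np.hypot(X, Y).ravel()
        total = kernel_cell_mass(d[d > 0], h, params).sum()
        assert total == pytest.approx(1.0, abs=0.01)

    def test_monotone_decay_beyond_median(self):
        params = KernelParams(mu=math.log(1200), sigma=1.0)
        assert kernel_cell_mass(15_000.0, 4927.0, params) < kernel_cell_mass(
            5_000.0, 4927.0, params
        )

    def test_nonpositive_distance_rejected(self):
        params = KernelParams()
        with pytest.raises(ValueError):
            kernel_cell_mass(0.0, 4927.0, params)
        with pytest.raises(ValueError):
            kernel_cell_mass(-10.0, 4927.0, params)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            KernelParams(sigma=0.0)
        with pytest.raises(ValueError):
            KernelParams(local_fraction=1.5)


class TestStepYear:
    def test_local_only_equals_logistic_map(self):
        land = make_lattice(1, 1, rate=0.8, occupancy=[2.0])
        params = KernelParams(local_fraction=1.0)
        state = run_years(land, params, 10)
        x = 2.0
        for _ in range(10):
            x = x + 0.8 * x * (1 - x / 100.0)
        assert state.occupancy[0] == pytest.approx(x)

    def test_dispersal_off_equivalence_multicell(self):
        rng = np.random.default_rng(3)
        occ = rng.uniform(0, 100, 20)
        land = make_lattice(4, 5, rate=0.5, occupancy=occ)
        build_neighbor_index(land, 30_000.0)
        state = run_years(land, KernelParams(local_fraction=1.0), 7)
        expect = occ.copy()
        for _ in range(7):
            expect = expect + 0.5 * expect * (1 - expect / 100.0)
        np.testing.assert_array_equal(state.occupancy, np.clip(expect, 0, 100))

    def test_input_state_not_modified(self, two_cell_landscape):
        state = SpreadState.from_landscape(two_cell_landscape)
        before = state.occupancy.copy()
        step_year(state, two_cell_landscape, KernelParams(), np.random.default_rng(0))
        np.testing.assert_array_equal(state.occupancy, before)
        assert state.year == 0

    def test_maturation_delay_gates_export(self):
        # cell 0 colonized at year 0; cell 1 far enough to receive only from 0
        land = make_lattice(1, 2, rate=0.6, occupancy=[10.0, 40.0],
                            colonized_year=[0, -10])
        build_neighbor_index(land, 10_000.0)
        params = KernelParams(local_fraction=0.5)
        mass = kernel_cell_mass(4927.0, 4927.0, params)
        state = SpreadState(year=0, occupancy=np.array([10.0, 40.0]),
                            colonized_year=np.array([0, -10]))
        for year in range(1, 5):
            g0 = 0.6 * state.occupancy[0] * (1 - state.occupancy[0] / 100.0)
            g1 = 0.6 * state.occupancy[1] * (1 - state.occupancy[1] / 100.0)
            mature0 = state.year - 0 >= 3
            # manual one-step oracle
            expect0 = state.occupancy[0] + (0.5 * g0 if mature0 else g0) + 0.5 * g1 * mass
            expect1 = state.occupancy[1] + 0.5 * g1 + (0.5 * g0 * mass if mature0 else 0.0)
            state = step_year(state, land, params, np.random.default_rng([9, year]))
            assert state.occupancy[0] == pytest.approx(expect0)
            assert state.occupancy[1] == pytest.approx(expect1), f"year {year}"

    def test_colonization_frequency_matches_binomial(self, two_cell_landscape):
        params = KernelParams(local_fraction=0.5)
        p12 = min(kernel_cell_mass(4927.0, 4927.0, params), 1.0)
        n = 10_000
        hits = 0
        state0 = SpreadState.from_landscape(two_cell_landscape)
        for seed in range(n):
            state = step_year(state0, two_cell_landscape, params,
                              np.random.default_rng([seed, 1]))
            hits += state.occupancy[1] > 0
        se = math.sqrt(p12 * (1 - p12) / n)
        assert hits / n == pytest.approx(p12, abs=3 * se)

    def test_colonized_cell_state(self, two_cell_landscape):
        params = KernelParams(local_fraction=0.5)
        for seed in range(200):
            state = step_year(
                SpreadState.from_landscape(two_cell_landscape),
                two_cell_landscape, params, np.random.default_rng([seed, 1]),
                x_colonize=0.25,
            )
            if state.occupancy[1] > 0:
                assert state.occupancy[1] == 0.25
                assert state.colonized_year[1] == 1
                break
        else:
            pytest.fail("no colonization observed in 200 seeded steps")

    def test_nonforested_never_colonizes(self):
        land = make_lattice(1, 3, occupancy=[80.0, 0.0, 0.0])
        land.forested[1] = False
        build_neighbor_index(land, 30_000.0)
        state = run_years(land, KernelParams(local_fraction=0.2), 15, seed=5)
        assert state.occupancy[1] == 0.0

    def test_determinism(self, two_cell_landscape):
        params = KernelParams(local_fraction=0.5)
        a = run_years(two_cell_landscape, params, 12, seed=11)
        b = run_years(two_cell_landscape, params, 12, seed=11)
        np.testing.assert_array_equal(a.occupancy, b.occupancy)
        np.testing.assert_array_equal(a.colonized_year, b.colonized_year)


class TestSpreadProperties:
    def test_occupancy_bounds_and_no_spontaneous_generation(self):
        # 1,000 random steps split over randomized small landscapes
        rng = np.random.default_rng(7)
        for trial in range(20):
            occ = np.where(rng.random(16) < 0.5, rng.uniform(0, 100, 16), 0.0)
            land = make_lattice(4, 4, rate=float(rng.uniform(0, 1.5)), occupancy=occ)
            build_neighbor_index(land, 30_000.0)
            params = KernelParams(
                mu=math.log(rng.uniform(500, 3000)),
                sigma=float(rng.uniform(0.5, 2.0)),
                local_fraction=float(rng.uniform(0, 1)),
            )
            state = SpreadState.from_landscape(land)
            for year in range(1, 51):
                state = step_year(state, land, params, np.random.default_rng([trial, year]))
                assert np.all(state.occupancy >= 0.0)
                assert np.all(state.occupancy <= 100.0)
                if not occ.any():
                    assert not state.occupancy.any()

    def test_empty_landscape_stays_empty(self):
        land = make_lattice(3, 3)
        build_neighbor_index(land, 30_000.0)
        state = run_years(land, KernelParams(local_fraction=0.1), 30, seed=1)
        assert not state.occupancy.any()
        assert (state.colonized_year == NEVER).all()

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_bounds_hold_for_any_seed(self, seed):
        land = make_lattice(2, 3, rate=1.2, occupancy=[90.0, 0, 0, 0, 0, 0])
        build_neighbor_index(land, 30_000.0)
        state = run_years(land, KernelParams(local_fraction=0.3), 10, seed=seed)
        assert np.all((state.occupancy >= 0) & (state.occupancy <= 100))


class TestFrontPropagation:
    def test_front_monotone_and_speed_orders_with_median(self):
        # homogeneous 1-row lattice; mean rightmost-invaded position must be
        # non-decreasing in time, with asymptotic slope increasing in exp(mu)
        def mean_front(mu):
            land = make_lattice(1, 120, rate=0.6, occupancy=[50.0] + [0.0] * 119)
            build_neighbor_index(land, 30_000.0)
            params = KernelParams(mu=mu, sigma=1.0, local_fraction=0.9)
            fronts = []
            for rep in range(50):
                state = SpreadState.from_landscape(land)
                pos = []
                for year in range(1, 26):
                    state = step_year(state, land, params,
                                      np.random.default_rng([rep, year]))
                    invaded = np.flatnonzero(state.occupancy > 0)
                    pos.append(invaded.max())
                fronts.append(pos)
            return np.mean(fronts, axis=0)

        slopes = []
        for median in (600.0, 1200.0, 2400.0):
            front = mean_front(math.log(median))
            assert np.all(np.diff(front) >= 0.0)
            slopes.append(np.polyfit(np.arange(10, 25), front[10:25], 1)[0])
        assert slopes[0] < slopes[1] < slopes[2]
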