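"""Microsimulation: determinism, analytic oracle agreement, mechanism patterns."""

from dataclasses import replace

import numpy as np
import pytest

import lexiscreen as lx
from lexiscreen.grid import InvitationSchedule
from lexiscreen.simulate import expected_death_grid, sample_count_grid


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"participation": 1.2},
            {"stage_shift": -0.1},
            {"incidence_base": -1e-4},
            {"lead_time_pmf": {2: 0.5, 3: 0.4}},     # does not sum to 1
            {"lead_time_pmf": {0: 1.0}},             # lead must be >= 1 year
            {"cohort_size": -5},
            {"schedules": {1: InvitationSchedule(2000)}},
        ],
    )
    def test_invalid_configs_rejected_before_simulation(self, kwargs):
        config = lx.SimulationConfig(**kwargs)
        with pytest.raises(ValueError):
            lx.simulate(config, seed=0)


class TestSimulate:
    def test_same_seed_reproduces_identical_output(self):
        config = lx.SimulationConfig(cohort_size=300)
        r1, w1 = lx.simulate(config, seed=9)
        r2, w2 = lx.simulate(config, seed=9)
        assert r1 == r2
        assert w1.equals(w2)
        r3, _ = lx.simulate(config, seed=10)
        assert r1 != r3

    def test_zero_hazard_yields_no_events_full_exposure(self, spec):
        config = lx.SimulationConfig(cohort_size=50, incidence_base=0.0)
        records, wy = lx.simulate(config, seed=1)
        assert records == []
        grid = lx.build_grid(records, wy, spec)
        assert np.all(grid.women_years == 50.0)
        exp = lx.expected_cell_rates(config)
        assert exp.stage24.sum() == 0 and exp.deaths.sum() == 0

    def test_null_world_mh_ratio_near_one(self, spec, partition):
        """No screening, identical baselines: eligible MH ratio ~ 1.

        60 replicate registries at Poisson-count scale; the mean estimate
        should sit within Monte-Carlo error of the null."""
        config = lx.SimulationConfig(cohort_size=1000,
                                     schedules={1: None, 2: None})
        exp = lx.expected_cell_rates(config)
        rng = np.random.default_rng(77)
        ests = []
        for _ in range(60):
            cases = rng.poisson(exp.stage24)
            strata = np.column_stack([
                cases[partition.eligible, 0], exp.women_years[partition.eligible, 0],
                cases[partition.eligible, 1], exp.women_years[partition.eligible, 1],
            ])
            ests.append(lx.mh_rate_ratio(strata).estimate)
        assert np.mean(ests) == pytest.approx(1.0, abs=0.02)

    def test_cell_means_match_analytic_oracle(self, small_sim, expected_default):
        """Law of large numbers: ~100k simulated women against the exact DP.

        Totals by (region, year) lie within 3 standard errors of the
        expected surfaces for diagnoses and deaths."""
        config, records, wy = small_sim
        _, exp = expected_default
        grid = lx.build_grid(records, wy, config.spec)
        for obs, mean in [(grid.stage24_cases, exp.stage24),
                          (grid.deaths, exp.deaths)]:
            o = obs.sum(axis=0)    # (n_years, 2)
            m = mean.sum(axis=0)
            se = np.sqrt(np.maximum(m, 1.0))
            assert np.all(np.abs(o - m) <= 3.2 * se)
        assert np.allclose(grid.women_years.sum(), exp.women_years.sum(),
                           rtol=5e-4)


class TestMechanismProperties:
    def test_participation_mixture_identity(self):
        """Expected outcomes at 70% participation are exactly the
        0.7/0.3 mixture of the full-participation and null worlds."""
        base = lx.SimulationConfig(cohort_size=500)
        full = lx.expected_cell_rates(replace(base, participation=1.0))
        none = lx.expected_cell_rates(replace(base, participation=0.0))
        mixed = lx.expected_cell_rates(replace(base, participation=0.7))
        for name in ("stage24", "stage1", "deaths", "women_years"):
            blend = 0.7 * getattr(full, name) + 0.3 * getattr(none, name)
            assert np.allclose(getattr(mixed, name), blend, atol=1e-9)

    def test_stage_shift_transient_then_sustained_deficit(self, spec):
        """Screening region shows a first-round stage 2-4 excess, then a
        sustained deficit relative to the unscreened region."""
        config = lx.SimulationConfig(
            cohort_size=1000, schedules={1: InvitationSchedule(2000), 2: None}
        )
        exp = lx.expected_cell_rates(config)
        rate = exp.stage24.sum(axis=0) / exp.women_years.sum(axis=0)
        ratio = rate[:, 0] / rate[:, 1]
        assert ratio[0] > 1.0                   # prevalence-round harvest
        assert np.all(ratio[1:] < 1.0)          # deficit thereafter
        assert ratio[4:].mean() < 0.95          # and it is sustained

    def test_mortality_benefit_lags_first_invitation(self, spec):
        """Death deficits appear only years after the first round; early
        years show no benefit (screen-advanced cases can only add deaths)."""
        screened = lx.SimulationConfig(
            cohort_size=1000, schedules={1: InvitationSchedule(2000), 2: None}
        )
        unscreened = replace(screened, schedules={1: None, 2: None})
        d_s = lx.expected_cell_rates(screened).deaths[..., 0].sum(axis=0)
        d_n = lx.expected_cell_rates(unscreened).deaths[..., 0].sum(axis=0)
        lead = int(round(screened.lead_time_mean))
        assert np.all(d_s[: 1 + lead] >= d_n[: 1 + lead] - 1e-9)
        assert np.all(d_s[-4:] < d_n[-4:])      # benefit established later
        assert d_s.sum() < d_n.sum()

    def test_invited_mortality_reduction_near_stated_world(self, partition):
        """Default parameters imply a long-run net mortality ratio ~0.91."""
        exp = lx.expected_cell_rates(lx.SimulationConfig(cohort_size=1000))
        m = partition.eligible
        d1, d0 = exp.deaths[m, 0], exp.deaths[m, 1]
        T1, T0 = exp.women_years[m, 0], exp.women_years[m, 1]
        T = T1 + T0
        net = (d1 * T0 / T).sum() / (d0 * T1 / T).sum()
        assert net == pytest.approx(0.91, abs=0.02)


class TestParametricCellRegistry:
    def test_expected_death_grid_places_net_ratio_in_eligible_cells_only(
        self, spec, partition
    ):
        wy = np.full((spec.n_ages, spec.n_years, 2), 10.0)
        rate = np.full(spec.n_ages, 0.5)
        means = expected_death_grid(spec, partition.eligible, wy, rate,
                                    background_ratio=0.96, net_ratio=0.85)
        assert np.allclose(means[..., 1], 5.0)
        assert np.allclose(means[partition.eligible, 0], 5.0 * 0.96 * 0.85)
        assert np.allclose(means[partition.too_old, 0], 5.0 * 0.96)

    def test_sampling_is_seeded_and_unbiased(self):
        means = np.full((4, 3, 2), 7.0)
        draws = sample_count_grid(means, np.random.default_rng(3))
        again = sample_count_grid(means, np.random.default_rng(3))
        assert np.array_equal(draws, again)
        big = sample_count_grid(np.full((200, 200), 7.0),
                                np.random.default_rng(4))
        assert big.mean() == pytest.approx(7.0, abs=0.05)
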