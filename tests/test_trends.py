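"""Stage 2-4 trend fits: band Poisson slopes, yearly ratios, conditional Poisson."""

import numpy as np
import pytest
from scipy.special import expit, logit

import lexiscreen as lx
from lexiscreen.trends import (
    annual_change,
    band_annual_change,
    fit_conditional_poisson,
    table1_bands,
    yearly_mh_ratios,
)
from conftest import make_grid


class TestAnnualChange:
    years = np.arange(2000, 2008)

    def test_exact_loglinear_data_recovered(self):
        counts = 100 * 1.05 ** (self.years - 2000)
        assert annual_change(counts, self.years, np.ones(8)) == pytest.approx(
            5.0, abs=1e-6
        )

    def test_constant_rates_give_zero(self):
        assert annual_change(np.full(8, 50.0), self.years, np.ones(8)) == pytest.approx(
            0.0, abs=1e-8
        )

    def test_two_point_closed_form(self):
        assert annual_change(
            [100, 90], [2000, 2001], [1.0, 1.0]
        ) == pytest.approx(-10.0, abs=1e-6)

    def test_invariant_to_persontime_rescaling(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(40, 8)
        wy = rng.gamma(5, 1, 8)
        a = annual_change(counts, self.years, wy)
        b = annual_change(counts, self.years, wy * 137.5)
        assert a == pytest.approx(b, abs=1e-8)

    def test_all_zero_counts_undefined(self):
        with pytest.raises(ValueError, match="trend undefined"):
            annual_change(np.zeros(8), self.years, np.ones(8))

    def test_fewer_than_two_years_rejected(self):
        with pytest.raises(ValueError):
            annual_change([5], [2000], [1.0])


class TestBands:
    def test_table1_band_geometry(self, spec):
        bands = table1_bands(spec)
        assert len(bands) == 7
        horizontal = [b for b in bands if b.kind == "attained_age"]
        # each 5-age x 8-year horizontal band holds 40 cells; 120 in all
        assert all(b.mask.sum() == 40 for b in horizontal)
        assert sum(b.mask.sum() for b in horizontal) == 120

    def test_band_slope_on_synthetic_decline(self, spec):
        years = spec.years
        stage24 = np.zeros((spec.n_ages, spec.n_years, 2))
        stage24[:, :, 0] = 200 * 0.97 ** (years - 2000)[None, :]
        stage24 = np.round(stage24)
        grid = make_grid(spec, stage24=stage24)
        band = table1_bands(spec)[0]
        assert band_annual_change(grid, 1, band) == pytest.approx(-3.0, abs=0.1)
        with pytest.raises(ValueError, match="trend undefined"):
            band_annual_change(grid, 2, band)


class TestYearlyRatios:
    def test_single_age_grid_year_ratio_is_crude(self):
        spec = lx.GridSpec(60, 60, 2000, 2001)
        part = lx.partition_cells(spec)
        stage24 = np.array([[[6, 2], [3, 3]]], dtype=float)
        wy = np.full((1, 2, 2), 1.0)
        wy[0, 0, 1] = 2.0
        grid = make_grid(spec, stage24=stage24, women_years=wy)
        ratios = yearly_mh_ratios(grid, part)
        assert ratios[0].estimate == pytest.approx((6 / 1.0) / (2 / 2.0))
        assert ratios[1].estimate == pytest.approx(1.0)

    def test_years_without_events_marked_undefined(self, spec, partition):
        stage24 = np.zeros((spec.n_ages, spec.n_years, 2))
        stage24[5, 3, 0] = stage24[5, 3, 1] = 4
        grid = make_grid(spec, stage24=stage24)
        ratios = yearly_mh_ratios(grid, partition)
        assert ratios[3] is not None
        assert all(r is None for k, r in enumerate(ratios) if k != 3)

    def test_null_expected_surfaces_give_unit_ratios(self, spec, partition):
        """No screening and identical baselines: every defined yearly ratio is 1."""
        config = lx.SimulationConfig(cohort_size=1000, schedules={1: None, 2: None})
        exp = lx.expected_cell_rates(config)
        grid = make_grid(spec, stage24=exp.stage24, women_years=exp.women_years)
        for rr in yearly_mh_ratios(grid, partition):
            assert rr.estimate == pytest.approx(1.0, abs=1e-9)

    def test_staggered_screening_transient_then_deficit(self, spec, partition,
                                                        expected_default):
        """First-round harvest pushes the ratio above 1, later years below."""
        _, exp = expected_default
        grid = make_grid(spec, stage24=exp.stage24, women_years=exp.women_years)
        est = [r.estimate for r in yearly_mh_ratios(grid, partition)]
        assert est[0] > 1.0
        assert all(e < 1.0 for e in est[1:9])  # before region 2's rounds bite


class TestConditionalPoisson:
    def test_symmetric_null_gives_half_split(self, spec, partition):
        stage24 = np.zeros((spec.n_ages, spec.n_years, 2))
        stage24[partition.eligible] = 12
        stage24[partition.too_old] = 8
        grid = make_grid(spec, stage24=stage24)
        model = fit_conditional_poisson(grid, partition, "constant")
        assert model.background_log_rr == pytest.approx(0.0, abs=1e-8)
        assert model.coefficients[0] == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(model.net_rr_by_year, 1.0)

    def test_single_cell_closed_form_mle(self):
        """One eligible cell: netRR = (n1/n0) / (T1/T0) / exp(background)."""
        spec = lx.GridSpec(60, 60, 2000, 2000)
        part = lx.partition_cells(spec)
        stage24 = np.array([[[17.0, 9.0]]])
        wy = np.array([[[1.8, 1.1]]])
        grid = make_grid(spec, stage24=stage24, women_years=wy)
        bg = np.log(1.05)
        model = fit_conditional_poisson(grid, part, "constant", background_log_rr=bg)
        closed = (17 / 9) / (1.8 / 1.1) / np.exp(bg)
        assert model.net_rr_by_year[0] == pytest.approx(closed, abs=1e-4)

    def test_constant_fit_single_stratum_matches_mh_over_background(self):
        spec = lx.GridSpec(60, 60, 2000, 2000)
        part = lx.partition_cells(spec)
        stage24 = np.array([[[23.0, 31.0]]])
        wy = np.array([[[2.5, 2.0]]])
        grid = make_grid(spec, stage24=stage24, women_years=wy)
        bg = 0.04
        model = fit_conditional_poisson(grid, part, "constant", background_log_rr=bg)
        mh = lx.mh_rate_ratio([(23, 2.5, 31, 2.0)])
        assert model.net_rr_by_year[0] == pytest.approx(
            mh.estimate / np.exp(bg), abs=1e-4
        )

    def test_fit_improves_on_null_and_centring_is_cosmetic(self, spec, partition):
        rng = np.random.default_rng(42)
        wy = np.full((spec.n_ages, spec.n_years, 2), 1.0)
        yc = (spec.years - 2006.5)[None, :]
        p = expit(np.where(partition.eligible, -0.2 + 0.01 * yc, 0.0))
        n = rng.poisson(30, size=p.shape)
        n1 = rng.binomial(n, p)
        grid = make_grid(spec, stage24=np.stack([n1, n - n1], axis=-1),
                         women_years=wy)
        model = fit_conditional_poisson(grid, partition, "quadratic")
        assert model.converged
        assert model.loglik >= model.null_loglik
        raw = fit_conditional_poisson(grid, partition, "quadratic", year_center=0.0)
        assert np.allclose(raw.net_rr_by_year, model.net_rr_by_year, rtol=1e-6)
        assert raw.background_log_rr == pytest.approx(model.background_log_rr)

    def test_separation_detected(self, spec, partition):
        stage24 = np.zeros((spec.n_ages, spec.n_years, 2))
        stage24[..., 0] = 5  # every event in region 1
        grid = make_grid(spec, stage24=stage24)
        with pytest.raises(ValueError, match="separation"):
            fit_conditional_poisson(grid, partition)

    def test_events_without_persontime_rejected(self, spec, partition):
        stage24 = np.zeros((spec.n_ages, spec.n_years, 2))
        stage24[partition.eligible] = 3
        stage24[partition.too_old] = 3
        grid = make_grid(spec, stage24=stage24)
        i, j = np.argwhere(partition.eligible)[0]
        grid.women_years[i, j, 1] = 0.0  # events remain in region 1 of that cell
        grid.stage24_cases[i, j, 1] = 0.0
        with pytest.raises(ValueError, match="positive person-time"):
            fit_conditional_poisson(grid, partition)
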