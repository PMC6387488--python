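"""Rates, the two projection scenarios, and growth-model behaviour."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from arthroburden import (
    PopulationSeries,
    RateTable,
    StratumCountTable,
    aggregate_rate,
    compute_rates,
    filter_primary_oa,
    fit_growth_model,
    generate_population,
    generate_registry,
    pct_increase,
    project_scenario1,
    project_scenario2,
    tabulate_counts,
)


def _population(rows):
    return PopulationSeries(
        pd.DataFrame(rows, columns=list(PopulationSeries.COLUMNS))
    )


def _counts(rows):
    return StratumCountTable(
        pd.DataFrame(rows, columns=list(StratumCountTable.COLUMNS))
    )


@pytest.fixture()
def one_cell():
    counts = _counts([("knee", "40-69", "female", 2013, 500)])
    pop = _population([("40-69", "female", 2013, 1_000_000, "observed")])
    return counts, pop


class TestComputeRates:
    def test_direct_arithmetic(self, one_cell):
        counts, pop = one_cell
        rates = compute_rates(counts, pop)
        assert rates.get("knee", "40-69", "female", 2013) == pytest.approx(50.0)

    def test_zero_count_zero_rate(self):
        counts = _counts([("hip", "70+", "male", 2010, 0)])
        pop = _population([("70+", "male", 2010, 50_000, "observed")])
        assert compute_rates(counts, pop).get("hip", "70+", "male", 2010) == 0.0

    def test_missing_denominator_names_stratum(self, one_cell):
        counts, _ = one_cell
        empty_pop = _population([("70+", "male", 2013, 1000, "observed")])
        with pytest.raises(KeyError, match="40-69"):
            compute_rates(counts, empty_pop)

    def test_empirical_rate_matches_generator(self, single_stratum_config):
        """At rate 200/100k and a large denominator, the realised rate sits
        within 3 Poisson standard errors of the generator rate."""
        config = single_stratum_config
        pop = generate_population(config)
        records, _ = generate_registry(config, pop)
        counts = tabulate_counts(
            filter_primary_oa(records),
            joints=("knee",),
            age_groups=("40-69",),
            sexes=("female",),
        )
        rates = compute_rates(counts, pop)
        n_pop = pop.get("40-69", "female", 2003)
        se = 1e5 * math.sqrt(200.0 * n_pop / 1e5) / n_pop
        assert rates.get("knee", "40-69", "female", 2003) == pytest.approx(
            200.0, abs=3 * se
        )

    def test_aggregate_rate_invariant_to_stratum_splits(self):
        """Splitting a cell into sub-strata leaves the aggregate rate unchanged."""
        merged = _counts([("knee", "40-69", "female", 2013, 300)])
        split = _counts(
            [
                ("knee", "40-69", "female", 2013, 120),
                ("knee", "40-69", "male", 2013, 180),
            ]
        )
        pop_merged = _population([("40-69", "female", 2013, 600_000, "observed")])
        pop_split = _population(
            [
                ("40-69", "female", 2013, 250_000, "observed"),
                ("40-69", "male", 2013, 350_000, "observed"),
            ]
        )
        assert aggregate_rate(merged, pop_merged, 2013) == pytest.approx(
            aggregate_rate(split, pop_split, 2013)
        )


class TestScenario1:
    def _rates(self):
        return RateTable(
            pd.DataFrame(
                [
                    ("knee", "40-69", "female", 2013, 100.0),
                    ("knee", "70+", "female", 2013, 400.0),
                ],
                columns=list(RateTable.COLUMNS),
            )
        )

    def test_flat_population_flat_counts(self):
        pop = _population(
            [
                ("40-69", "female", y, 1_000_000, "projected")
                for y in range(2013, 2031)
            ]
            + [("70+", "female", y, 100_000, "projected") for y in range(2013, 2031)]
        )
        res = project_scenario1(self._rates(), pop, 2013, 2030, "knee")
        totals = res.year_totals()
        assert totals.loc[2030] == pytest.approx(totals.loc[2013])
        assert totals.loc[2013] == pytest.approx(1000 + 400)

    def test_hand_computed_two_strata(self):
        pop = _population(
            [
                ("40-69", "female", 2013, 1_000_000, "observed"),
                ("40-69", "female", 2014, 1_100_000, "projected"),
                ("70+", "female", 2013, 100_000, "observed"),
                ("70+", "female", 2014, 150_000, "projected"),
            ]
        )
        res = project_scenario1(self._rates(), pop, 2013, 2014, "knee")
        # 100/1e5*1.1e6 + 400/1e5*1.5e5 = 1100 + 600
        assert res.total(2014) == pytest.approx(1700.0)

    def test_population_doubling_doubles_counts_exactly(self):
        years = range(2013, 2021)
        pop = _population(
            [("40-69", "female", y, 1_000_000 + 7 * y, "projected") for y in years]
            + [("70+", "female", y, 90_000 + y, "projected") for y in years]
        )
        res1 = project_scenario1(self._rates(), pop, 2013, 2020, "knee")
        res2 = project_scenario1(self._rates(), pop.scaled(2.0), 2013, 2020, "knee")
        assert np.allclose(
            2.0 * res1.table["count"].to_numpy(), res2.table["count"].to_numpy()
        )

    def test_horizon_before_base_rejected(self):
        pop = _population([("40-69", "female", 2013, 1000, "observed")])
        with pytest.raises(ValueError, match="precedes"):
            project_scenario1(self._rates(), pop, 2013, 2010, "knee")


def _exponential_fixture(beta=0.1, lam0=100.0, years=range(2003, 2014)):
    """Noise-free counts lam0*e^{beta*(t-t0)} on a constant population."""
    rows = [
        ("knee", "40-69", "female", y, lam0 * math.exp(beta * (y - 2003)))
        for y in years
    ]
    counts = StratumCountTable(
        pd.DataFrame(rows, columns=list(StratumCountTable.COLUMNS))
    )
    pop = _population(
        [("40-69", "female", y, 1_000_000, "observed") for y in range(2003, 2031)]
    )
    return counts, pop


class TestGrowthModel:
    def test_deterministic_exponential_counts_recover_slope(self):
        counts, pop = _exponential_fixture()
        model = fit_growth_model(counts, pop, "knee", base_year=2003)
        assert model.converged
        assert model.year_coefficient == pytest.approx(0.1, abs=1e-4)

    def test_zero_growth_slope_within_two_se(self, single_stratum_config):
        config = single_stratum_config
        pop = generate_population(config)
        records, _ = generate_registry(config, pop)
        counts = tabulate_counts(
            filter_primary_oa(records),
            joints=("knee",),
            age_groups=("40-69",),
            sexes=("female",),
        )
        model = fit_growth_model(counts, pop, "knee")
        assert abs(model.year_coefficient) < 2 * model.stderr["year_c"]

    def test_needs_two_years(self):
        counts = _counts([("knee", "40-69", "female", 2013, 5)])
        pop = _population([("40-69", "female", 2013, 1000, "observed")])
        with pytest.raises(ValueError, match="two distinct years"):
            fit_growth_model(counts, pop, "knee")

    def test_full_design_recovers_age_and_sex_effects(self, default_sim):
        """On the default synthetic study the fitted rate ratios between
        strata track the generator's baseline rate ratios."""
        config, pop, records, _ = default_sim
        counts = tabulate_counts(filter_primary_oa(records))
        model = fit_growth_model(counts, pop, "knee", base_year=2003)
        fitted_ratio = model.rate_per_100k("70+", "female", 2003) / model.rate_per_100k(
            "40-69", "female", 2003
        )
        true_ratio = (
            config.baseline_rates[("knee", "70+", "female")]
            / config.baseline_rates[("knee", "40-69", "female")]
        )
        assert fitted_ratio == pytest.approx(true_ratio, rel=0.15)


class TestScenario2:
    def test_closed_form_extrapolation(self):
        counts, pop = _exponential_fixture(beta=0.1, lam0=100.0)
        model = fit_growth_model(counts, pop, "knee", base_year=2003)
        res = project_scenario2(model, pop, 2030)
        expected = 100.0 * math.exp(0.1 * (2030 - 2003))  # constant population
        assert res.total(2030) == pytest.approx(expected, rel=1e-3)

    def test_monotone_totals_under_positive_slope(self):
        counts, pop = _exponential_fixture(beta=0.05)
        model = fit_growth_model(counts, pop, "knee", base_year=2013)
        totals = project_scenario2(model, pop, 2030).year_totals()
        assert (totals.diff().dropna() > 0).all()

    def test_unconverged_model_refused(self):
        counts, pop = _exponential_fixture()
        model = fit_growth_model(counts, pop, "knee")
        bad = type(model)(**{**model.__dict__, "converged": False})
        with pytest.raises(ValueError, match="converge"):
            project_scenario2(bad, pop, 2030)

    def test_horizon_beyond_population_coverage_refused(self):
        counts, pop = _exponential_fixture()
        model = fit_growth_model(counts, pop, "knee")
        with pytest.raises(ValueError, match="population series ends"):
            project_scenario2(model, pop, 2050)

    def test_zero_year_effect_reduces_to_scenario1(self, default_sim):
        """With the year coefficient forced to zero, extrapolating the fitted
        rates is cell-for-cell the constant-rate projection from those rates."""
        _, pop, records, _ = default_sim
        counts = tabulate_counts(filter_primary_oa(records))
        model = fit_growth_model(counts, pop, "knee", base_year=2013)
        frozen = model.with_year_coefficient(0.0)
        fitted_rates = RateTable(
            pd.DataFrame(
                [
                    ("knee", ag, sex, 2013, frozen.rate_per_100k(ag, sex, 2013))
                    for ag in model.age_levels
                    for sex in model.sex_levels
                ],
                columns=list(RateTable.COLUMNS),
            )
        )
        res1 = project_scenario1(fitted_rates, pop, 2013, 2030, "knee")
        res2 = project_scenario2(frozen, pop, 2030)
        key = ["age_group", "sex", "year"]
        merged = res1.table.merge(res2.table, on=key, suffixes=("_s1", "_s2"))
        assert len(merged) == len(res1.table)
        assert np.allclose(
            merged["count_s1"], merged["count_s2"], rtol=1e-8, atol=0.0
        )


class TestPctIncrease:
    @pytest.mark.parametrize(
        "base,final,expected",
        [(42_920, 161_231, 276), (25_945, 79_795, 208), (1000, 1000, 0)],
    )
    def test_values(self, base, final, expected):
        assert pct_increase(base, final) == expected

    def test_zero_base_rejected(self):
        with pytest.raises(ValueError):
            pct_increase(0, 10)
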