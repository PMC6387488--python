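"""Stratified incidence rates and two-scenario projection of procedure counts.

Scenario 1 holds the base-year age- and sex-specific surgery rates constant
and lets projected population growth drive procedure numbers:

    count(s, t) = rate(s, base) * population(s, t) / 100,000.

Scenario 2 assumes surgery rates keep growing as they did over the observed
decade.  A Poisson log-linear model of stratum-year counts with a
log-population offset, categorical age group and sex, and a linear
calendar-year term is fitted by maximum likelihood:

    log E[count(s, t)] = log(pop(s, t)/1e5) + a + b_age(s) + b_sex(s) + beta * (t - base)

so exp(linear predictor) is a rate per 100,000 extrapolated along the year
term, then multiplied by the projected population.  A no-offset pure-count
variant is available for comparison.  Models are fitted per joint; year
enters as a main effect only by default (age/sex-by-year interactions sit
behind a flag).

Projected counts are kept fractional internally and rounded half away from
zero only at report time.
"""

from __future__ import annotations

import math
import dataclasses
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._util import iround_half_away
from .registry_core import AGE_GROUPS, SEXES, StratumCountTable

__all__ = [
    "PopulationSeries",
    "RateTable",
    "GrowthModel",
    "ProjectionResult",
    "compute_rates",
    "aggregate_rate",
    "project_scenario1",
    "fit_growth_model",
    "project_scenario2",
    "pct_increase",
]


@dataclass
class PopulationSeries:
    """Population per (age group, sex, year), observed or projected.

    Tidy DataFrame with columns ``age_group, sex, year, population,
    provenance`` where provenance is ``observed`` or ``projected``.
    """

    df: pd.DataFrame

    COLUMNS = ("age_group", "sex", "year", "population", "provenance")

    def __post_init__(self) -> None:
        self.df = self.df.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        if (self.df["population"] <= 0).any():
            raise ValueError("population counts must be positive")
        self._lookup = {
            (r.age_group, r.sex, r.year): int(r.population)
            for r in self.df.itertuples()
        }

    @classmethod
    def from_csv(cls, path: str | Path) -> "PopulationSeries":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    def get(self, age_group: str, sex: str, year: int) -> int:
        try:
            return self._lookup[(age_group, sex, year)]
        except KeyError:
            raise KeyError(
                f"no population for stratum (age_group={age_group}, sex={sex}, "
                f"year={year})"
            ) from None

    def total(self, year: int) -> int:
        sub = self.df[self.df["year"] == year]
        if sub.empty:
            raise KeyError(f"no population for year {year}")
        return int(sub["population"].sum())

    @property
    def years(self) -> list[int]:
        return sorted(self.df["year"].unique().tolist())

    def scaled(self, factor: float) -> "PopulationSeries":
        """A copy with every cell multiplied by ``factor`` (rounded to int)."""
        df = self.df.copy()
        df["population"] = (df["population"] * factor).round().astype(int)
        return PopulationSeries(df)


@dataclass
class RateTable:
    """Procedure rates per 100,000 population per (joint, age group, sex, year)."""

    df: pd.DataFrame

    COLUMNS = ("joint", "age_group", "sex", "year", "rate")

    def __post_init__(self) -> None:
        self.df = self.df.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        if (self.df["rate"] < 0).any():
            raise ValueError("rates must be non-negative")

    def get(self, joint: str, age_group: str, sex: str, year: int) -> float:
        mask = (
            (self.df["joint"] == joint)
            & (self.df["age_group"] == age_group)
            & (self.df["sex"] == sex)
            & (self.df["year"] == year)
        )
        sub = self.df.loc[mask, "rate"]
        if sub.empty:
            raise KeyError((joint, age_group, sex, year))
        return float(sub.iloc[0])

    def at_year(self, year: int) -> "RateTable":
        return RateTable(self.df[self.df["year"] == year].copy())

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


def compute_rates(
    counts: StratumCountTable, population: PopulationSeries
) -> RateTable:
    """Rates per 100,000: ``1e5 * count / population`` cell-wise.

    Raises KeyError naming the stratum if a denominator cell is missing.
    """
    rows = []
    for r in counts.df.itertuples():
        pop = population.get(r.age_group, r.sex, r.year)
        rows.append(
            (r.joint, r.age_group, r.sex, r.year, 1e5 * r.count / pop)
        )
    return RateTable(pd.DataFrame(rows, columns=list(RateTable.COLUMNS)))


def aggregate_rate(
    counts: StratumCountTable,
    population: PopulationSeries,
    year: int,
    joint: str | None = None,
) -> float:
    """Aggregate rate for one year: 1e5 * total count / total denominator."""
    total = int(counts.year_totals(joint).get(year, 0))
    return 1e5 * total / population.total(year)


@dataclass
class ProjectionResult:
    """Projected procedure counts for one joint under a named scenario.

    ``table`` holds fractional expected counts per (age_group, sex, year),
    including the base year; totals and report rounding are derived.
    """

    scenario: str
    joint: str
    base_year: int
    table: pd.DataFrame  # columns: age_group, sex, year, count

    def __post_init__(self) -> None:
        self.table = self.table.loc[
            :, ["age_group", "sex", "year", "count"]
        ].reset_index(drop=True)
        if (self.table["count"] < 0).any():
            raise ValueError("projected counts must be non-negative")

    def year_totals(self) -> pd.Series:
        return self.table.groupby("year")["count"].sum()

    def total(self, year: int) -> float:
        return float(self.year_totals().loc[year])

    def total_rounded(self, year: int) -> int:
        return iround_half_away(self.total(year))

    def rate_per_100k(self, population: PopulationSeries, year: int) -> float:
        return 1e5 * self.total(year) / population.total(year)

    def sex_totals(self, year: int) -> dict[str, float]:
        sub = self.table[self.table["year"] == year]
        return sub.groupby("sex")["count"].sum().to_dict()

    def age_group_year_totals(self) -> pd.DataFrame:
        return (
            self.table.groupby(["year", "age_group"])["count"]
            .sum()
            .reset_index()
        )

    def to_csv(self, path: str | Path) -> None:
        out = self.table.copy()
        out["count_rounded"] = out["count"].map(iround_half_away)
        totals = self.year_totals().reset_index()
        totals["age_group"] = "total"
        totals["sex"] = "all"
        totals["count_rounded"] = totals["count"].map(iround_half_away)
        pd.concat([out, totals], ignore_index=True).to_csv(path, index=False)


def project_scenario1(
    base_rates: RateTable,
    population: PopulationSeries,
    base_year: int,
    horizon: int,
    joint: str,
) -> ProjectionResult:
    """Constant-rate projection: base-year stratum rates applied to the
    projected population for every year from the base year to the horizon."""
    if horizon < base_year:
        raise ValueError(f"horizon {horizon} precedes base year {base_year}")
    sub = base_rates.df[
        (base_rates.df["joint"] == joint) & (base_rates.df["year"] == base_year)
    ]
    if sub.empty:
        raise ValueError(f"no {joint} rates at base year {base_year}")
    rows = []
    for year in range(base_year, horizon + 1):
        for r in sub.itertuples():
            pop = population.get(r.age_group, r.sex, year)
            rows.append((r.age_group, r.sex, year, r.rate * pop / 1e5))
    return ProjectionResult(
        scenario="scenario1",
        joint=joint,
        base_year=base_year,
        table=pd.DataFrame(rows, columns=["age_group", "sex", "year", "count"]),
    )


@dataclass
class GrowthModel:
    """Fitted Poisson log-linear growth model for one joint.

    ``params`` maps design-column names (``const``, ``age[...]``,
    ``sex[...]``, ``year_c``, optionally interaction columns) to
    coefficients.  ``year_c`` is calendar year centred at ``base_year``;
    with the offset convention, exp(linear predictor) is a rate per
    100,000 population.
    """

    joint: str
    params: dict[str, float]
    base_year: int
    age_levels: tuple[str, ...]
    sex_levels: tuple[str, ...]
    use_offset: bool = True
    interactions: bool = False
    llf: float = float("nan")
    converged: bool = True
    stderr: dict[str, float] = dataclasses.field(default_factory=dict)

    @property
    def year_coefficient(self) -> float:
        return self.params["year_c"]

    def with_year_coefficient(self, value: float) -> "GrowthModel":
        """Copy with the year slope (and any interactions) replaced by ``value``."""
        params = dict(self.params)
        for name in params:
            if name == "year_c" or name.startswith("year_c:"):
                params[name] = 0.0
        params["year_c"] = value
        return replace(self, params=params)

    def linear_predictor(self, age_group: str, sex: str, year: int) -> float:
        lp = self.params.get("const", 0.0)
        lp += self.params.get(f"age[{age_group}]", 0.0)
        lp += self.params.get(f"sex[{sex}]", 0.0)
        yc = year - self.base_year
        lp += self.params.get("year_c", 0.0) * yc
        lp += self.params.get(f"year_c:age[{age_group}]", 0.0) * yc
        lp += self.params.get(f"year_c:sex[{sex}]", 0.0) * yc
        return lp

    def rate_per_100k(self, age_group: str, sex: str, year: int) -> float:
        if not self.use_offset:
            raise ValueError("rates are only defined for the offset model")
        return math.exp(self.linear_predictor(age_group, sex, year))

    def expected_count(
        self, age_group: str, sex: str, year: int, population: int
    ) -> float:
        lp = self.linear_predictor(age_group, sex, year)
        if self.use_offset:
            return population / 1e5 * math.exp(lp)
        return math.exp(lp)


def _design_matrix(
    df: pd.DataFrame,
    age_levels: Sequence[str],
    sex_levels: Sequence[str],
    base_year: int,
    interactions: bool,
) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    for level in age_levels[1:]:
        X[f"age[{level}]"] = (df["age_group"] == level).astype(float)
    for level in sex_levels[1:]:
        X[f"sex[{level}]"] = (df["sex"] == level).astype(float)
    X["year_c"] = (df["year"] - base_year).astype(float)
    if interactions:
        for level in age_levels[1:]:
            X[f"year_c:age[{level}]"] = X["year_c"] * X[f"age[{level}]"]
        for level in sex_levels[1:]:
            X[f"year_c:sex[{level}]"] = X["year_c"] * X[f"sex[{level}]"]
    return X


def fit_growth_model(
    counts: StratumCountTable,
    population: PopulationSeries,
    joint: str,
    *,
    base_year: int | None = None,
    use_offset: bool = True,
    interactions: bool = False,
) -> GrowthModel:
    """Maximum-likelihood Poisson fit of stratum-year counts for one joint.

    Treatment coding with the first observed age group and sex as baselines;
    ``base_year`` (default: the last observed year, the projection anchor)
    centres the linear year term.  ``use_offset=False`` drops the
    log-population offset and models raw counts.
    """
    sub = counts.for_joint(joint).df
    if sub.empty:
        raise ValueError(f"no counts for joint {joint!r}")
    years = sorted(sub["year"].unique())
    if len(years) < 2:
        raise ValueError("need at least two distinct years to fit a trend")
    if base_year is None:
        base_year = max(years)

    df = sub.copy()
    df["population"] = [
        population.get(r.age_group, r.sex, r.year) for r in df.itertuples()
    ]
    age_levels = tuple(g for g in AGE_GROUPS if g in set(df["age_group"]))
    sex_levels = tuple(s for s in SEXES if s in set(df["sex"]))
    X = _design_matrix(df, age_levels, sex_levels, base_year, interactions)

    offset = np.log(df["population"] / 1e5) if use_offset else None
    model = sm.GLM(
        df["count"].astype(float),
        X,
        family=sm.families.Poisson(),
        offset=offset,
    )
    result = model.fit()
    converged = bool(getattr(result, "converged", True)) and bool(
        np.isfinite(result.params).all()
    )
    return GrowthModel(
        joint=joint,
        params={k: float(v) for k, v in result.params.items()},
        stderr={k: float(v) for k, v in result.bse.items()},
        base_year=base_year,
        age_levels=age_levels,
        sex_levels=sex_levels,
        use_offset=use_offset,
        interactions=interactions,
        llf=float(result.llf),
        converged=converged,
    )


def project_scenario2(
    model: GrowthModel,
    population: PopulationSeries,
    horizon: int,
) -> ProjectionResult:
    """Extrapolate the fitted rate along the year term and multiply by the
    projected population, from the model's base year to the horizon."""
    if not model.converged:
        raise ValueError("growth model did not converge; refusing to project")
    if horizon < model.base_year:
        raise ValueError(f"horizon {horizon} precedes base year {model.base_year}")
    if horizon not in population.years:
        raise ValueError(
            f"population series ends at {max(population.years)}, before "
            f"horizon {horizon}"
        )
    rows = []
    for year in range(model.base_year, horizon + 1):
        for age_group in model.age_levels:
            for sex in model.sex_levels:
                pop = population.get(age_group, sex, year)
                rows.append(
                    (
                        age_group,
                        sex,
                        year,
                        model.expected_count(age_group, sex, year, pop),
                    )
                )
    return ProjectionResult(
        scenario="scenario2",
        joint=model.joint,
        base_year=model.base_year,
        table=pd.DataFrame(rows, columns=["age_group", "sex", "year", "count"]),
    )


def pct_increase(n_base: float, n_final: float) -> int:
    """Percent change from ``n_base`` to ``n_final``, rounded to an integer.

    E.g. 42,920 -> 161,231 is a 276% increase.
    """
    if n_base <= 0:
        raise ValueError("baseline count must be positive")
    return iround_half_away(100.0 * (n_final - n_base) / n_base)
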