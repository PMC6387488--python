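"""Unit-cost schedules, price-index inflation, and admission-level costing.

Costs are taken from the health-system perspective: each hospital admission
is priced once from a unit-cost schedule keyed by (joint, sector,
laterality).  A simultaneous bilateral admission is costed at the bilateral
rate — the conservative choice, since staged (sequential) admissions cost
more.  Schedules carry a price-year; a price index (e.g. a total health
price index) inflates between years multiplicatively.

The default schedule shipped with the package is synthetic: blended
per-admission unit costs in 2016 Australian dollars back-derived from
published aggregate knee/hip replacement expenditure (about $21,100 per
unilateral procedure), with a modest private-sector loading and a bilateral
rate at 1.75x the unilateral rate.  Real schedules plug in via CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from ._util import round_half_away
from .registry_core import Admission

__all__ = [
    "CostSchedule",
    "PriceIndex",
    "CostResult",
    "inflate",
    "cost_admissions",
    "average_unit_cost",
    "scenario_cost_delta",
    "default_cost_schedule",
    "default_price_index",
]

LATERALITIES = ("unilateral", "bilateral_simultaneous")


@dataclass
class CostSchedule:
    """Unit cost per (joint, sector, laterality) at a stated price-year.

    All unit costs must be positive and a bilateral admission must cost at
    least as much as a unilateral one in the same joint/sector cell.
    """

    df: pd.DataFrame  # columns: joint, sector, laterality, unit_cost, price_year
    currency: str = "AUD-2016"

    COLUMNS = ("joint", "sector", "laterality", "unit_cost", "price_year")

    def __post_init__(self) -> None:
        self.df = self.df.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        if (self.df["unit_cost"] <= 0).any():
            raise ValueError("unit costs must be positive")
        self._cells = {
            (r.joint, r.sector, r.laterality): float(r.unit_cost)
            for r in self.df.itertuples()
        }
        for (joint, sector, lat), cost in self._cells.items():
            if lat == "bilateral_simultaneous":
                uni = self._cells.get((joint, sector, "unilateral"))
                if uni is not None and cost < uni:
                    raise ValueError(
                        f"bilateral cost below unilateral for ({joint}, {sector})"
                    )

    def unit_cost(self, joint: str, sector: str, laterality: str) -> float:
        try:
            return self._cells[(joint, sector, laterality)]
        except KeyError:
            raise KeyError(
                f"no schedule entry for (joint={joint}, sector={sector}, "
                f"laterality={laterality})"
            ) from None

    @classmethod
    def from_csv(cls, path: str | Path, currency: str = "AUD-2016") -> "CostSchedule":
        return cls(pd.read_csv(path), currency=currency)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    def inflated(self, to_year: int, index: "PriceIndex") -> "CostSchedule":
        """A copy with every cell inflated from its price-year to ``to_year``."""
        df = self.df.copy()
        df["unit_cost"] = [
            inflate(r.unit_cost, int(r.price_year), to_year, index)
            for r in df.itertuples()
        ]
        df["price_year"] = to_year
        return CostSchedule(df, currency=self.currency)


@dataclass
class PriceIndex:
    """Price-index values by year; inflation is the ratio of index values."""

    values: Mapping[int, float]

    def __getitem__(self, year: int) -> float:
        try:
            return self.values[year]
        except KeyError:
            raise KeyError(f"price index has no value for year {year}") from None

    @classmethod
    def from_csv(cls, path: str | Path) -> "PriceIndex":
        df = pd.read_csv(path)
        return cls({int(r.year): float(r.index_value) for r in df.itertuples()})

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.values.items()), columns=["year", "index_value"]
        ).to_csv(path, index=False)


def inflate(cost: float, from_year: int, to_year: int, index: PriceIndex) -> float:
    """Re-express ``cost`` from one price-year in another: cost * idx(to)/idx(from)."""
    return cost * index[to_year] / index[from_year]


@dataclass
class CostResult:
    """Aggregated admission costs with a sector breakdown."""

    total: float
    by_sector: dict[str, float]
    n_admissions: int
    n_procedures: int
    currency: str = "AUD-2016"

    def __post_init__(self) -> None:
        if abs(sum(self.by_sector.values()) - self.total) > 1e-6 * max(
            1.0, abs(self.total)
        ):
            raise ValueError("sector costs do not sum to the total")

    @property
    def average_per_procedure(self) -> float:
        return average_unit_cost(self.total, self.n_procedures)

    def total_millions(self) -> float:
        return round_half_away(self.total / 1e6)


def cost_admissions(
    admissions: Iterable[Admission], schedule: CostSchedule
) -> CostResult:
    """Sum unit costs over admissions, bilateral admissions costed once
    at the bilateral rate; raises KeyError naming any missing schedule cell."""
    total = 0.0
    by_sector: dict[str, float] = {}
    n_adm = 0
    n_proc = 0
    for adm in admissions:
        cost = schedule.unit_cost(adm.joint, adm.hospital_sector, adm.laterality)
        total += cost
        by_sector[adm.hospital_sector] = by_sector.get(adm.hospital_sector, 0.0) + cost
        n_adm += 1
        n_proc += adm.n_procedures
    return CostResult(
        total=total,
        by_sector=by_sector,
        n_admissions=n_adm,
        n_procedures=n_proc,
        currency=schedule.currency,
    )


def average_unit_cost(total_cost: float, n_procedures: int) -> float:
    """Blended cost per procedure: total / n."""
    if n_procedures <= 0:
        raise ValueError("procedure count must be positive")
    return total_cost / n_procedures


def scenario_cost_delta(delta_procedures: float, avg_cost: float) -> float:
    """Cost effect of a procedure-count change: delta * average unit cost.

    Returned at full precision; report at the nearest million via
    ``round_half_away(delta / 1e6)``.
    """
    if avg_cost <= 0:
        raise ValueError("average cost must be positive")
    return delta_procedures * avg_cost


def default_cost_schedule() -> CostSchedule:
    """Synthetic default unit costs (2016 AUD per admission).

    Back-derived from aggregate expenditure so that the blended average is
    about $21,100 per procedure; private cells carry a small loading and
    bilateral admissions cost 1.75x the unilateral rate.  Editable —
    replace with a real schedule via :meth:`CostSchedule.from_csv`.
    """
    base = {
        ("knee", "public"): 20_200.0,
        ("knee", "private"): 21_500.0,
        ("hip", "public"): 20_100.0,
        ("hip", "private"): 21_400.0,
    }
    rows = []
    for (joint, sector), uni in base.items():
        rows.append((joint, sector, "unilateral", uni, 2016))
        rows.append((joint, sector, "bilateral_simultaneous", 1.75 * uni, 2016))
    return CostSchedule(
        pd.DataFrame(rows, columns=list(CostSchedule.COLUMNS)), currency="AUD-2016"
    )


def default_price_index(
    first_year: int = 2008, last_year: int = 2030, annual_growth: float = 0.02
) -> PriceIndex:
    """Synthetic smooth health price index, 1.0 at 2016, ±2%/yr elsewhere."""
    return PriceIndex(
        {
            year: (1.0 + annual_growth) ** (year - 2016)
            for year in range(first_year, last_year + 1)
        }
    )
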