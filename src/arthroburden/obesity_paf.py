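"""Overweight/obesity prevalence trends and attributable-fraction scenarios.

Combined overweight-and-obesity prevalence (BMI >= 25 kg/m2, percent of
adults) is observed at two national survey anchor years per sex, carried
forward linearly, and converted into adjustments of projected knee
replacement counts through a population attributable fraction (PAF).

The PAF form used by default is a modified Peto-Lopez expression

    PAF = (P0 * RR - P1 * RR) / (P0 * RR)

with P0 the current prevalence, P1 the counterfactual (projected or
reduced) prevalence and RR the relative risk of knee replacement given
overweight/obesity.  RR cancels algebraically, so the expression equals
1 - P1/P0: prevalence shifts map proportionally onto procedure counts.
This RR-invariant form is the default because it is what the downstream
scenario arithmetic (reduction ladder, per-sex uplifts) follows exactly;
the standard Levin form P*(RR-1)/(P*(RR-1)+1), in which RR matters, is
available via ``mode="levin"`` for comparison but drives no scenario.

Two scenario families operate on a projected base count:

* increasing prevalence — per sex, extra = base_sex * (P1/P0 - 1),
  apportioning the base by a configured sex mix when the projection
  itself carries none;
* prevalence reduction — a fraction x of the overweight/obese population
  attains normal BMI, so P1 = P0*(1-x), PAF = x, and fewer = round(x*base).

Hip replacement is left out of these adjustments by default: no consistent
association between BMI and hip replacement risk is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from ._util import iround_half_away, round_half_away

__all__ = [
    "PrevalenceSeries",
    "PafAdjustment",
    "annual_trend",
    "extrapolate_prevalence",
    "paf",
    "apply_reduction_scenario",
    "apply_increase_scenario",
]


@dataclass(frozen=True)
class PrevalenceSeries:
    """Survey prevalence points for one sex.

    ``points`` is a sequence of (anchor year, prevalence %) pairs with
    strictly increasing years.  Surveys spanning two years (e.g. a
    2011-2012 collection) anchor at the first year.
    """

    sex: str
    points: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        years = [y for y, _ in self.points]
        if years != sorted(set(years)):
            raise ValueError("anchor years must be strictly increasing")
        for _, p in self.points:
            if not 0.0 <= p <= 100.0:
                raise ValueError(f"prevalence {p} outside [0, 100]")

    @property
    def last_year(self) -> int:
        return self.points[-1][0]

    @property
    def last_prevalence(self) -> float:
        return self.points[-1][1]


def annual_trend(series: PrevalenceSeries) -> float:
    """Linear prevalence trend in percentage points per year.

    With exactly two survey points this is (p2 - p1)/(y2 - y1); e.g. male
    prevalence 67.7% (2007) to 70.3% (2011) gives 0.65 pp/yr.
    """
    if len(series.points) < 2:
        raise ValueError("need at least two survey points to estimate a trend")
    (y1, p1), (y2, p2) = series.points[0], series.points[-1]
    return (p2 - p1) / (y2 - y1)


def extrapolate_prevalence(
    series: PrevalenceSeries,
    trend: float,
    target_year: int,
    *,
    ndigits: int = 1,
) -> float:
    """Carry the last survey prevalence forward linearly to ``target_year``.

    Applies ``trend`` percentage points per year from the last anchor year
    (19 increments from a 2011 anchor to 2030), clips to [0, 100], and
    rounds half away from zero to ``ndigits`` decimals — matching the
    precision at which survey prevalences are quoted.
    """
    if target_year < series.last_year:
        raise ValueError(
            f"target year {target_year} precedes last survey anchor "
            f"{series.last_year}"
        )
    value = series.last_prevalence + trend * (target_year - series.last_year)
    value = min(100.0, max(0.0, value))
    if ndigits is not None:
        value = round_half_away(value, ndigits)
    return value


def paf(p0: float, p1: float, rr: float = 2.0, mode: str = "peto_lopez") -> float:
    """Population attributable fraction for a prevalence shift p0 -> p1.

    ``mode="peto_lopez"`` (default) evaluates (P0*RR - P1*RR)/(P0*RR), the
    RR-invariant modified Peto-Lopez form; negative values mean the shift
    *adds* attributable procedures.  ``mode="levin"`` evaluates the
    classical Levin fraction P0*(RR-1)/(P0*(RR-1)+1) for the current
    prevalence alone.  Prevalences are proportions in [0, 1].
    """
    if p0 <= 0:
        raise ValueError("current prevalence P0 must be positive")
    if p1 < 0:
        raise ValueError("projected prevalence P1 must be non-negative")
    if rr <= 0:
        raise ValueError("relative risk must be positive")
    if mode == "peto_lopez":
        return (p0 * rr - p1 * rr) / (p0 * rr)
    if mode == "levin":
        return (p0 * (rr - 1.0)) / (p0 * (rr - 1.0) + 1.0)
    raise ValueError(f"unknown paf mode {mode!r}")


@dataclass(frozen=True)
class PafAdjustment:
    """A scenario's effect on a projected procedure count.

    ``delta`` is signed (negative = fewer procedures) and already rounded;
    ``adjusted = base + delta`` holds by construction.
    """

    scenario: str
    paf_by_sex: Mapping[str, float]
    base: float
    delta: int

    @property
    def adjusted(self) -> float:
        return self.base + self.delta


def apply_reduction_scenario(base_total: float, shift: float) -> PafAdjustment:
    """Prevalence-reduction scenario: a fraction ``shift`` of the
    overweight/obese population attains a normal BMI.

    P1 = P0*(1 - shift) for both sexes, hence PAF = shift and
    fewer procedures = round(shift * base), rounded half away from zero
    at this final step only (e.g. 0.05 * 161,231 = 8061.55 -> 8062).
    """
    if not 0.0 <= shift < 1.0:
        raise ValueError(f"shift must be in [0, 1), got {shift}")
    fewer = iround_half_away(shift * base_total)
    return PafAdjustment(
        scenario=f"reduction {shift:.0%}",
        paf_by_sex={"female": shift, "male": shift},
        base=base_total,
        delta=-fewer,
    )


def apply_increase_scenario(
    base_total: float,
    prevalence_now: Mapping[str, float],
    prevalence_future: Mapping[str, float],
    *,
    base_by_sex: Mapping[str, float] | None = None,
    female_share: float | None = None,
) -> PafAdjustment:
    """Increasing-prevalence scenario applied per sex, then summed.

    Per sex, extra procedures = base_sex * (P1/P0 - 1), the negative of
    the Peto-Lopez PAF; the total is rounded half away from zero at the end.
    ``base_by_sex`` gives sex-specific projected counts directly; failing
    that, ``female_share`` apportions ``base_total`` (female then male).
    Prevalences may be given as percentages or proportions, consistently.
    """
    if base_by_sex is None:
        if female_share is None:
            raise ValueError("need base_by_sex or female_share to split the base")
        if not 0.0 <= female_share <= 1.0:
            raise ValueError("female_share must be in [0, 1]")
        base_by_sex = {
            "female": base_total * female_share,
            "male": base_total * (1.0 - female_share),
        }
    paf_by_sex: dict[str, float] = {}
    extra = 0.0
    for sex, base_sex in base_by_sex.items():
        p0 = prevalence_now[sex]
        p1 = prevalence_future[sex]
        if p0 <= 0:
            raise ValueError(f"current prevalence for {sex} must be positive")
        paf_by_sex[sex] = 1.0 - p1 / p0  # RR-invariant form; negative when rising
        extra += base_sex * (p1 / p0 - 1.0)
    return PafAdjustment(
        scenario="increasing_prevalence",
        paf_by_sex=paf_by_sex,
        base=base_total,
        delta=iround_half_away(extra),
    )
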