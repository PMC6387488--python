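"""Synthetic registry generator with recorded ground truth.

Emulates the four inputs of the burden-projection analysis so every
pipeline stage is testable without external data:

* a procedure-level registry whose stratum-year counts are Poisson draws
  around log-linearly growing rates, with configurable bilateral pairs,
  sector/setting labels, and non-qualifying (non-OA / revision)
  contamination records;
* an age/sex-stratified population series growing geometrically per
  stratum, observed through the study window and projected beyond it;
* two-point overweight/obesity prevalence surveys per sex; and
* a unit-cost schedule with a price index.

Defaults mirror the national study conditions at 1/100 population scale:
an 11-year window (2003-2013) with knee rates doubling-and-some over the
decade (slope ln(2.05)/10 per year) and hip rates growing 73% (slope
ln(1.73)/10), about 89% of primary procedures carrying an osteoarthritis
diagnosis, bilateral procedure shares of 16.3% (knee) and 6.5% (hip),
and a 70% private / 65% metropolitan case mix.  Every draw is recorded
in a :class:`GroundTruth` so tabulated counts can be checked exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import math

import numpy as np
import pandas as pd

from .costing import (
    CostSchedule,
    PriceIndex,
    default_cost_schedule,
    default_price_index,
)
from .obesity_paf import PrevalenceSeries
from .rates_projection import PopulationSeries
from .registry_core import (
    AGE_GROUPS,
    JOINTS,
    SEXES,
    ProcedureRecord,
    StratumCountTable,
    write_registry,
)

__all__ = [
    "GeneratorConfig",
    "load_prevalence_csv",
    "GroundTruth",
    "default_config",
    "generate_population",
    "generate_registry",
    "generate_prevalence_surveys",
    "generate_cost_schedule",
    "write_synthetic_inputs",
]

# Two-point national survey defaults: (anchor year, % of adults overweight
# or obese), measured waves anchored at the first collection year.
DEFAULT_PREVALENCE_POINTS: dict[str, tuple[tuple[int, float], ...]] = {
    "male": ((2007, 67.7), (2011, 70.3)),
    "female": ((2007, 54.6), (2011, 56.2)),
}

_AGE_RANGES = {"<40": (18, 40), "40-69": (40, 70), "70+": (70, 96)}


def _default_baseline_rates() -> dict[tuple[str, str, str], float]:
    # per 100,000 at the first study year; chosen to land near national
    # aggregate rates (~120/100k knee, ~85/100k hip) given the default
    # population structure
    return {
        ("knee", "<40", "female"): 1.0,
        ("knee", "<40", "male"): 1.0,
        ("knee", "40-69", "female"): 170.0,
        ("knee", "40-69", "male"): 150.0,
        ("knee", "70+", "female"): 700.0,
        ("knee", "70+", "male"): 650.0,
        ("hip", "<40", "female"): 3.0,
        ("hip", "<40", "male"): 3.0,
        ("hip", "40-69", "female"): 110.0,
        ("hip", "40-69", "male"): 110.0,
        ("hip", "70+", "female"): 500.0,
        ("hip", "70+", "male"): 480.0,
    }


def _default_base_population() -> dict[tuple[str, str], int]:
    # 1/100 of an Australia-like age structure, per sex
    return {
        ("<40", "female"): 55_000,
        ("<40", "male"): 56_000,
        ("40-69", "female"): 36_000,
        ("40-69", "male"): 35_000,
        ("70+", "female"): 10_000,
        ("70+", "male"): 8_000,
    }


def _default_population_growth() -> dict[str, float]:
    # ageing population: the oldest group grows fastest
    return {"<40": 0.010, "40-69": 0.015, "70+": 0.030}


@dataclass
class GeneratorConfig:
    """Full parameterisation of the synthetic study; the seed fixes everything."""

    seed: int = 0
    start_year: int = 2003
    end_year: int = 2013
    horizon_year: int = 2030
    age_groups: tuple[str, ...] = AGE_GROUPS
    sexes: tuple[str, ...] = SEXES
    joints: tuple[str, ...] = JOINTS
    #: baseline rate per 100,000 per (joint, age_group, sex) at start_year
    baseline_rates: dict[tuple[str, str, str], float] = field(
        default_factory=_default_baseline_rates
    )
    #: per-year log-linear rate growth per joint
    growth_rates: dict[str, float] = field(
        default_factory=lambda: {
            "knee": math.log(2.05) / 10.0,
            "hip": math.log(1.73) / 10.0,
        }
    )
    #: base population per (age_group, sex) at start_year
    base_population: dict[tuple[str, str], int] = field(
        default_factory=_default_base_population
    )
    #: annual geometric population growth per age group
    population_growth: dict[str, float] = field(
        default_factory=_default_population_growth
    )
    #: fraction of procedures belonging to same-year bilateral pairs, per joint
    bilateral_fraction: dict[str, float] = field(
        default_factory=lambda: {"knee": 0.163, "hip": 0.065}
    )
    private_fraction: float = 0.70
    metropolitan_fraction: float = 0.65
    #: fraction of primary procedures with an osteoarthritis diagnosis
    oa_fraction: float = 0.89
    #: revision procedures as a fraction of the primary-OA volume
    revision_fraction: float = 0.05
    prevalence_points: dict[str, tuple[tuple[int, float], ...]] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE_POINTS)
    )

    def __post_init__(self) -> None:
        for name in (
            "private_fraction",
            "metropolitan_fraction",
            "oa_fraction",
            "revision_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        for frac in self.bilateral_fraction.values():
            if not 0.0 <= frac <= 1.0:
                raise ValueError("bilateral fractions must lie in [0, 1]")
        for rate in self.baseline_rates.values():
            if rate <= 0:
                raise ValueError("baseline rates must be positive")
        if self.end_year <= self.start_year:
            raise ValueError("end_year must follow start_year")
        if self.horizon_year < self.end_year:
            raise ValueError("horizon_year must not precede end_year")
        if self.oa_fraction <= 0:
            raise ValueError("oa_fraction must be positive")


def default_config(seed: int = 0) -> GeneratorConfig:
    """The default study conditions with a chosen seed."""
    return GeneratorConfig(seed=seed)


@dataclass
class GroundTruth:
    """What the generator actually drew, for exact downstream checks."""

    counts: StratumCountTable  # primary-OA procedure counts per stratum-year
    baseline_rates: Mapping[tuple[str, str, str], float]
    growth_rates: Mapping[str, float]
    bilateral_pairs: dict[tuple[str, str, str, int], int]
    n_contaminant_records: int


def generate_population(config: GeneratorConfig) -> PopulationSeries:
    """Geometric growth per stratum from start_year through horizon_year.

    population(s, t) = base(s) * (1 + g(s))^(t - t0), rounded; years up to
    the study end are flagged observed, later years projected.
    """
    rows = []
    for (age_group, sex), base in sorted(config.base_population.items()):
        g = config.population_growth[age_group]
        for year in range(config.start_year, config.horizon_year + 1):
            pop = int(round(base * (1.0 + g) ** (year - config.start_year)))
            provenance = "observed" if year <= config.end_year else "projected"
            rows.append((age_group, sex, year, pop, provenance))
    return PopulationSeries(
        pd.DataFrame(rows, columns=list(PopulationSeries.COLUMNS))
    )


def generate_registry(
    config: GeneratorConfig, population: PopulationSeries
) -> tuple[list[ProcedureRecord], GroundTruth]:
    """Draw a procedure-level registry for the study window.

    Per (joint, age group, sex, year) the primary-OA count is Poisson with
    mean rate0 * exp(beta*(t - t0)) * population/1e5.  A configured share
    of those procedures arrives as same-patient bilateral pairs (shared
    synthetic patient id, same sector/setting, left+right sides).
    Non-qualifying records — 'other' diagnoses and revisions — are added
    on top at rates implied by the OA and revision fractions, so the
    primary-OA filter recovers the ground-truth counts exactly.
    """
    rng = np.random.default_rng(config.seed)
    records: list[ProcedureRecord] = []
    count_rows = []
    bilateral_pairs: dict[tuple[str, str, str, int], int] = {}
    n_contaminant = 0
    patient_counter = 0

    def next_patient() -> str:
        nonlocal patient_counter
        patient_counter += 1
        return f"SYN{patient_counter:07d}"

    def draw_common(age_group: str) -> tuple[int, str, str]:
        lo, hi = _AGE_RANGES[age_group]
        age = int(rng.integers(lo, hi))
        sector = "private" if rng.random() < config.private_fraction else "public"
        setting = (
            "metropolitan"
            if rng.random() < config.metropolitan_fraction
            else "regional"
        )
        return age, sector, setting

    for joint in config.joints:
        beta = config.growth_rates[joint]
        bfrac = config.bilateral_fraction.get(joint, 0.0)
        for year in range(config.start_year, config.end_year + 1):
            for age_group in config.age_groups:
                for sex in config.sexes:
                    rate0 = config.baseline_rates[(joint, age_group, sex)]
                    pop = population.get(age_group, sex, year)
                    mu = rate0 * math.exp(beta * (year - config.start_year)) * pop / 1e5
                    n = int(rng.poisson(mu))
                    count_rows.append((joint, age_group, sex, year, n))

                    n_pairs = int(round(bfrac * n / 2.0))
                    n_pairs = min(n_pairs, n // 2)
                    bilateral_pairs[(joint, age_group, sex, year)] = n_pairs
                    for _ in range(n_pairs):
                        age, sector, setting = draw_common(age_group)
                        pid = next_patient()
                        for side in ("left", "right"):
                            records.append(
                                ProcedureRecord(
                                    patient_id=pid,
                                    age_years=age,
                                    sex=sex,
                                    year=year,
                                    joint=joint,
                                    procedure_class="primary",
                                    diagnosis="osteoarthritis",
                                    hospital_sector=sector,
                                    hospital_setting=setting,
                                    side=side,
                                )
                            )
                    for _ in range(n - 2 * n_pairs):
                        age, sector, setting = draw_common(age_group)
                        records.append(
                            ProcedureRecord(
                                patient_id=next_patient(),
                                age_years=age,
                                sex=sex,
                                year=year,
                                joint=joint,
                                procedure_class="primary",
                                diagnosis="osteoarthritis",
                                hospital_sector=sector,
                                hospital_setting=setting,
                                side="left" if rng.random() < 0.5 else "right",
                            )
                        )

                    # contamination: primaries with non-OA diagnoses ...
                    n_other = int(
                        rng.poisson(mu * (1.0 - config.oa_fraction) / config.oa_fraction)
                    )
                    # ... and revision procedures
                    n_rev = int(rng.poisson(mu * config.revision_fraction))
                    n_contaminant += n_other + n_rev
                    for kind in ("other",) * n_other + ("revision",) * n_rev:
                        age, sector, setting = draw_common(age_group)
                        records.append(
                            ProcedureRecord(
                                patient_id=next_patient(),
                                age_years=age,
                                sex=sex,
                                year=year,
                                joint=joint,
                                procedure_class=(
                                    "revision" if kind == "revision" else "primary"
                                ),
                                diagnosis=(
                                    "other" if kind == "other" else "osteoarthritis"
                                ),
                                hospital_sector=sector,
                                hospital_setting=setting,
                                side="left" if rng.random() < 0.5 else "right",
                            )
                        )

    counts = StratumCountTable(
        pd.DataFrame(count_rows, columns=list(StratumCountTable.COLUMNS))
    )
    truth = GroundTruth(
        counts=counts,
        baseline_rates=dict(config.baseline_rates),
        growth_rates=dict(config.growth_rates),
        bilateral_pairs=bilateral_pairs,
        n_contaminant_records=n_contaminant,
    )
    return records, truth


def generate_prevalence_surveys(
    config: GeneratorConfig | None = None,
) -> dict[str, PrevalenceSeries]:
    """Two-point prevalence surveys per sex (national survey defaults)."""
    points = (
        config.prevalence_points if config is not None else DEFAULT_PREVALENCE_POINTS
    )
    return {
        sex: PrevalenceSeries(sex=sex, points=tuple(pts))
        for sex, pts in sorted(points.items())
    }


def generate_cost_schedule(
    config: GeneratorConfig | None = None,
) -> tuple[CostSchedule, PriceIndex]:
    """The default synthetic unit-cost schedule and price index."""
    return default_cost_schedule(), default_price_index()


def write_synthetic_inputs(
    config: GeneratorConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Generate and write all four input files (plus ground truth) as CSV/JSON.

    Deterministic given the config seed: identical configs write identical
    bytes.  Returns the emitted paths keyed by input kind.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    population = generate_population(config)
    records, truth = generate_registry(config, population)
    surveys = generate_prevalence_surveys(config)
    schedule, index = generate_cost_schedule(config)

    paths = {
        "registry": out / "registry.csv",
        "population": out / "population.csv",
        "prevalence": out / "prevalence.csv",
        "cost_schedule": out / "cost_schedule.csv",
        "price_index": out / "price_index.csv",
        "ground_truth_counts": out / "ground_truth_counts.csv",
        "generator_manifest": out / "generator_manifest.json",
    }
    write_registry(records, paths["registry"])
    population.to_csv(paths["population"])
    prev_rows = [
        (sex, year, pct)
        for sex, series in surveys.items()
        for year, pct in series.points
    ]
    pd.DataFrame(
        prev_rows, columns=["sex", "anchor_year", "prevalence_pct"]
    ).to_csv(paths["prevalence"], index=False)
    schedule.to_csv(paths["cost_schedule"])
    index.to_csv(paths["price_index"])
    truth.counts.to_csv(paths["ground_truth_counts"])
    manifest = {
        "seed": config.seed,
        "start_year": config.start_year,
        "end_year": config.end_year,
        "horizon_year": config.horizon_year,
        "growth_rates": dict(config.growth_rates),
        "n_records": len(records),
        "n_contaminant_records": truth.n_contaminant_records,
    }
    paths["generator_manifest"].write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return paths


def load_prevalence_csv(path: str | Path) -> dict[str, PrevalenceSeries]:
    """Read the prevalence CSV dialect written by write_synthetic_inputs."""
    df = pd.read_csv(path)
    out: dict[str, PrevalenceSeries] = {}
    for sex, sub in df.groupby("sex"):
        pts = tuple(
            (int(r.anchor_year), float(r.prevalence_pct))
            for r in sub.sort_values("anchor_year").itertuples()
        )
        out[str(sex)] = PrevalenceSeries(sex=str(sex), points=pts)
    return out
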