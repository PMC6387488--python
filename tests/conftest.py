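"""Shared fixtures: a small deterministic synthetic study and hand-built records."""

from __future__ import annotations

import pytest

from arthroburden import (
    GeneratorConfig,
    ProcedureRecord,
    default_config,
    generate_population,
    generate_registry,
)


def make_record(**overrides) -> ProcedureRecord:
    """A valid record with every field overridable."""
    kwargs = dict(
        patient_id="P1",
        age_years=68,
        sex="female",
        year=2013,
        joint="knee",
        procedure_class="primary",
        diagnosis="osteoarthritis",
        hospital_sector="private",
        hospital_setting="metropolitan",
        side="left",
    )
    kwargs.update(overrides)
    return ProcedureRecord(**kwargs)


@pytest.fixture(scope="session")
def default_sim():
    """One full-size synthetic study (default conditions, fixed seed)."""
    config = default_config(seed=20230)
    population = generate_population(config)
    records, truth = generate_registry(config, population)
    return config, population, records, truth


@pytest.fixture()
def single_stratum_config() -> GeneratorConfig:
    """One joint / one stratum at a large population, no growth or noise knobs."""
    return GeneratorConfig(
        seed=7,
        start_year=2003,
        end_year=2013,
        horizon_year=2030,
        joints=("knee",),
        age_groups=("40-69",),
        sexes=("female",),
        baseline_rates={("knee", "40-69", "female"): 200.0},
        growth_rates={"knee": 0.0},
        base_population={("40-69", "female"): 500_000},
        population_growth={"40-69": 0.0},
        bilateral_fraction={"knee": 0.0},
        oa_fraction=1.0,
        revision_fraction=0.0,
    )
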