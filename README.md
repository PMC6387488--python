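# arthroburden

Projection of the future burden of primary total knee replacement (TKR) and
total hip replacement (THR) performed for osteoarthritis, from
registry-style procedure records: incidence scenarios to a horizon year,
obesity sensitivity analyses, and health-system costs by hospital sector.

## Who this is for

Epidemiologists and health-economics analysts working with national
arthroplasty registry extracts (procedure-level rows with age, sex, year,
joint, diagnosis, sector, setting, side), age/sex-stratified population
projections, two-point overweight/obesity prevalence surveys, and
per-admission unit-cost schedules. A synthetic-registry generator with
recorded ground truth replaces the real data sources, so the entire
pipeline is runnable and testable out of the box.

## The model

Records are filtered to **primary procedures with an osteoarthritis
diagnosis**, binned into age groups <40, 40–69, 70+, and tabulated into
(joint, age group, sex, year) counts. Two projection scenarios:

* **Scenario 1 (constant rate).** Base-year stratum rates are held fixed:
  `count(s, t) = rate(s, base) × population(s, t) / 100,000`; growth is
  driven purely by projected population size and ageing.
* **Scenario 2 (continued growth).** A Poisson log-linear model with a
  log-population offset,

  `log E[count(s,t)] = log(pop(s,t)/10⁵) + α + β_age(s) + β_sex(s) + β_year·(t − base)`,

  fitted per joint by maximum likelihood (statsmodels GLM), extrapolates
  the decade's rate growth along the year term before multiplying by the
  projected population.

**Obesity sensitivity (knee only).** Combined overweight/obesity prevalence
(P, % of adults) from two survey anchors per sex is carried forward
linearly. A modified Peto–Lopez population attributable fraction
`PAF = (P₀·RR − P₁·RR)/(P₀·RR)`, which is invariant to the relative risk RR
and equals `1 − P₁/P₀`, maps prevalence shifts onto projected counts: per
sex, extra procedures = base × (P₁/P₀ − 1); a reduction scenario in which
x% of the overweight/obese population attains normal BMI removes
round(x · base) procedures.

**Costing.** Same-patient, same-year, same-joint, same-sector record pairs
are collapsed into one simultaneous bilateral admission (costing only —
incidence always counts procedures), and admissions are priced from a
(joint × sector × laterality) schedule with price-index inflation.

## Worked example

```python
from arthroburden import *

config = default_config(seed=7)          # 1/100-scale synthetic study, 2003-2013
population = generate_population(config)
records, truth = generate_registry(config, population)
oa = filter_primary_oa(records)          # keeps 7319 of 8528 records
counts = tabulate_counts(oa)

rates = compute_rates(counts, population)
s1 = project_scenario1(rates.at_year(2013), population, 2013, 2030, "knee")
model = fit_growth_model(counts, population, "knee", base_year=2013)
s2 = project_scenario2(model, population, 2030)
```

This prints, via the obvious accessors:

```
knee 2013 total: 602
knee rate 2003: 134 per 100,000   ->   2013: 263 per 100,000
fitted knee year slope: 0.0708 (generator truth: 0.0718)
scenario 1, 2030:  899 procedures (+49% from 2013)
scenario 2, 2030: 3025 procedures (+402% from 2013)
```

Under the constant-rate scenario growth comes only from the population
(+49% by 2030); under continued rate growth the fitted slope of 0.0708/yr
(~7.3%/yr) compounds to a 402% increase. The obesity scenarios then operate
on those bases:

```python
surveys = generate_prevalence_surveys()  # male 67.7->70.3, female 54.6->56.2
# linear trends: 0.65 and 0.40 pp/yr; 2030: 82.7% (men), 63.8% (women)
inc = apply_increase_scenario(s2.total_rounded(2030), {"male": 70.3, "female": 56.2},
                              {"male": 82.7, "female": 63.8},
                              base_by_sex=s2.sex_totals(2030))
# inc.delta == +464 extra knee procedures in 2030
red = apply_reduction_scenario(s2.total_rounded(2030), 0.05)
# red.delta == -151 procedures
```

The same pipeline is scriptable end to end:

```bash
arthroburden report --config run.yaml --out-dir out/
```

where `run.yaml` either names the four input CSVs (registry, population,
prevalence, cost schedule) or a `generator:` block; outputs are
per-scenario stratum CSVs, figure-data CSVs (per-year totals by age
group), an obesity sensitivity ladder in burden-table shape, a cost
report, and a provenance manifest.

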