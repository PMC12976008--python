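# pvsignals

Disproportionality signal detection and time-to-onset modelling for
spontaneous adverse-event report databases in the FAERS quarterly ASCII
dialect.

## What this is for

Regulators and pharmacovigilance groups mine spontaneous-reporting systems
(such as the FDA Adverse Event Reporting System) for drug safety signals:
drug–event pairs reported more often than the rest of the database would
predict. `pvsignals` implements that workflow end to end for analysts who
want a scripted, reproducible pipeline rather than ad-hoc spreadsheets:

1. **Ingest** `$`-delimited DEMO/DRUG/REAC/THER/INDI/OUTC tables, keeping
   partial dates as explicit (value, precision) pairs.
2. **Deduplicate** case versions by the regulatory rule: per CASEID keep the
   latest FDA receipt date, ties broken by the highest PRIMARYID.
3. **Select the cohort**: reports listing the study drug as a primary-suspect
   (PS) drug; everything else becomes the comparator.
4. **Count** unique (report, event-term) pairs into a 2×2 table per MedDRA
   preferred term (PT) or system organ class (SOC).
5. **Test** each pair with four estimators (below) and flag a signal when
   any one exceeds its field-standard threshold.
6. **Model onset**: days from the earliest PS therapy start to event onset,
   fitted by a Weibull law whose shape parameter classifies the hazard as
   early-failure / random / wear-out.
7. **Stratify** by sex, age group and reporter type, and rerun after
   excluding reports that carry listed co-medications (sensitivity).

Because real extracts are multi-gigabyte downloads with unknowable truth,
the package ships a **synthetic-database generator** that emits the same
file formats with planted associations, injected duplicate versions,
Weibull onset times and a truth manifest — every stage of the pipeline is
validated against that ground truth.

## The statistics

For a 2×2 table — `a` cohort reports with the event, `b` cohort reports
with other events, `c`/`d` the same for the comparator, `N = a+b+c+d` and
`E = (a+b)(a+c)/N`:

| method | point estimate | interval / test | signal when |
|---|---|---|---|
| ROR | `ad/(bc)` | Wald 95% CI on log scale | `a ≥ 3` and CI lower > 1 |
| PRR | `[a/(a+b)]/[c/(c+d)]` | Pearson χ² (no Yates) | `a ≥ 3`, PRR ≥ 2, χ² ≥ 4 |
| BCPNN | `IC = log2 p11/(p1·p2)`, posterior mean under Beta posteriors | `IC025 = E[IC] − 1.96·sd` | IC025 > 0 |
| MGPS | `EBGM = 2^{E[log2 λ]}`, `a ~ Poisson(λE)`, λ with a fitted two-component gamma-mixture prior | EBGM05 = posterior 5th percentile | EBGM05 > 2 |

The gamma-mixture hyperparameters `(α₁, β₁, α₂, β₂, P)` are fitted once per
database by maximizing the marginal (negative-binomial mixture) likelihood
over all (PS drug, term) cells. Zero cells receive a Haldane–Anscombe
+0.5 correction only where a ratio would otherwise be undefined, and rows
are flagged when corrected.

Time to onset is modelled as Weibull with density
`f(t) = (β/α)(t/α)^{β−1} exp(−(t/α)^β)`; a shape CI entirely below 1 means
the reporting hazard is highest right after treatment initiation ("early
failure"), the pattern typical of infusion biologics.

## Worked example

Simulate a 20,000-case database with one association planted at a tenfold
relative reporting rate, then run the full analysis:

```python
from pvsignals import (
    DrugDictionary, PlantedSignal, SimConfig, assemble_cases, compute_tto,
    count_pairs, database_cells, deduplicate, detect_signals, fit_mgps_prior,
    fit_weibull, generate, select_primary_suspect,
)

cfg = SimConfig(
    n_cases=20_000, seed=42,
    planted_signals=(PlantedSignal("DRUG_00", "event_30", 10.0),),
    rate_overrides={"event_30": 0.005},
)
sim = generate(cfg)

demos = deduplicate(sim.demos)
cases = assemble_cases(demos, sim.drugs, sim.reactions, sim.outcomes,
                       sim.indications, sim.therapies)
cohort, comparator = select_primary_suspect(
    cases, DrugDictionary(frozenset(["DRUG_00"])))

tables = count_pairs(cohort, comparator)
cells = database_cells(cases)
prior = fit_mgps_prior(cells["a"], cells["E"])
signals = detect_signals(tables, prior)

sample = compute_tto(cohort, DrugDictionary(frozenset(["DRUG_00"])))
fit = fit_weibull(sample)
```

Output (printed by the snippet above with small f-strings):

```
23978 report versions -> 20000 cases, cohort 991
event_30: a=54  ROR=10.30 (7.38-14.36)  PRR=10.06 (chi2=289.1)  IC=2.63 (2.18)  EBGM=7.01 (6.31)  signal=True
TTO n=676  median=122 d (IQR 32, 348)
Weibull alpha=223.2 (197.2-252.7)  beta=0.64 (0.61-0.68)  type=early_failure
```

Reading this: the injected duplicates collapse back to exactly 20,000
cases; the planted pair is recovered with all four estimators near the
planted tenfold rate (EBGM sits lower because empirical-Bayes shrinkage
pulls small counts toward the database mean); and the onset sample
reproduces the configured early-failure Weibull (true α = 198.63 days,
β = 0.63, both inside the fitted CIs).

The same analysis is available from the shell:

```sh
pvsignals simulate --n-cases 20000 --seed 42 --outdir data \
    --planted DRUG_00:event_30:10
pvsignals signals --data-dir data --drug-file data/drug_dictionary.txt \
    --soc-map data/soc_map.tsv --outdir out
pvsignals report --config run.yaml     # full pipeline from a YAML config
```

Outputs are deterministic CSVs (baseline table, PT/SOC signal tables,
TTO/Weibull table, subgroup and sensitivity tables, an attrition log and a
run manifest).

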