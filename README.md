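# faersig

Disproportionality signal detection for FAERS-style spontaneous
adverse-event reports, aimed at pharmacovigilance analysts who work with
the FDA Adverse Event Reporting System quarterly extracts — in particular
at pediatric drug-safety screens such as the oral influenza antivirals
oseltamivir and baloxavir marboxil.

The package covers the whole screening pipeline:

1. **Ingestion** of the `$`-delimited DEMO/DRUG/REAC quarterly ASCII
   tables and deleted-case lists, tolerant of schema drift and dirty text.
2. **Deduplication** per FDA guidance: drop deleted cases, then keep one
   version per case (latest FDA receipt date, ties to the higher
   `primaryid`).
3. **Cohorting**: pediatric stratum (0–18 years after age-unit
   conversion), primary-suspect (PS) matching of the target drug by name
   patterns, descriptive demographics and concomitant-medication tables.
4. **Screening**: four disproportionality algorithms per preferred term
   (PT), with combined signal criteria.
5. **Gender subgroups** and **system-organ-class (SOC) aggregation**
   (MedDRA itself is licensed and not bundled; the PT→SOC map is supplied
   by the user or by the synthetic vocabulary).
6. A **synthetic-report generator** with planted drug–event associations,
   and an **inversion oracle** that recovers contingency cells from
   published statistics — so the entire pipeline is testable offline.

## The statistics

For each (drug, PT) pair the screen counts unique (report, PT) pairs into
the 2×2 table *a, b, c, d* (target∧event, target∧other, other∧event,
neither; *N = a+b+c+d*) and evaluates

- **ROR** = *ad/(bc)*, 95% CI `exp(ln ROR ± 1.96σ)`,
  σ² = 1/a + 1/b + 1/c + 1/d — signal when the lower bound > 1;
- **PRR** = [*a*/(*a*+*b*)] / [*c*/(*c*+*d*)] with Pearson's χ²
  (no continuity correction) — signal when PRR ≥ 2 and χ² ≥ 4;
- **IC** = log₂[*aN*/((*a*+*b*)(*a*+*c*))] with IC025 = IC − 2√V(IC)
  using the closed-form BCPNN posterior variance — signal when IC025 > 0;
- **EBGM** = *aN*/((*a*+*b*)(*a*+*c*)) with
  EBGM05 = exp(ln EBGM − 1.96σ) — signal when EBGM05 ≥ 2,

each rule additionally requiring *a* ≥ 3, and the combined signal being
their conjunction. See `docs/methods.md` for the reasoning behind the
non-shrunk EBGM form and the IC variance choice.

## Worked example

```python
from faersig import (CohortSpec, DisproportionalityScreen, clean_snapshot,
                     default_config, generate_snapshot, select_cohort)

cfg = default_config(n_cases=20_000, seed=7)        # synthetic FAERS-like data
snapshot, truth = generate_snapshot(cfg)
clean, audit = clean_snapshot(snapshot)
print(f"reports: {audit.n_reports_in} -> {audit.n_reports_out} after dedup")

cohort = select_cohort(clean, CohortSpec(drug_name_patterns=["OSELTAMIVIR", "TAMIFLU"]))
print(f"pediatric primary-suspect reports: {cohort.n_members}")

results = DisproportionalityScreen.from_cohort(cohort, drug="oseltamivir").fit()
print(results.summary(top=6))
```

prints

```
reports: 22426 -> 19576 after dedup
pediatric primary-suspect reports: 509
Disproportionality screen
============================================================
drug: oseltamivir
background pairs: 16566  (member pairs: 1358)
PTs screened: 117   signals: 2
------------------------------------------------------------
    pt   a   ror ror_l95 ror_u95   prr   chi2    ic ic025 ebgm ebgm05  signal
PT_006 236  0.95    0.82    1.10  0.96   0.47 -0.06 -0.26 0.96   0.83   False
PT_007  96  0.74    0.59    0.91  0.75   7.87 -0.38 -0.69 0.77   0.62   False
PT_008  80  0.98    0.77    1.24  0.98   0.04 -0.03 -0.37 0.98   0.77   False
PT_009  58  0.89    0.68    1.17  0.90   0.65 -0.14 -0.54 0.91   0.69   False
PT_000  48 10.48    7.06   15.55 10.14 208.85  2.54  2.03 5.80   3.91    True
PT_010  48  0.90    0.67    1.21  0.90   0.48 -0.14 -0.57 0.91   0.67   False
```

The dedup step removed ~2,850 rows (duplicate case versions plus deleted
cases); 509 pediatric reports name the target drug as primary suspect.
`PT_000` — planted in the generator with a reporting-rate ratio of 10 —
is the strongest row: ROR 10.48 (7.06–15.55) with *a* = 48
co-occurrences, and it passes all four criteria (`signal` = True), while
the common background terms sit at ROR ≈ 1 and flag nothing.

The same pipeline runs from the shell:

```sh
faersig synth --n-cases 20000 --seed 7 --out data/
faersig run --config run.yaml --out results/
```

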