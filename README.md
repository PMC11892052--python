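# offlabel

Analysis pipeline for measuring **off-label** and **contraindicated**
outpatient prescription drug use and its association with health status and
healthcare utilisation, in the style of studies that link US household-survey
microdata (MEPS-type person, condition, prescribed-medicine and event-link
files) with a drug-label knowledge base (DrugCentral-type drug–concept pairs
mapped from SNOMED CT to ICD-10-CM).

It is aimed at health-services and pharmacoepidemiology researchers who need
a tested, reproducible implementation of the full chain: knowledge-base
construction → prescription classification → prevalence tables → group
comparisons → regression estimates, plus a seeded synthetic-data generator
so every stage can be validated without licensed data extracts.

## The measures

For each prescription event of drug *d* by person *i*, with *L* the set of
3-character ICD-10 categories linked to the event, *C<sub>i</sub>* the person's
recorded (current) condition categories, and *I(d)*, *X(d)* the drug's
indicated and contraindicated categories:

- `indic_narrow` = 1 iff *L* ∩ *I(d)* ≠ ∅ — the condition recorded against the
  prescription itself is an approved indication;
- `indic_broad` = 1 iff *C<sub>i</sub>* ∩ *I(d)* ≠ ∅ — any recorded condition is an
  approved indication (1 − `indic_broad` is **off-label use**);
- `contraindicated` = 1 iff *C<sub>i</sub>* ∩ *X(d)* ≠ ∅;
- `indic_not_contra` = `indic_broad` × (1 − `contraindicated`) — "optimal use".

Person-level exposures are the unweighted means of these indicators over the
person-year's in-scope prescriptions (`frac_indicated`,
`frac_contraindicated`, `frac_offlabel` = 1 − `frac_indicated`), plus the
mean FDA approval year of the prescribed drugs. Associations with binary
health-status outcomes *y<sub>i</sub>* are estimated by

- a linear probability model with HC1-robust standard errors,
- a probit reported as average marginal effects, and
- cross-fitted double machine learning for the partially linear model
  *y = θD + g(X) + ε* (residual-on-residual Neyman-orthogonal score,
  random-forest or regression-tree nuisance learners),

all controlling for one dummy per condition category present in the data,
sex, single-year-of-age, education, race, survey-year and
prescription-count dummies, and mean approval year. Each estimate is also
reported as a *mean percentage*, 100·θ̂ / ȳ.

## Worked example

```python
from offlabel import (generate, classify_all, person_exposures,
                      median_split_compare, fit_lpm, ModelSpec,
                      build_analysis_table)
from offlabel.simulate import preset_effect_recovery

sim = generate(preset_effect_recovery(seed=42))       # 5000 synthetic persons
cls, qc = classify_all(sim.kb, sim.dataset)           # four indicators per rx
expo = person_exposures(cls, sim.dataset, sim.kb)     # person-level fractions

comp = median_split_compare(expo, sim.dataset.persons,
                            "frac_contraindicated", ("UNABLE31",))
table = build_analysis_table(expo, sim.dataset)
results = fit_lpm(ModelSpec(outcome="UNABLE31"), table)
```

prints (via `comp` and the result objects):

```
variable            split_var  median  n_low  n_high  mean_low  mean_high  difference  p_value
UNABLE31 frac_contraindicated  0.6667   2510    2490    0.0888     0.1253     -0.0365      0.0
lpm frac_contraindicated:  0.0516 (SE 0.0102, p 0.0000, mean% 48.20)
lpm frac_indicated:       -0.0220 (SE 0.0093, p 0.0181, mean% -20.57)
```

Reading: persons above the median contraindicated-use fraction report the
31-day activity limitation more often (12.5% vs 8.9%, Welch p < 1e-4); in
the adjusted linear probability model a fully contraindicated prescription
mix is associated with a +5.2 pp higher limitation probability (the
generator planted +4 pp) and a fully indicated mix with −2.2 pp (planted
−3 pp), i.e. about +48% and −21% of the outcome's mean.

The same analysis runs from the shell:

```bash
offlabel simulate --out-dir data/            # calibrated preset
offlabel classify --data-dir data/ --out-dir out/
offlabel prevalence --data-dir data/ --classifications out/classifications.csv \
         --out out/prevalence.csv
offlabel run-all --out-dir run/ --seed 1     # everything, one manifest
```

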