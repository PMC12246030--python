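# rxpersist

Treatment persistence, adherence and competing-risks analysis of
prescription-fill streams.

`rxpersist` is aimed at pharmacoepidemiologists studying how patients use
chronic medication in routine care — the motivating application is
glucose-lowering therapy (GLP-1 receptor agonists, SGLT2 inhibitors) in
nationwide prescription registers.  In such data the only observable signal
of drug use is the sequence of pharmacy dispensations, so "being on
treatment", "discontinuing" and "reinitiating" are *constructed* quantities,
and they are sensitive to the technical choices used to construct them.
This package makes those constructions explicit, configurable and testable.

## What it computes

**Exposure model.**  Each fill dispenses `days_supply` days of drug.  Early
refills are *stockpiled* (the patient finishes the old supply first), so a
person's coverage is a set of half-open day intervals.  Supplies pool at the
drug-class level, so switching drug within the class never interrupts
exposure.  Coverage gaps no longer than a *grace period* `g` are bridged;
a longer gap ends the treatment episode, with the discontinuation dated at

```
discontinuation day = estimated end of supply + g          (default g = 90 days)
```

The next fill after a discontinuation is a reinitiation, and patients may
cycle any number of times.

**Statistics.**  With death as a competing risk (a dead patient can never
discontinue), cumulative incidence is estimated by the Aalen–Johansen
estimator

```
CIF_k(t) = Σ_{t_j ≤ t}  S(t_j−) · d_kj / n_j ,
```

where `S` is the all-cause Kaplan–Meier, and covariate associations by the
Fine–Gray sub-distribution hazard model, fitted by Newton–Raphson on the
IPCW-weighted partial likelihood in which subjects with a prior competing
event stay in risk sets with weight `G(t−)/G(T_i−)` (`G` = censoring
Kaplan–Meier).  Reported effects are sub-distribution hazard ratios (sdHR)
with log-scale CIs.

**Utilization metrics.**
*PDC* — proportion of days covered in the first 365 days after initiation
(raw supply, no grace), for patients alive at one year, with the share above
the ≥80 / ≥90 / 100 % adherence thresholds.
*PPC* — proportion of patients covered: at each time since initiation, the
share of alive, non-emigrated initiators whose grace-extended treatment is
ongoing, counting reinitiators.  Unlike 1 − CIF, PPC is only weakly
sensitive to the grace period, which is the reason to report both.

**Trajectories.**  Over a 3-year horizon each patient's path is summarised
as up to five events — first within-class switch, discontinuation,
reinitiation, death/emigration, continued treatment — with terminal-state
shares and a switch matrix between drug categories.

**Synthetic register.**  `rxpersist.simulate` generates fills/persons tables
from a latent behaviour model (entry process, refill gaps with early refills
and long lapses, covariate-dependent discontinuation hazard, reinitiation,
switching, death/emigration) together with the latent ground truth, so every
estimator can be validated without access to confidential register data.

## Worked example

```python
import rxpersist as rx
from rxpersist.pipeline import RunConfig, run_study

cfg = rx.SimConfig(n_patients=2000, seed=42)       # synthetic register
fills, persons, truth = rx.simulate_registry(cfg)
res = run_study(RunConfig(), fills=fills, persons=persons)

print(rx.format_cif(res.cif_discontinuation[90], 365))   # grace 90, 1 year
print(rx.format_cif(res.cif_discontinuation[90], 1095))  # grace 90, 3 years
print(rx.format_cif(res.cif_reinitiation[90], 365))
fit = res.fg_fits["bmi_category"]
```

prints

```
11.0% (95% CI 9.7, 12.4)
40.7% (95% CI 38.3, 43.1)
73.6% (95% CI 70.3, 76.6)
```

— 11.0 % of the 2,000 simulated initiators have discontinued (no refill
within 90 days of running out of supply) one year after their first fill,
40.7 % by three years; among those who discontinued, 73.6 % have refilled
again within a year of the discontinuation day.  The Fine–Gray fit reports,
e.g., `age_band_50_69: sdHR 0.82 (0.68, 0.98)` — patients aged 50–69
discontinue at a lower sub-distribution hazard than the youngest band, as
configured in the generator.  The proportion of patients covered at one
year is 93.8 %, well above `1 − CIF` because reinitiators count as covered.

The same pipeline runs from the shell:

```
rxpersist simulate --n 2000 --seed 42 --out data/
rxpersist run-study --config study.yaml --out results/
rxpersist ppc --config study.yaml --out ppc.csv
rxpersist finegray --records records.csv --covars male,age_band_50_69 --out fit.json
```

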