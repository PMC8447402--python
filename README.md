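# hccsurv

Risk-based surveillance scheduling for hepatocellular-carcinoma (HCC)
patients in complete response after radical treatment.

After curative treatment of intermediate-stage (BCLC-B) HCC, roughly a third
of complete responders progress within the first year and about two thirds
within three years, yet guideline follow-up grids are fixed calendars that
ignore when progression actually tends to happen. `hccsurv` implements the
full analysis pipeline behind an individualized alternative:

1. **Estimate** the monthly progression-probability profile from
   right-censored progression-free-survival (PFS) data — nonparametrically
   (Kaplan–Meier) and with a covariate-adjusted random survival forest (RSF,
   log-rank splits, out-of-bag ensemble curves).
2. **Schedule** a fixed budget of k follow-up visits (k = 6…11) over a
   36-month horizon to minimize the expected delay between progression and
   its detection, by exact dynamic programming.
3. **Evaluate** schedules by per-patient delayed-detection months and compare
   them against guideline controls (paired t, Wilcoxon signed-rank,
   Kruskal–Wallis).
4. **Simulate** calibrated synthetic cohorts so the whole pipeline is
   testable without patient-level data (none is publicly deposited for this
   population); covariate prevalences, event-time distribution and censoring
   are tuned to the published cohort statistics.

## Model

For survival curve S(t) on an integer monthly grid, the **monthly
progression mass** is

    p_m = S(m − 1) − S(m),   F(t) = 1 − S(t) = Σ_{m ≤ t} p_m,

i.e. the unconditional probability that progression falls in month m (the
conditional hazard h_m = p_m / S(m−1) is available as an accessor). Given a
visit set V ⊆ {1,…,H} with |V| = k, the **expected detection delay** is

    D(V) = Σ_m p_m · (next(m) − m),   next(m) = min{v ∈ V ∪ {H} : v ≥ m},

progressions after the last visit being detected at the horizon boundary H.
`min_expected_delay_schedule` minimizes D(V) exactly in O(H²k) by dynamic
programming over (last visit, visits used); `top_mass_schedule` implements
the simpler rule "visit the k highest-probability months". A patient who
progresses at time t and is next seen at visit v ≥ t contributes delay
v − t (e.g. progression on day 200 with the next visit on day 240 counts 40
delayed days).

## Worked example

```python
import numpy as np
from hccsurv import (
    default_generator_config, generate_cohort, split_cohort,
    min_expected_delay_schedule, fixed_schedule,
    evaluate_schedule, compare_schedules,
)
from hccsurv.hazard import RSFConfig, rsf_profile

cohort = generate_cohort(default_generator_config(n=546, seed=1))
train, valid = split_cohort(cohort, 0.70, seed=2)

profile = rsf_profile(train, RSFConfig(n_trees=1000, seed=3), 36)
schedule = min_expected_delay_schedule(profile, 7)

ecio = fixed_schedule("ecio")      # guideline control: 1,3,6,9,12,18,24,30,36
cmp = compare_schedules(train, schedule, ecio)
```

Output of the session above:

```
cohort: n=546, progression events 56.4%, median PFS 12.99 mo
train n=382; RSF peak month 10; F(12)=0.351, F(24)=0.567, F(36)=0.656
optimized 7-visit schedule: [8, 10, 12, 15, 18, 25, 31]
train delays: risk-based total 289.6 mo (mean 1.47), ECIO total 411.6 mo (mean 2.09)
paired t p=2.27e-07, Wilcoxon p=5.37e-07, mean difference -0.62 mo
validation: risk-based 149.7 vs ECIO 180.7 total mo
```

Reading: the synthetic cohort reproduces the published event rate (~57%) and
median PFS; the forest locates the progression wave's peak near month 9–10;
a 7-visit optimized schedule concentrates visits where the monthly mass is
high and cuts mean delayed detection from 2.1 to 1.5 months per progressor
relative to the 9-visit guideline grid, with paired p-values far below 0.01
— and the gain carries over to the held-out validation split.

The same pipeline is available from a shell:

```bash
hccsurv run-all --seed 1 --output run1            # simulate → estimate → schedule → evaluate
hccsurv simulate --n 546 --seed 1 --output data/  # individual stages
hccsurv estimate data/cohort_train.csv --output profile.csv
hccsurv schedule profile.csv --budget 7
hccsurv evaluate data/cohort_train.csv run1/schedule_min_expected_delay_k7.json
```

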