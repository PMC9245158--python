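# msrelsurv

Non-parametric Markov multi-state models integrated with **relative
survival**: when a registry records *that* patients died but not *why*,
external population mortality tables (life tables indexed by age, sex and
calendar year) make it possible to split every transition into a death
state into a **population** part — the mortality the matched general
population would have produced — and an **excess**, disease-related part.

The package is aimed at biostatisticians analysing cohorts with competing
risks and intermediate events (the leading example is an illness–death
model for transplant patients: alive relapse-free → relapse, with death
before relapse, "NRM", and death after relapse, "DaR"), where especially in
older cohorts a substantial share of deaths is not caused by the disease.

## Model

For a Markov multi-state process with states `h, j` and transition hazards
`λ_hj(t)`, transition probabilities are the product integral
`P(s,t) = ∏_(s,t] (I + dΛ(u))`, estimated by plugging in the Nelson–Aalen
estimator `Λ̂_hj(t) = ∫ dN_hj(u)/Y_h(u)` (Aalen–Johansen). For a transition
into a death state the additive relative-survival decomposition
`λ_hj = λ_hj,P + λ_hj,E` is estimated by

```
Λ̂_hj,P(t) = ∫₀ᵗ Σᵢ Y_h,i(u) dΛ_Pi(u) / Y_h(u)        (ratetable part)
Λ̂_hj,E(t) = Λ̂_hj(t) − Λ̂_hj,P(t)                      (excess part)
```

where `Λ_Pi` is subject *i*'s cumulative population hazard along their own
age/sex/calendar trajectory. Each death state is replaced by a population
and an excess counterpart and the same product integral runs over the
extended hazard matrix, yielding `P̂_hj,P(s,t)` and `P̂_hj,E(s,t)` whose sum
reproduces the unsplit model exactly. Variances come either from the
Greenwood estimator (treating the population part as fixed) or from a
subject-level bootstrap; six confidence-interval constructions are
provided (`plain.G`, `plain.boot`, `log.boot`, `q.boot`, `logit.boot`,
`cloglog.boot`).

A scenario simulator generates cohorts with latent population/excess death
times drawn from a ratetable, and numerically integrates the extended model
over the covariate distribution to obtain exact true values, enabling
bias / SE / coverage studies.

## Worked example

```python
import numpy as np
from msrelsurv import (make_scenario, simulate_cohort, nelson_aalen,
                       extend_structure, split_hazards, extended_probtrans,
                       DAYS_PER_YEAR)
from msrelsurv.simulator import illness_death_structure

cfg = make_scenario("exp.large")          # old cohort: many population deaths
cohort = simulate_cohort(cfg, n=1000, seed=7)

smap = extend_structure(illness_death_structure(), ["NRM", "DaR"])
haz = nelson_aalen(cohort.dataset, extra_times=[10 * DAYS_PER_YEAR])
ext = split_hazards(haz, cohort.dataset, cfg.ratetable, smap)
probs = extended_probtrans(ext, smap, s=0.0)

P = probs.at(10 * DAYS_PER_YEAR)[0]       # occupation probabilities at 10y
for state, p in zip(smap.extended.states, P):
    print(f"{state:8s} {p:.3f}")
```

prints (seed 7):

```
ARF      0.089
Relapse  0.015
NRM.p    0.369
NRM.e    0.245
DaR.p    0.055
DaR.e    0.227
```

i.e. at 10 years an estimated 36.9% of patients have died of population
causes before relapse (`NRM.p`) versus 24.5% of disease-related causes
(`NRM.e`) — in this old cohort more than half of the deaths without
relapse are *not* attributable to the disease, which a standard
multi-state analysis (NRM 61.4%) cannot reveal. After relapse the excess
part dominates (`DaR.e` 22.7% vs `DaR.p` 5.5%): death after relapse is
mostly disease-related.

A command-line interface mirrors this flow
(`msrs simulate|fit|ci|evaluate`, see `msrs --help`).

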