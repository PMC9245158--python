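# Methods

## Model and estimators

The process is a Markov multi-state model on a finite state space with
clock-forward time (all times measured in days since study entry).
Transition hazards are estimated by Nelson–Aalen,
`Λ̂_hj(t) = Σ_{u≤t} dN_hj(u)/Y_h(u)`, with risk intervals `(Tstart, Tstop]`:
a subject with delayed entry is excluded at their entry time and an event
keeps the subject in the risk set at the event time; when an event and a
censoring tie, the event is counted first. Transition probability matrices
are the Aalen–Johansen product integral with diagonal increments
`−Σ_{j≠h} ΔΛ̂_hj`, multiplied in increasing time order; this construction
forces every row to sum to one regardless of the signs of the increments.

The relative-survival extension assumes the observed hazard of each
transition into a death state decomposes additively into a population part
and an excess part. The population part is estimated as the risk-set
weighted mean of the subjects' individual ratetable hazards,

    Λ̂_hj,P(t) = ∫₀ᵗ Σᵢ Y_h,i(u) dΛ_Pi(u) / Y_h(u),

where each subject's attained age and calendar date advance with follow-up
(the "trajectory" matching). The excess part is the difference from the
Nelson–Aalen estimate, so the two parts add back to the observed estimate
exactly at every grid point — an identity the tests assert at 1e-10
together with its probability-level counterpart
`P̂_h(j,P) + P̂_h(j,E) = P̂_hj`. Excess cumulative hazards may decrease, and
may go negative when the cohort outlives its reference population; they
are never floored by default (`clamp_excess` exists, off by default, and
logs how many points it clamps), since a negative excess estimate is a
diagnostic worth seeing, to be interpreted with caution.

## Ratetable conventions

* Year length 365.241 days for all age/calendar arithmetic (the
  convention of the established relative-survival ratetables), defined
  once in `_constants.py`.
* Annual death probabilities `q` convert to a constant daily hazard
  `−log(1−q)/365.241` within each age × year × sex cell; hazards are held
  constant over each day.
* Attained age is `floor((age_at_entry + u)/365.241)`; the calendar year
  advances the same way. Lookups clamp at the table boundary — values are
  held constant, never extrapolated.
* Unknown sex is an error, not an imputation.
* Per-subject cumulative hazards use left-aligned daily rectangles, making
  `Λ_Pi` piecewise linear with daily knots; death times are drawn by
  inverting this function against an exponential deviate, with a +inf
  sentinel if the clamped table cannot reach the deviate within 200
  attained years.

## Daily accumulation and the evaluation grid

The population part is accumulated on a daily lattice. Within a day, each
subject contributes their daily hazard weighted by their time at risk in
that day, normalized by the total time at risk, times the part of the day
with a non-empty risk set. This is exact whenever within-day risk
intervals are nested (always true for a common entry time) and makes
identical individual hazards pass through unchanged: if every subject has
hazard λ, the estimate is exactly λ·t while the risk set is non-empty.

Estimates are reported on a grid. The default grid is the pooled distinct
event times of all transitions, with population mass between two grid
points lumped onto the *later* one (right-continuity of the step
convention); the estimators may additionally be evaluated at any requested
time points (the CLI exposes `--eval daily`), which removes the lumping
ambiguity. The replication harness adds its reporting times (1, 2, 5, 10
years) to the grid so that population mass accrued since the last event is
included at the reporting time; the residual within-day discretization is
far below Monte-Carlo error at the sample sizes studied.

## Variances and confidence intervals

Two variance routes:

* **Greenwood** — population-kind transitions are treated as fixed (zero
  variance and covariance, because mortality tables are deterministic);
  excess-kind transitions inherit the Greenwood variance of their observed
  parent. For transition probabilities the covariance of vec P(s,t) is
  propagated recursively through the product integral, with increment
  covariances `var = dN(Y−dN)/Y³`, `cov = −dN dN′/Y³` for transitions
  sharing a departure state, diagonal entries by linearity. Degenerate
  increments (Y = dN) fall back to the Aalen form 1/Y with a warning.
  This route knowingly understates the uncertainty of population-related
  quantities: the risk-set composition makes Λ̂_hj,P random even though the
  table is not. The simulation harness shows exactly this failure (CP of
  `plain.G` collapsing for population states) — it is a property of the
  assumption, not a bug.
* **Bootstrap** — simple resampling of subjects with replacement (records
  and demographic profile travel together; left-truncated records keep
  their entry times), re-running the full pipeline per replicate; B = 100
  by default. Sample variance uses denominator B − 1; replicates with an
  empty risk set at a target time are excluded with a logged count rather
  than imputed.

Six interval constructions: plain scale with Greenwood or bootstrap SE,
log scale (delta method), empirical bootstrap quantiles (interpolated,
type-7 — the choice is visible and pinned for reproducibility), logit and
complementary log-log scales. `Φ(1−α/2)` is read as the standard normal
quantile (a cdf value could not scale a standard error). Plain intervals
are deliberately not clipped to [0,1]; zero variance yields a degenerate
point interval. Logit/cloglog apply only on the probability scale.

## Simulator

Five scenarios share the illness–death layout, uniform age, Bernoulli(0.5)
sex and uniform diagnosis year on [1990-01-01, 2000-01-01], a 10-year
administrative cutoff, and event times from `λ(t) = a·b·t^(b−1)·exp(β·agec)`
(age centred before applying β). Population death times are drawn from the
ratetable along each subject's own trajectory; after relapse, the excess
death time comes from a left-truncated Weibull conditional on the relapse
time and the population death time from the ratetable truncated at the
relapse time — clock-forward, so the Markov property holds. Only the
minimum of the latent times is observed; cause labels never enter the
emitted dataset.

Scenario parameters (per-year rates; isolated in
`simulator.SCENARIO_DEFAULTS`) were fixed once to satisfy the design's
qualitative constraints and reflect a realistic transplant cohort:

| scenario    | ages  | relapse        | excess NRM      | excess DaR |
|-------------|-------|----------------|-----------------|------------|
| exp.small   | 20–45 | 0.10           | 0.08            | 0.40       |
| exp.large   | 65–80 | 0.08           | 0.07            | 0.40       |
| weibull     | 20–45 | 0.10, b=0.8    | 0.08, b=1.2     | 0.40, b=0.9|
| cov.eff.pos | 20–45 | 0.10, β=+0.03  | 0.08, β=+0.05   | 0.40, β=0  |
| cov.eff.neg | 20–45 | 0.10, β=−0.03  | 0.08, β=+0.05   | 0.40, β=0  |

The old age range of `exp.large` makes population and excess NRM deaths
comparably frequent (≈57% of observed NRM deaths are population deaths
under the bundled table, verified by simulation); the young ranges keep
the population share small (≈4%). The large excess DaR rate encodes the
poor post-relapse prognosis. The bundled ratetable is **synthetic**:
a Gompertz age shape (1e-4·exp(0.09·age) per year, ≈5%/yr for 70-year-old
men), sex factors 0.8/1.5 and a mild −0.5%/yr calendar trend — realistic
in shape and magnitude for a European national table while keeping the
repository free of external data; any table in the supported CSV/HMD
formats can be substituted.

Censoring is exponential; its rate is calibrated by bisection so that the
share of subjects whose follow-up ends in *random* censoring (not the
10-year cutoff — the administrative reading is available by recomputing on
the latent times) is 20% ± 1pp, using one large internally-seeded cohort
(n=20000) with one censoring draw per subject, which makes the share
monotone in the rate and the calibration deterministic.

## True values

Exact hazards and occupation probabilities are obtained by integrating the
extended model over the covariate law: a midpoint lattice over age × sex ×
diagnosis year (16 × 2 × 6 by default; doubling changes occupation
probabilities by < 1e-4) carries per-combination daily intensities — exact
per-day cumulative-hazard increments for the parametric laws (robust to
the Weibull b<1 singularity at t=0) and the ratetable trajectory for the
population transitions. Because the extended chain is acyclic with depth
two, the within-day transition matrix has a closed form, so the forward
solve is exact for intensities constant within a day; the constant-hazard
zero-table case reproduces the competing-risks closed form to ~1e-8.
Marginal occupation probabilities are the covariate-weighted mixture;
marginal cumulative hazards weight each combination's hazard by its
probability of being at risk — the population counterpart of the risk-set
weighted estimator.

## Performance harness and problem sizes

`run_replications` spawns one child seed per replicate (any replicate is
reproducible in isolation), simulates, fits, computes both variance
routes, all applicable intervals, and aggregates relative bias
`(θ−θ̄)/θ`, empirical SE (denominator nsim−1) and coverage per method
(failed or inapplicable replicates excluded with counts reported). The
default study sizes in the test suite — nsim = 200 at n = 2000 for bias
and n = 1000 with B = 100 for SE/coverage — were chosen as the smallest
sizes at which the Monte-Carlo error bands (3 SEs) are tight enough to be
informative while a full study runs in minutes on a single core; the
formula `nsim_for_cp_se` reports what a publication-grade coverage study
would need (1900 replications for a 0.5% SE at 95% coverage).

The repeated-fit engine (`_fast.py`) is a vectorized reimplementation of
the same estimators for the fixed illness–death layout, using bootstrap
multiplicity weights so per-subject daily-hazard rows and the evaluation
grid are prepared once per cohort; it is tested to agree with the generic
pipeline to 1e-12, including under resampling (a weighted fit equals the
generic fit on the physically duplicated dataset). Its occupation-row
factorization exploits the acyclic chain via cumulative products and falls
back to the sequential recursion when a risk set is wiped out.

## Known limitations

* Greenwood variances for left-truncated transitions understate the truth
  (visible for the relapse → excess-death hazard); this is inherent to the
  classical estimator in basic multi-state models as well, and no fix is
  attempted here.
* The within-day risk-set approximation of the population accumulation is
  exact only for nested within-day risk intervals; with fractional entry
  times of several subjects inside one day it is an approximation (error
  bounded by one day of population hazard).
* Only death states are split; splitting transitions into intermediate
  states would require event-specific population tables and is out of
  scope, as are covariate models on the excess hazards and net-survival
  style measures.
* The simulator emulates independent event times, exponential censoring
  and exact event dates. Real registry data bring dependent censoring,
  reporting delays and misrecorded dates that passing tests say nothing
  about.
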