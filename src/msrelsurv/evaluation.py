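"""Replication harness for simulation performance (ADEMP-style).

Runs ``nsim`` independent replications of simulate -> estimate ->
variances -> confidence intervals against the numerically integrated
truth, and summarizes per estimand and evaluation time:

* mean estimate and relative bias ``(theta - mean) / theta``,
* empirical SE (SD across replications, denominator nsim - 1),
* mean Greenwood SE and mean bootstrap SE,
* coverage probability of each interval method (share of replications
  whose interval contains the true value, among replications where the
  method is applicable).

Child seeds are spawned from one seed sequence, so any single replicate
can be reproduced in isolation.  Logit and cloglog intervals are only
applied on the probability scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._constants import DAYS_PER_YEAR
from ._fast import IllnessDeathFitter, extended_illness_death_map
from .msm_core import greenwood_var_probtrans, _greenwood_increments
from .simulator import (
    EXT_STATES,
    EXT_TRANS_LABELS,
    ScenarioConfig,
    TrueValueTable,
    _simulate_arrays,
    true_values,
)
from .variance_ci import CI_METHODS, confidence_interval

__all__ = ["PerformanceTable", "run_replications", "nsim_for_cp_se", "ESTIMANDS"]

ESTIMANDS = tuple(f"Haz:{t}" for t in EXT_TRANS_LABELS) + tuple(
    f"P:{s}" for s in EXT_STATES
)
#: columns 0-4 cumulative hazards, 5-10 occupation probabilities
_PROB_COLS = np.arange(5, 11)
_HAZ_KIND = ("observed", "population", "excess", "population", "excess")


def nsim_for_cp_se(p: float, se: float) -> int:
    """Replications needed so the Monte-Carlo SE of a coverage estimate is ``se``.

    Smallest integer >= p (1 - p) / se^2 (binomial variance of the
    coverage proportion).
    """
    if not 0 < p < 1 or se <= 0:
        raise ValueError("need 0 < p < 1 and se > 0")
    return int(math.ceil(round(p * (1 - p) / se**2, 9)))


@dataclass
class PerformanceTable:
    """Tidy summary of one replication study plus raw per-replicate estimates."""

    table: pd.DataFrame
    truth: TrueValueTable
    estimates: np.ndarray  # (nsim, T, 11)
    meta: dict = field(default_factory=dict)

    def row(self, estimand: str, time_years: float) -> pd.Series:
        sel = (self.table["estimand"] == estimand) & (
            np.isclose(self.table["time_years"], time_years)
        )
        return self.table.loc[sel].iloc[0]


def _ci_cover(method, th, truth, se=None, reps=None, alpha=0.05, prob_cols=None):
    """Coverage indicators for one method, with domain masking.

    Invalid applications (non-positive estimate on the log scale, values
    outside (0, 1) for logit/cloglog, and those two methods on the
    hazard scale) are masked out rather than counted.
    """
    valid = np.isfinite(th)
    if method == "log.boot":
        valid &= th > 0
    elif method in ("logit.boot", "cloglog.boot"):
        valid &= (th > 0) & (th < 1)
        if prob_cols is not None:
            mask = np.zeros(th.shape, dtype=bool)
            mask[..., prob_cols] = True
            valid &= mask
    safe = np.where(valid, th, 0.5)
    if method == "q.boot":
        lo, hi = np.nanquantile(reps, [alpha / 2, 1 - alpha / 2], axis=0)
    else:
        lo, hi = confidence_interval(safe, variance=se**2, method=method, alpha=alpha)
    cover = (lo <= truth) & (truth <= hi)
    return cover, valid


def run_replications(
    cfg: ScenarioConfig,
    n: int,
    nsim: int,
    B: int = 100,
    seed: int = 0,
    eval_years=(1.0, 2.0, 5.0, 10.0),
    alpha: float = 0.05,
    bootstrap: bool = True,
    greenwood_probs: bool = True,
    truth: TrueValueTable = None,
) -> PerformanceTable:
    """Full replication study for one scenario and sample size.

    Replicate ``i`` uses the ``i``-th child of ``SeedSequence(seed)``
    for simulation and for its own bootstrap.  ``bootstrap=False`` or
    ``greenwood_probs=False`` skip the corresponding variance pieces
    (and the interval methods needing them) for speed.
    """
    if nsim < 2:
        raise ValueError("nsim must be >= 2")
    eval_days = np.asarray(eval_years, dtype=float) * DAYS_PER_YEAR
    T = eval_days.size
    if truth is None:
        truth = true_values(cfg)
    theta = np.concatenate(
        [truth.cum_hazard(eval_days), truth.occupation(eval_days)], axis=1
    )  # (T, 11)

    smap = extended_illness_death_map()
    methods = [
        m
        for m in CI_METHODS
        if (bootstrap or m == "plain.G") and (greenwood_probs or m != "plain.G")
    ]
    est = np.full((nsim, T, 11), np.nan)
    gw_se = np.full((nsim, T, 11), np.nan)
    boot_se = np.full((nsim, T, 11), np.nan)
    cover = {m: np.zeros((nsim, T, 11), dtype=bool) for m in methods}
    valid = {m: np.zeros((nsim, T, 11), dtype=bool) for m in methods}
    n_failed = 0

    children = np.random.SeedSequence(seed).spawn(nsim)
    with warnings.catch_warnings():
        # surface degenerate-risk-set notes once, not per replicate
        warnings.simplefilter("once")
        for i in range(nsim):
            rng = np.random.default_rng(children[i])
            try:
                arr = _simulate_arrays(cfg, n, rng)
                fitter = IllnessDeathFitter(arr, eval_days)
                fit = fitter.fit()
            except Exception:
                n_failed += 1
                continue
            est[i, :, :5] = fit.cum_hazard
            est[i, :, 5:] = fit.occupation

            # Greenwood variances: hazards from their counting data (zero for
            # population parts), probabilities from the recursive estimator
            dn_for = (0, None, 1, None, 2)
            y_for = (0, 0, 0, 1, 1)
            for m in range(5):
                if dn_for[m] is None:
                    gw_se[i, :, m] = 0.0
                else:
                    v = np.cumsum(
                        _greenwood_increments(fit.dN[:, dn_for[m]], fit.Y[:, y_for[m]])
                    )
                    gw_se[i, :, m] = np.sqrt(v[fitter.eval_pos])
            if greenwood_probs:
                probs = greenwood_var_probtrans(
                    fitter.hazard_estimates(fit), smap.extended, 0.0
                )
                pos = np.searchsorted(probs.grid, eval_days, side="right") - 1
                gw_se[i, :, 5:] = np.sqrt(probs.variance[pos][:, 0, :])

            reps = None
            if bootstrap:
                reps = np.empty((B, T, 11))
                for b in range(B):
                    counts = np.bincount(rng.integers(0, n, size=n), minlength=n)
                    fb = fitter.fit(counts.astype(float))
                    reps[b, :, :5] = fb.cum_hazard
                    reps[b, :, 5:] = fb.occupation
                boot_se[i] = np.std(reps, axis=0, ddof=1)

            for m in methods:
                se = gw_se[i] if m == "plain.G" else boot_se[i]
                cover[m][i], valid[m][i] = _ci_cover(
                    m, est[i], theta, se=se, reps=reps, alpha=alpha, prob_cols=_PROB_COLS
                )

    ok = ~np.isnan(est[:, 0, 0])
    nsim_done = int(ok.sum())
    mean_est = np.nanmean(est, axis=0)
    emp_se = np.nanstd(est, axis=0, ddof=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN SE columns
        mean_gw = np.nanmean(gw_se, axis=0)
        mean_boot = np.nanmean(boot_se, axis=0) if bootstrap else None
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_bias = (theta - mean_est) / theta

    rows = []
    for t_i, ty in enumerate(np.asarray(eval_years, dtype=float)):
        for k, name in enumerate(ESTIMANDS):
            row = {
                "estimand": name,
                "time_years": ty,
                "true_value": theta[t_i, k],
                "mean_est": mean_est[t_i, k],
                "rel_bias": rel_bias[t_i, k],
                "emp_se": emp_se[t_i, k],
                "mean_gw_se": mean_gw[t_i, k],
                "mean_boot_se": mean_boot[t_i, k] if bootstrap else np.nan,
                "nsim": nsim_done,
                "n": n,
                "B": B if bootstrap else 0,
                "seed": seed,
                "n_failed": n_failed,
            }
            for m in methods:
                nv = valid[m][ok, t_i, k].sum()
                row["cp_" + m.replace(".", "_")] = (
                    cover[m][ok, t_i, k].sum() / nv if nv else np.nan
                )
                row["cp_n_" + m.replace(".", "_")] = int(nv)
            rows.append(row)
    table = pd.DataFrame(rows)
    meta = dict(
        scenario=cfg.name, n=n, nsim=nsim, B=B, seed=seed, alpha=alpha,
        n_failed=n_failed,
    )
    return PerformanceTable(table, truth, est, meta)
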