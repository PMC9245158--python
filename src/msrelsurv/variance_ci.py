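"""Variance estimation and confidence intervals.

Two variance routes are supported for the split estimators.  The
Greenwood route treats the population hazard as fixed (zero variance and
covariance, since mortality tables are deterministic) and assigns the
excess hazard the Greenwood variance of the corresponding observed
transition.  The non-parametric bootstrap resamples whole subjects with
replacement (records and demographic profile travel together) and
re-runs the full pipeline, capturing the variability that the risk-set
composition injects into the population part as well.

Six interval constructions (``plain.G``, ``plain.boot``, ``log.boot``,
``q.boot``, ``logit.boot``, ``cloglog.boot``) cover plain, log, logit
and complementary log-log scales plus bootstrap quantiles.  Plain
intervals are deliberately not clipped to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .msm_core import MultiStateDataset, nelson_aalen
from .ratetable import RateTable
from .relsurv_split import SplitMap, extended_probtrans, split_hazards

__all__ = [
    "CI_METHODS",
    "Target",
    "BootstrapDistribution",
    "ConfidenceInterval",
    "bootstrap_estimates",
    "variance_of",
    "confidence_interval",
]

logger = logging.getLogger(__name__)

CI_METHODS = ("plain.G", "plain.boot", "log.boot", "q.boot", "logit.boot", "cloglog.boot")


@dataclass(frozen=True)
class Target:
    """What to extract from one fitted extended model.

    ``scale`` is ``hazard`` (key = extended transition number) or
    ``probability`` (key = (from_state_label, to_state_label) of the
    extended structure, evaluated as P(0, time) with the step
    convention).  ``time`` is in days.
    """

    scale: str
    key: object
    time: float

    def extract(self, ext_hazards, probs):
        if self.scale == "hazard":
            est = ext_hazards[self.key]
            k = np.searchsorted(est.grid, self.time, side="right") - 1
            return est.cum_hazard[k] if k >= 0 else 0.0
        mat = probs.at(self.time)
        h = probs.structure.states.index(self.key[0])
        j = probs.structure.states.index(self.key[1])
        return mat[h, j]


@dataclass
class BootstrapDistribution:
    """Replicate values of one target (NaN marks failed replicates)."""

    target: Target
    values: np.ndarray
    B: int
    seed: int

    @property
    def n_missing(self):
        return int(np.isnan(self.values).sum())

    def variance(self) -> float:
        vals = self.values[~np.isnan(self.values)]
        if vals.size < 2:
            raise ValueError("not enough bootstrap replicates for a variance")
        return float(np.var(vals, ddof=1))


@dataclass(frozen=True)
class ConfidenceInterval:
    lower: float
    upper: float
    method: str
    alpha: float


def bootstrap_estimates(
    ds: MultiStateDataset,
    rt: RateTable,
    smap: SplitMap,
    targets,
    B: int = 100,
    seed: int = 0,
    s: float = 0.0,
) -> list:
    """Subject-level bootstrap of the full estimation pipeline.

    Each replicate draws n subject ids with replacement; a subject's
    records and profile travel together under a fresh id (so a subject
    drawn twice counts twice in every risk set, and left-truncated
    records keep their entry times).  The pipeline (Nelson-Aalen ->
    split -> product integral) is re-run per replicate.  Replicates with
    an empty risk set at a target time are recorded as NaN and excluded
    from variances, with a logged count.

    Returns one :class:`BootstrapDistribution` per target.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    ids = ds.records["id"].unique()
    n = ids.size
    by_id_rec = {i: g for i, g in ds.records.groupby("id")}
    prof = ds.profiles.set_index("subject_id") if ds.profiles is not None else None
    need_prob = any(t.scale == "probability" for t in targets)
    grid_extra = sorted({t.time for t in targets})
    values = np.full((len(targets), B), np.nan)
    for b in range(B):
        draw = ids[rng.integers(0, n, size=n)]
        rec_parts, prof_rows = [], []
        for new_id, old in enumerate(draw):
            g = by_id_rec[old].copy()
            g["id"] = new_id
            rec_parts.append(g)
            if prof is not None:
                row = prof.loc[old]
                prof_rows.append(
                    {"subject_id": new_id, **{k: row[k] for k in prof.columns}}
                )
        ds_b = MultiStateDataset(
            ds.structure,
            pd.concat(rec_parts, ignore_index=True),
            pd.DataFrame(prof_rows) if prof_rows else None,
        )
        try:
            haz = nelson_aalen(ds_b, extra_times=grid_extra)
            ext = split_hazards(haz, ds_b, rt, smap)
            probs = extended_probtrans(ext, smap, s) if need_prob else None
            for k, t in enumerate(targets):
                values[k, b] = t.extract(ext, probs)
        except ValueError:
            pass  # replicate left as NaN
    out = []
    for k, t in enumerate(targets):
        dist = BootstrapDistribution(t, values[k], B, seed)
        if dist.n_missing:
            logger.info(
                "bootstrap target %s: %d/%d replicates missing", t, dist.n_missing, B
            )
        out.append(dist)
    return out


def variance_of(theta_hat, option: str, context) -> float:
    """Variance of one estimate under the chosen option.

    ``greenwood``: ``context`` is a precomputed scalar variance or an
    ``(estimate, time)`` pair, where the estimate is a
    :class:`~msrelsurv.msm_core.HazardEstimate`; population-kind
    estimates have zero variance, excess-kind ones carry the Greenwood
    variance of their observed parent transition (the fixed-population
    convention), observed ones their own Greenwood series.
    ``bootstrap``: ``context`` is a :class:`BootstrapDistribution`; the
    sample variance of the replicates (denominator B - 1) is returned.
    """
    if option == "bootstrap":
        if not isinstance(context, BootstrapDistribution):
            raise ValueError("bootstrap variance requires bootstrap replicates")
        return context.variance()
    if option != "greenwood":
        raise ValueError(f"unknown variance option {option!r}")
    if np.isscalar(context):
        return float(context)
    est, time = context
    if est.kind == "population":
        return 0.0
    if est.variance is None:
        raise ValueError("estimate carries no Greenwood variance series")
    k = np.searchsorted(est.grid, time, side="right") - 1
    return float(est.variance[k]) if k >= 0 else 0.0


def _check(cond, method, what):
    if not np.all(cond):
        raise ValueError(f"{method} interval requires {what}")


def confidence_interval(
    theta_hat,
    variance=None,
    method: str = "log.boot",
    alpha: float = 0.05,
    replicates=None,
):
    """One of the six interval constructions (vectorized over inputs).

    ``plain.G`` and ``plain.boot`` share the symmetric plain-scale form
    and differ only in which variance the caller supplies; ``q.boot``
    ignores ``variance`` and takes interpolated (type-7) empirical
    quantiles of ``replicates``.  Log/logit/cloglog intervals follow the
    delta method on their scale and require theta in the right domain.
    Plain intervals may leave [0, 1]; zero variance yields a degenerate
    point interval.
    """
    if method not in CI_METHODS:
        raise ValueError(f"unknown CI method {method!r}")
    z = norm.ppf(1 - alpha / 2)
    th = np.asarray(theta_hat, dtype=float)
    if method == "q.boot":
        if replicates is None:
            raise ValueError("q.boot requires bootstrap replicates")
        vals = np.asarray(replicates, dtype=float)
        vals = vals[~np.isnan(vals)]
        lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2], method="linear")
    else:
        se = np.sqrt(np.asarray(variance, dtype=float))
        if method in ("plain.G", "plain.boot"):
            lo, hi = th - z * se, th + z * se
        elif method == "log.boot":
            _check(th > 0, method, "theta > 0")
            lo = th * np.exp(-z * se / th)
            hi = th * np.exp(z * se / th)
        elif method == "logit.boot":
            _check((th > 0) & (th < 1), method, "0 < theta < 1")
            span = z * se / (th * (1 - th))
            l = np.log(th / (1 - th)) - span
            u = np.log(th / (1 - th)) + span
            lo, hi = np.exp(l) / (1 + np.exp(l)), np.exp(u) / (1 + np.exp(u))
        elif method == "cloglog.boot":
            _check((th > 0) & (th < 1), method, "0 < theta < 1")
            c = se / (th * np.log(th))  # log(theta) < 0, so c <= 0
            base = np.log(-np.log(th))
            lo = np.exp(-np.exp(base - z * c))
            hi = np.exp(-np.exp(base + z * c))
    if np.ndim(th) == 0 and np.ndim(lo) == 0:
        return ConfidenceInterval(float(lo), float(hi), method, alpha)
    return lo, hi
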