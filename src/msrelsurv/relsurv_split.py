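"""Splitting death transitions into population and excess parts.

When causes of death are unrecorded, external mortality tables let each
transition into a death state be decomposed additively,
``lambda_hj = lambda_hj,P + lambda_hj,E``: the population part is what
the general population matched on age, sex and calendar time would
experience; the excess part is the disease-related remainder.  Each death
state is replaced by a population and an excess counterpart, giving an
extended state space over which the usual product-integral machinery runs
unchanged.

The population cumulative hazard for transition h -> j is the risk-set
weighted mean of the subjects' individual ratetable hazards,

    Lambda_hj,P(t) = int_0^t sum_i Y_h,i(u) dLambda_Pi(u) / Y_h(u),

accumulated on a daily lattice (each subject's attained age and calendar
date advance with follow-up); the excess cumulative hazard is the
difference Nelson-Aalen minus population part, so the two parts sum to
the observed estimate exactly.  Excess increments may be negative (the
cohort can outlive its reference population); they are kept by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .msm_core import (
    HazardEstimate,
    MultiStateDataset,
    TransitionProbabilities,
    TransitionStructure,
    aalen_johansen,
    greenwood_var_probtrans,
)
from .ratetable import RateTable, subject_daily_hazards

__all__ = [
    "SplitMap",
    "extend_structure",
    "population_cum_hazard_transition",
    "split_hazards",
    "extended_probtrans",
    "clamp_excess",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitMap:
    """Bookkeeping between an original structure and its split extension.

    ``trans_map[m]`` is either an int (transition kept as-is, new number)
    or a ``(pop, excess)`` pair of new transition numbers.  ``state_map``
    maps each original state index to its extended index or to a
    ``(pop, excess)`` index pair for split death states.
    """

    original: TransitionStructure
    extended: TransitionStructure
    trans_map: dict
    state_map: dict

    @property
    def split_transitions(self):
        return {m: v for m, v in self.trans_map.items() if isinstance(v, tuple)}

    def kind_of(self, ext_trans: int) -> str:
        for v in self.trans_map.values():
            if isinstance(v, tuple):
                if ext_trans == v[0]:
                    return "population"
                if ext_trans == v[1]:
                    return "excess"
        return "observed"


def extend_structure(structure: TransitionStructure, death_states) -> SplitMap:
    """Replace each (absorbing) death state by population/excess twins.

    State order is preserved, each death state contributing its population
    counterpart (suffix ``.p``) immediately followed by its excess
    counterpart (suffix ``.e``).  Every transition into a death state is
    split into a population and an excess transition, numbered in the
    original transition order (population first).
    """
    death_idx = []
    for s in death_states:
        k = structure.states.index(s)
        if not structure.absorbing[k]:
            raise ValueError(f"death state {s!r} is not absorbing")
        death_idx.append(k)

    new_states, state_map = [], {}
    for k, s in enumerate(structure.states):
        if k in death_idx:
            state_map[k] = (len(new_states), len(new_states) + 1)
            new_states += [f"{s}.p", f"{s}.e"]
        else:
            state_map[k] = len(new_states)
            new_states.append(s)

    new_trans, trans_map = [], {}
    for m, (h, j) in enumerate(structure.transitions, start=1):
        h_new = state_map[h]
        if isinstance(h_new, tuple):  # cannot happen: death states are absorbing
            raise AssertionError
        if j in death_idx:
            jp, je = state_map[j]
            trans_map[m] = (len(new_trans) + 1, len(new_trans) + 2)
            new_trans += [(h_new, jp), (h_new, je)]
        else:
            trans_map[m] = len(new_trans) + 1
            new_trans.append((h_new, state_map[j]))
    extended = TransitionStructure(tuple(new_states), tuple(new_trans))
    return SplitMap(structure, extended, trans_map, state_map)


def _daily_pop_accumulation(H, tstart, tstop, n_days, counts=None):
    """Daily increments of the risk-set weighted population hazard.

    For day ``d`` (covering ``(d, d+1]``) the increment is the weighted
    mean of the subjects' daily hazards, weights equal to each subject's
    time at risk within the day, times the part of the day with a
    non-empty risk set.  Exact when within-day risk intervals are nested
    (always true for a common entry time); the weighted-mean form makes
    identical individual hazards pass through unchanged.

    ``counts`` are optional subject multiplicities (bootstrap reweighting).
    """
    n = len(tstart)
    D = int(n_days)
    c = np.ones(n) if counts is None else np.asarray(counts, dtype=float)
    a = np.ceil(tstart).astype(int)  # first fully covered day index
    fb = np.minimum(np.floor(tstop), D).astype(int)  # one past last full day
    num = np.zeros(D)
    active = np.nonzero((c > 0) & (fb > a))[0]
    for i in active:
        ci = c[i]
        seg = H[i, a[i]:fb[i]]
        num[a[i]:fb[i]] += seg if ci == 1.0 else ci * seg

    den = np.zeros(D + 1)
    np.add.at(den, a[active], c[active])
    np.add.at(den, fb[active], -c[active])
    den = np.cumsum(den[:-1])
    cover = np.zeros(D + 1)
    np.add.at(cover, a[active], 1.0)
    np.add.at(cover, fb[active], -1.0)
    ell = (np.cumsum(cover[:-1]) > 0).astype(float)

    # partial days at interval ends (fractional entry / exit times)
    has_mass = c > 0
    d0 = np.floor(tstart).astype(int)
    w0 = np.minimum(tstop, d0 + 1.0) - tstart
    part0 = has_mass & (w0 > 0) & (w0 < 1) & (d0 < D)
    d1 = np.floor(tstop).astype(int)
    w1 = tstop - np.maximum(tstart, d1.astype(float))
    part1 = has_mass & (w1 > 0) & (d1 < D) & (d1 != d0)
    for dd, ww, sel in ((d0, w0, part0), (d1, w1, part1)):
        if np.any(sel):
            np.add.at(num, dd[sel], c[sel] * ww[sel] * H[sel, dd[sel]])
            np.add.at(den, dd[sel], c[sel] * ww[sel])
            np.maximum.at(ell, dd[sel], ww[sel])

    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where(den[:D] > 0, num / den[:D] * ell, 0.0)
    return inc


def population_cum_hazard_transition(
    ds: MultiStateDataset,
    rt: RateTable,
    h,
    grid: np.ndarray,
    trans: int = None,
    H: np.ndarray = None,
) -> HazardEstimate:
    """Population cumulative hazard for transitions departing state ``h``.

    ``h`` may be a state label or index of the original structure.  The
    daily accumulation is reported on ``grid`` by linear interpolation of
    the piecewise-linear daily trajectory.  ``H`` optionally supplies
    precomputed per-subject daily hazards (rows aligned with the risk-set
    records of state ``h``).
    """
    if isinstance(h, str):
        h = ds.structure.states.index(h)
    trans_from_h = ds.structure.trans_from(h)
    rows = ds.records.loc[ds.records["trans"] == trans_from_h[0]]
    tstart = rows["Tstart"].to_numpy(dtype=float)
    tstop = rows["Tstop"].to_numpy(dtype=float)
    grid = np.asarray(grid, dtype=float)
    n_days = int(np.ceil(tstop.max())) if tstop.size else 0
    n_days = max(n_days, int(np.ceil(grid.max())) if grid.size else 0)
    if H is None:
        if ds.profiles is None:
            raise ValueError("population split requires demographic profiles")
        prof = ds.profiles.set_index("subject_id")
        missing = [i for i in rows["id"] if i not in prof.index]
        if missing:
            raise ValueError(f"subjects at risk without a profile: {missing[:5]}")
        prof = prof.loc[rows["id"]]
        sex_idx = np.asarray([rt.sex_index(s) for s in prof["sex"]])
        H = subject_daily_hazards(
            rt,
            prof["age_days"].to_numpy(dtype=float),
            sex_idx,
            prof["entry_year"].to_numpy(dtype=float),
            n_days,
        )
    inc = _daily_pop_accumulation(H, tstart, tstop, n_days)
    knots = np.arange(n_days + 1, dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(inc)])
    on_grid = np.interp(grid, knots, cum)
    return HazardEstimate(
        trans, grid, on_grid, variance=np.zeros(grid.size), kind="population"
    )


def split_hazards(
    hazards: dict,
    ds: MultiStateDataset,
    rt: RateTable,
    smap: SplitMap,
    grid: np.ndarray = None,
) -> dict:
    """Extended hazard set: population/excess pair per split transition.

    ``hazards`` are the Nelson-Aalen estimates for the original structure
    (all on one grid, which must contain every event time of the split
    transitions).  Non-split transitions pass through under their new
    numbers.  The additivity ``Lambda_P + Lambda_E = Lambda`` holds exactly
    at every grid point by construction.  Excess estimates inherit the
    counting-process data (and hence the Greenwood variance) of their
    observed parent, following the convention that the population part is
    treated as fixed.
    """
    base = next(iter(hazards.values())).grid
    if grid is None:
        grid = base
    grid = np.asarray(grid, dtype=float)
    for m, est in hazards.items():
        if est.n_event is not None and m in smap.split_transitions:
            ev = est.grid[est.n_event > 0]
            if np.any(~np.isin(ev, grid)):
                raise ValueError(
                    f"grid is missing event times of split transition {m}"
                )

    out = {}
    pop_cache = {}
    for m, est in hazards.items():
        target = smap.trans_map[m]
        if isinstance(target, tuple):
            mp, me = target
            h = smap.original.transitions[m - 1][0]
            if h not in pop_cache:
                pop_cache[h] = population_cum_hazard_transition(
                    ds, rt, h, grid, trans=mp
                )
            pop = replace(pop_cache[h], trans=mp)
            obs_cum = np.interp(grid, est.grid, est.cum_hazard) if not np.array_equal(
                grid, est.grid
            ) else est.cum_hazard
            dN = est.n_event
            Y = est.n_risk
            if not np.array_equal(grid, est.grid):
                dN = np.zeros(grid.size)
                Y = np.zeros(grid.size)
                pos = np.searchsorted(grid, est.grid[est.n_event > 0])
                dN[pos] = est.n_event[est.n_event > 0]
                Y[pos] = est.n_risk[est.n_event > 0]
            out[mp] = pop
            out[me] = HazardEstimate(
                me,
                grid,
                obs_cum - pop.cum_hazard,
                variance=est.variance,
                kind="excess",
                n_event=dN,
                n_risk=Y,
            )
        else:
            new = replace(est, trans=target)
            if not np.array_equal(grid, est.grid):
                dN = np.zeros(grid.size)
                Y = np.zeros(grid.size)
                pos = np.searchsorted(grid, est.grid[est.n_event > 0])
                dN[pos] = est.n_event[est.n_event > 0]
                Y[pos] = est.n_risk[est.n_event > 0]
                new = replace(
                    new,
                    grid=grid,
                    cum_hazard=np.interp(grid, est.grid, est.cum_hazard),
                    variance=None
                    if est.variance is None
                    else np.interp(grid, est.grid, est.variance),
                    n_event=dN,
                    n_risk=Y,
                )
            out[target] = new
    return out


def extended_probtrans(
    ext_hazards: dict, smap: SplitMap, s: float = 0.0, variance: bool = False
) -> TransitionProbabilities:
    """Aalen-Johansen over the extended (split) state space.

    The product integral of the extended increment matrix yields
    P_hj,P(s, t) and P_hj,E(s, t) for each split transition; their sum
    reproduces the unsplit P_hj exactly.  With ``variance=True`` the
    recursive Greenwood entry variances are attached (population-kind
    transitions treated as fixed).
    """
    if variance:
        return greenwood_var_probtrans(ext_hazards, smap.extended, s)
    return aalen_johansen(ext_hazards, smap.extended, s)


def clamp_excess(est: HazardEstimate) -> HazardEstimate:
    """Optional post-hoc floor of a cumulative excess hazard at zero.

    Negative excess estimates signal a cohort outliving its reference
    population and deserve caution rather than silent truncation, so this
    is never applied by default; the number of clamped grid points is
    logged.
    """
    neg = est.cum_hazard < 0
    if np.any(neg):
        logger.info(
            "clamped %d negative cumulative excess hazard values (trans %s)",
            int(neg.sum()),
            est.trans,
        )
    return replace(est, cum_hazard=np.maximum(est.cum_hazard, 0.0))
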