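"""Non-parametric Markov multi-state estimation.

Long-format event data (one row per subject x transition at risk) feed
counting processes N_hj and at-risk processes Y_h, from which cumulative
transition hazards are estimated by Nelson-Aalen, their variances by
Greenwood, and transition probability matrices P(s, t) by the
Aalen-Johansen product integral

    P(s, t) = prod_{u in (s, t]} (I + dLambda(u)),

with diagonal increments dLambda_hh = -sum_{j != h} dLambda_hj.

Conventions: clock-forward time (all times since study entry); risk
intervals are open-closed ``(Tstart, Tstop]`` so delayed entry excludes a
subject at their entry time and an event keeps them in the risk set at the
event time; between an event and a censoring at the same time, the event
is counted first.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TransitionStructure",
    "MultiStateDataset",
    "RiskSetSeries",
    "HazardEstimate",
    "TransitionProbabilities",
    "validate_msdata",
    "risk_and_counting",
    "nelson_aalen",
    "greenwood_var_hazard",
    "aalen_johansen",
    "greenwood_var_probtrans",
    "read_msdata",
    "write_estimates",
]

RECORD_COLUMNS = ["id", "trans", "Tstart", "Tstop", "status"]


@dataclass(frozen=True)
class TransitionStructure:
    """States and numbered transitions of a multi-state model.

    ``transitions[m]`` is the 0-based ``(from, to)`` state-index pair of
    transition number ``m + 1`` (numbering is dense, 1..M, as in the long
    data format).  Absorbing states have no outgoing transition.
    """

    states: tuple
    transitions: tuple
    absorbing: tuple = None

    def __post_init__(self):
        K = len(self.states)
        for h, j in self.transitions:
            if h == j or not (0 <= h < K and 0 <= j < K):
                raise ValueError(f"invalid transition ({h}, {j})")
        has_out = {h for h, _ in self.transitions}
        if self.absorbing is None:
            object.__setattr__(
                self, "absorbing", tuple(k not in has_out for k in range(K))
            )
        else:
            for k, absb in enumerate(self.absorbing):
                if absb and k in has_out:
                    raise ValueError(
                        f"absorbing state {self.states[k]!r} has an outgoing transition"
                    )

    @classmethod
    def from_labels(cls, states, transitions):
        """Build from state labels and (from_label, to_label) pairs."""
        idx = {s: k for k, s in enumerate(states)}
        pairs = tuple((idx[a], idx[b]) for a, b in transitions)
        return cls(tuple(states), pairs)

    @property
    def n_states(self):
        return len(self.states)

    @property
    def n_trans(self):
        return len(self.transitions)

    def trans_from(self, h: int):
        """Transition numbers (1-based) departing state index ``h``."""
        return [m + 1 for m, (a, _) in enumerate(self.transitions) if a == h]

    def to_json(self) -> str:
        return json.dumps(
            {
                "states": list(self.states),
                "transitions": [
                    [self.states[h], self.states[j]] for h, j in self.transitions
                ],
                "absorbing": [s for s, a in zip(self.states, self.absorbing) if a],
            }
        )

    @classmethod
    def from_json(cls, text: str):
        obj = json.loads(text)
        return cls.from_labels(obj["states"], [tuple(t) for t in obj["transitions"]])


@dataclass
class MultiStateDataset:
    """Long-format event records plus a transition structure.

    ``records`` has columns id, trans, Tstart, Tstop, status.  ``profiles``
    (needed only when population tables come into play) has columns
    subject_id, age_days, sex, entry_year (decimal calendar year).
    """

    structure: TransitionStructure
    records: pd.DataFrame
    profiles: pd.DataFrame = None

    def __post_init__(self):
        missing = [c for c in RECORD_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"records missing columns {missing}")

    @property
    def n_subjects(self):
        return self.records["id"].nunique()


@dataclass(frozen=True)
class RiskSetSeries:
    """Event times with dN(u) and Y(u-) for one transition."""

    trans: int
    times: np.ndarray
    n_event: np.ndarray
    n_risk: np.ndarray


@dataclass
class HazardEstimate:
    """Cumulative transition hazard on a time grid.

    ``kind`` is ``observed`` (Nelson-Aalen), ``population`` (ratetable
    weighted mean) or ``excess`` (difference; may decrease).  For kinds
    with counting-process data, ``n_event``/``n_risk`` aligned with the
    grid drive the Greenwood machinery.
    """

    trans: int
    grid: np.ndarray
    cum_hazard: np.ndarray
    variance: np.ndarray = None
    kind: str = "observed"
    n_event: np.ndarray = None
    n_risk: np.ndarray = None

    def increments(self) -> np.ndarray:
        return np.diff(self.cum_hazard, prepend=0.0)


@dataclass
class TransitionProbabilities:
    """Time-indexed K x K matrices P(s, t) (with optional entry variances)."""

    s: float
    grid: np.ndarray
    matrices: np.ndarray
    structure: TransitionStructure
    variance: np.ndarray = None

    def at(self, t: float) -> np.ndarray:
        """P(s, t) with the step convention (last grid point <= t)."""
        k = np.searchsorted(self.grid, t, side="right") - 1
        if k < 0:
            raise ValueError(f"t={t} precedes s={self.s}")
        return self.matrices[k]


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_msdata(ds: MultiStateDataset) -> list:
    """Report invariant violations (empty list means the dataset is clean)."""
    out = []
    rec = ds.records
    M = ds.structure.n_trans
    bad_trans = rec.loc[~rec["trans"].isin(range(1, M + 1))]
    for _, r in bad_trans.iterrows():
        out.append(f"subject {r['id']}: unknown transition {r['trans']}")
    bad_time = rec.loc[~(rec["Tstart"] < rec["Tstop"])]
    for _, r in bad_time.iterrows():
        out.append(
            f"subject {r['id']} trans {r['trans']}: Tstart {r['Tstart']} "
            f"not before Tstop {r['Tstop']}"
        )
    from_state = rec["trans"].map(
        {m + 1: h for m, (h, _) in enumerate(ds.structure.transitions)}
    )
    grp = rec.assign(from_state=from_state).groupby(["id", "from_state"])
    events = grp["status"].sum()
    for (sid, h), k in events[events > 1].items():
        out.append(
            f"subject {sid}: {int(k)} events out of state "
            f"{ds.structure.states[int(h)]!r} (at most one allowed)"
        )
    spans = grp.agg(a=("Tstart", "nunique"), b=("Tstop", "nunique"))
    for (sid, h), row in spans[(spans["a"] > 1) | (spans["b"] > 1)].iterrows():
        out.append(
            f"subject {sid}: records departing state "
            f"{ds.structure.states[int(h)]!r} disagree on (Tstart, Tstop)"
        )
    if ds.profiles is not None:
        known = set(ds.profiles["subject_id"])
        for sid in sorted(set(rec["id"]) - known, key=str):
            out.append(f"subject {sid}: no demographic profile")
    return out


# ---------------------------------------------------------------------------
# Counting processes and Nelson-Aalen
# ---------------------------------------------------------------------------

def _risk_at(tstart: np.ndarray, tstop: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Y(u) = #{i : Tstart_i < u <= Tstop_i} for each u in ``times``."""
    return np.searchsorted(np.sort(tstart), times, side="left") - np.searchsorted(
        np.sort(tstop), times, side="left"
    )


def risk_and_counting(ds: MultiStateDataset, trans: int) -> RiskSetSeries:
    """Event times, event counts and risk-set sizes for one transition."""
    if not 1 <= trans <= ds.structure.n_trans:
        raise ValueError(f"unknown transition {trans}")
    h = ds.structure.transitions[trans - 1][0]
    same_state = ds.structure.trans_from(h)
    # the risk set of state h is shared by all transitions departing h
    rows = ds.records.loc[ds.records["trans"] == same_state[0]]
    own = ds.records.loc[(ds.records["trans"] == trans) & (ds.records["status"] == 1)]
    times, counts = np.unique(own["Tstop"].to_numpy(dtype=float), return_counts=True)
    n_risk = _risk_at(
        rows["Tstart"].to_numpy(dtype=float), rows["Tstop"].to_numpy(dtype=float), times
    )
    return RiskSetSeries(trans, times, counts, n_risk)


def nelson_aalen(
    ds: MultiStateDataset, extra_times=None, with_variance: bool = True
) -> dict:
    """Nelson-Aalen cumulative hazards for every transition.

    All estimates share one grid: the pooled distinct event times of all
    transitions (plus any ``extra_times``, e.g. reporting times); each
    estimate is a right-continuous step function, constant between its own
    event times.

    Returns ``{trans: HazardEstimate}``.
    """
    series = {m: risk_and_counting(ds, m) for m in range(1, ds.structure.n_trans + 1)}
    pooled = np.concatenate(
        [rs.times for rs in series.values()]
        + ([np.asarray(extra_times, dtype=float)] if extra_times is not None else [])
    )
    grid = np.unique(pooled) if pooled.size else np.asarray([], dtype=float)
    out = {}
    for m, rs in series.items():
        dN = np.zeros(grid.size)
        Y = np.zeros(grid.size)
        pos = np.searchsorted(grid, rs.times)
        dN[pos] = rs.n_event
        Y[pos] = rs.n_risk
        with np.errstate(divide="ignore", invalid="ignore"):
            inc = np.where(dN > 0, dN / Y, 0.0)
        var = np.cumsum(_greenwood_increments(dN, Y)) if with_variance else None
        out[m] = HazardEstimate(
            m, grid, np.cumsum(inc), var, "observed", n_event=dN, n_risk=Y
        )
    return out


def _greenwood_increments(dN: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Per-time Greenwood variance increments dN / (Y (Y - dN)).

    When the whole risk set fails (Y == dN) the Greenwood increment is
    undefined; the Aalen-form limit 1/Y is substituted with a warning.
    """
    inc = np.zeros_like(dN, dtype=float)
    ev = dN > 0
    degen = ev & (Y == dN)
    if np.any(degen):
        warnings.warn(
            "risk set exhausted at an event time; using Aalen-form variance "
            "increment 1/Y there",
            stacklevel=3,
        )
        inc[degen] = 1.0 / Y[degen]
    ok = ev & ~degen
    inc[ok] = dN[ok] / (Y[ok] * (Y[ok] - dN[ok]))
    return inc


def greenwood_var_hazard(rs: RiskSetSeries) -> np.ndarray:
    """Cumulative Greenwood variance of the Nelson-Aalen estimate."""
    return np.cumsum(_greenwood_increments(rs.n_event, rs.n_risk))


# ---------------------------------------------------------------------------
# Aalen-Johansen and its Greenwood covariance recursion
# ---------------------------------------------------------------------------

def _increment_matrices(hazards: dict, structure: TransitionStructure, grid):
    """Stack of dLambda(u) matrices (with the diagonal filled in)."""
    G, K = grid.size, structure.n_states
    dA = np.zeros((G, K, K))
    for m, est in hazards.items():
        if not np.array_equal(est.grid, grid):
            raise ValueError("all hazard estimates must share one grid")
        h, j = structure.transitions[m - 1]
        dA[:, h, j] += est.increments()
    idx = np.arange(K)
    dA[:, idx, idx] = -dA.sum(axis=2)
    return dA


def aalen_johansen(
    hazards: dict, structure: TransitionStructure, s: float = 0.0
) -> TransitionProbabilities:
    """Product-integral transition probabilities P(s, t).

    ``hazards`` maps transition number to a :class:`HazardEstimate`; all
    must share one grid.  The output grid starts with ``s`` itself
    (``P(s, s) = I``) followed by the grid points above ``s``, matrices
    multiplied in increasing time order.
    """
    base = next(iter(hazards.values())).grid
    dA = _increment_matrices(hazards, structure, base)
    keep = base > s
    out_grid = np.concatenate([[s], base[keep]])
    K = structure.n_states
    mats = np.empty((out_grid.size, K, K))
    mats[0] = np.eye(K)
    P = np.eye(K)
    diag = np.arange(K)
    for k, inc in enumerate(dA[keep], start=1):
        if np.any(1.0 + inc[diag, diag] < -1.0):
            raise ValueError("pathological hazard increment: 1 + dLambda_hh < -1")
        P = P @ (np.eye(K) + inc)
        mats[k] = P
    return TransitionProbabilities(s, out_grid, mats, structure)


def _increment_cov(hazards: dict, structure: TransitionStructure, grid):
    """Cov(vec dLambda(u)) per grid point, Greenwood plug-in form.

    Only transitions carrying counting-process data (``n_event`` set)
    contribute; population-kind transitions are treated as fixed (zero
    variance, zero covariance).  For transitions j, j' departing the same
    state h at a time with risk set Y and events dN_j:

        var(dA_hj)        = dN_j (Y - dN_j) / Y^3
        cov(dA_hj, dA_hj') = -dN_j dN_j' / Y^3

    and the diagonal entry dA_hh = -sum_j dA_hj follows by linearity.
    """
    G, K = grid.size, structure.n_states
    S = np.zeros((G, K * K, K * K))
    by_state = {}
    for m, est in hazards.items():
        if est.n_event is None:
            continue
        h, j = structure.transitions[m - 1]
        by_state.setdefault(h, []).append((j, est))
    for h, members in by_state.items():
        cols = [j for j, _ in members]
        dN = np.stack([e.n_event for _, e in members])  # (J, G)
        Y = np.max(np.stack([e.n_risk for _, e in members]), axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            c = -dN[:, None, :] * dN[None, :, :] / Y**3  # (J, J, G)
            J = len(members)
            jj = np.arange(J)
            c[jj, jj] = dN * np.where(Y > dN, Y - dN, 0.0) / Y**3
        c = np.nan_to_num(c)
        # scatter the h-row block, including the diagonal column/row
        col_idx = np.asarray(cols)
        rows = h * K + col_idx
        S[:, rows[:, None], rows[None, :]] += np.moveaxis(c, 2, 0)
        hh = h * K + h
        row_sum = c.sum(axis=0)  # (J, G): sum over j' of cov(j', j)
        S[:, hh, rows] -= np.moveaxis(row_sum, 1, 0)
        S[:, rows, hh] -= np.moveaxis(row_sum, 1, 0)
        S[:, hh, hh] += c.sum(axis=(0, 1))
    return S


def greenwood_var_probtrans(
    hazards: dict, structure: TransitionStructure, s: float = 0.0
) -> TransitionProbabilities:
    """Aalen-Johansen estimate with recursive Greenwood entry variances.

    Propagates the covariance of vec(P(s, t)) through the product
    integral: with M_u = I + dLambda(u),

        C_u = (I (x) M_u^T) C_{u-} (I (x) M_u^T)^T + J_P S_u J_P^T,

    where S_u is the Greenwood covariance of the hazard increments and
    J_P maps d vec(dLambda) to d vec(P dLambda).  Population-kind
    transitions contribute nothing to S_u.
    """
    base = next(iter(hazards.values())).grid
    dA = _increment_matrices(hazards, structure, base)
    S = _increment_cov(hazards, structure, base)
    keep = base > s
    out_grid = np.concatenate([[s], base[keep]])
    K = structure.n_states
    mats = np.empty((out_grid.size, K, K))
    var = np.zeros((out_grid.size, K, K))
    P = np.eye(K)
    C = np.zeros((K * K, K * K))
    mats[0] = P
    eyeK = np.eye(K)
    for k, (inc, Sk) in enumerate(zip(dA[keep], S[keep]), start=1):
        M = eyeK + inc
        J1 = np.kron(eyeK, M.T)
        # J2[(h,j), (l,j)] = P[h, l]
        J2 = np.einsum("hl,jm->hjlm", P, eyeK).reshape(K * K, K * K)
        C = J1 @ C @ J1.T + J2 @ Sk @ J2.T
        P = P @ M
        mats[k] = P
        var[k] = np.diag(C).reshape(K, K)
    return TransitionProbabilities(s, out_grid, mats, structure, variance=var)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_msdata(path, structure: TransitionStructure, profiles_path=None):
    """Read long-format multi-state CSV (id, trans, Tstart, Tstop, status)."""
    rec = pd.read_csv(path)
    profiles = None
    if profiles_path is not None:
        profiles = pd.read_csv(profiles_path)
        if "entry_date" in profiles.columns and "entry_year" not in profiles.columns:
            from .ratetable import date_to_decimal_year

            profiles["entry_year"] = profiles["entry_date"].map(date_to_decimal_year)
    return MultiStateDataset(structure, rec[RECORD_COLUMNS + [
        c for c in rec.columns if c not in RECORD_COLUMNS
    ]], profiles)


def write_estimates(hazards: dict, path, cause: dict = None) -> None:
    """Export hazard estimates as tidy CSV (trans, cause, time, Haz, var)."""
    frames = []
    for m, est in hazards.items():
        frames.append(
            pd.DataFrame(
                {
                    "trans": m,
                    "cause": (cause or {}).get(m, {"observed": "total"}.get(est.kind, est.kind)),
                    "time": est.grid,
                    "Haz": est.cum_hazard,
                    "var": est.variance if est.variance is not None else np.nan,
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False)
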