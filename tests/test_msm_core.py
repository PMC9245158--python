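import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter, NelsonAalenFitter

from msrelsurv import (
    MultiStateDataset,
    TransitionStructure,
    aalen_johansen,
    greenwood_var_hazard,
    greenwood_var_probtrans,
    nelson_aalen,
    risk_and_counting,
    validate_msdata,
)

from conftest import surv_dataset


def competing_dataset():
    """3 states, 2 transitions from state 1; events at distinct times."""
    structure = TransitionStructure.from_labels(
        ("alive", "causeA", "causeB"), [("alive", "causeA"), ("alive", "causeB")]
    )
    rec = pd.DataFrame(
        {
            "id": [0, 0, 1, 1, 2, 2, 3, 3],
            "trans": [1, 2, 1, 2, 1, 2, 1, 2],
            "Tstart": 0.0,
            "Tstop": [1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 3.0, 3.0],
            "status": [1, 0, 0, 1, 0, 0, 0, 0],
        }
    )
    return MultiStateDataset(structure, rec)


class TestValidate:
    def test_clean_dataset(self, toy_surv):
        assert validate_msdata(toy_surv) == []

    def test_zero_length_interval(self):
        ds = surv_dataset([1.0, 2.0], [1, 1])
        ds.records.loc[0, "Tstart"] = 1.0
        out = validate_msdata(ds)
        assert len(out) == 1 and "Tstart" in out[0]

    def test_double_event_from_one_state(self):
        ds = competing_dataset()
        ds.records.loc[1, "status"] = 1  # subject 0 exits via both causes
        out = validate_msdata(ds)
        assert len(out) == 1 and "at most one" in out[0]


class TestRiskAndCounting:
    def test_enumeration(self, toy_surv):
        rs = risk_and_counting(toy_surv, 1)
        assert rs.times.tolist() == [1.0, 2.0]
        assert rs.n_risk.tolist() == [3, 2]
        assert rs.n_event.tolist() == [1, 1]

    def test_delayed_entry_excluded(self):
        ds = surv_dataset([4.0, 6.0], [1, 1], tstart=[0.0, 5.0])
        rs = risk_and_counting(ds, 1)
        assert rs.times.tolist() == [4.0, 6.0]
        assert rs.n_risk.tolist() == [1, 1]  # late entrant not at risk at u=4

    def test_tied_events_aggregate(self):
        ds = surv_dataset([2.0, 2.0, 5.0, 5.0], [1, 1, 0, 0])
        rs = risk_and_counting(ds, 1)
        assert rs.times.tolist() == [2.0]
        assert rs.n_event.tolist() == [2]
        assert rs.n_risk.tolist() == [4]

    def test_event_censoring_tie_keeps_censored_at_risk(self):
        ds = surv_dataset([2.0, 2.0], [1, 0])
        rs = risk_and_counting(ds, 1)
        assert rs.n_risk.tolist() == [2]


class TestNelsonAalen:
    def test_hand_value(self, toy_surv):
        est = nelson_aalen(toy_surv)[1]
        assert est.cum_hazard[-1] == pytest.approx(1 / 3 + 1 / 2, abs=1e-12)

    def test_no_events_is_zero(self):
        ds = surv_dataset([1.0, 2.0], [0, 0])
        est = nelson_aalen(ds)[1]
        assert est.grid.size == 0

    def test_tie_increment(self):
        ds = surv_dataset([2.0, 2.0, 5.0, 5.0], [1, 1, 0, 0])
        est = nelson_aalen(ds)[1]
        assert est.cum_hazard[0] == pytest.approx(0.5)

    def test_matches_lifelines(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(5, 60)
        c = rng.uniform(0, 8, 60)
        obs = np.minimum(t, c)
        status = (t <= c).astype(int)
        ds = surv_dataset(obs, status)
        est = nelson_aalen(ds)[1]
        naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
        naf.fit(obs, status)
        ours = pd.Series(est.cum_hazard, index=est.grid)
        theirs = naf.cumulative_hazard_.iloc[:, 0]
        for tt in est.grid[np.array(est.n_event) > 0]:
            assert ours[tt] == pytest.approx(theirs[tt], abs=1e-12)

    def test_invariant_to_subject_order_and_record_splitting(self, toy_surv):
        base = nelson_aalen(toy_surv)[1]
        shuffled = MultiStateDataset(
            toy_surv.structure,
            toy_surv.records.sample(frac=1, random_state=1).reset_index(drop=True),
        )
        assert np.allclose(nelson_aalen(shuffled)[1].cum_hazard, base.cum_hazard)
        # split subject 2's record at the non-event time 1.5
        rec = toy_surv.records.copy()
        rec = pd.concat(
            [
                rec[rec["id"] != 2],
                pd.DataFrame(
                    {
                        "id": [2, 2],
                        "trans": 1,
                        "Tstart": [0.0, 1.5],
                        "Tstop": [1.5, 3.0],
                        "status": [0, 0],
                    }
                ),
            ],
            ignore_index=True,
        )
        split = nelson_aalen(MultiStateDataset(toy_surv.structure, rec))[1]
        assert np.allclose(split.cum_hazard, base.cum_hazard, atol=1e-12)


class TestGreenwoodHazard:
    def test_hand_value(self, toy_surv):
        rs = risk_and_counting(toy_surv, 1)
        var = greenwood_var_hazard(rs)
        assert var[-1] == pytest.approx(1 / 6 + 1 / 2, abs=1e-12)

    def test_nondecreasing(self):
        rng = np.random.default_rng(3)
        ds = surv_dataset(rng.exponential(2, 50), rng.integers(0, 2, 50))
        est = nelson_aalen(ds)[1]
        if est.variance is not None and est.variance.size:
            assert np.all(np.diff(est.variance) >= 0)

    def test_exhausted_risk_set_falls_back_with_warning(self):
        ds = surv_dataset([1.0], [1])
        rs = risk_and_counting(ds, 1)
        with pytest.warns(UserWarning, match="exhausted"):
            var = greenwood_var_hazard(rs)
        assert var[0] == 1.0  # Aalen form 1/Y with Y=1


class TestAalenJohansen:
    def test_pure_survival_equals_kaplan_meier(self, toy_surv):
        haz = nelson_aalen(toy_surv)
        probs = aalen_johansen(haz, toy_surv.structure, 0.0)
        assert probs.at(2.0)[0, 0] == pytest.approx((1 - 1 / 3) * (1 - 1 / 2))
        kmf = KaplanMeierFitter().fit([1, 2, 3], [1, 1, 0])
        assert probs.at(2.0)[0, 0] == pytest.approx(
            kmf.survival_function_.loc[2.0].iloc[0], abs=1e-12
        )

    def test_zero_hazards_identity(self):
        ds = surv_dataset([1.0, 2.0], [0, 0])
        # no events: empty grid; P(s,t) = I for all t
        haz = nelson_aalen(ds, extra_times=[1.0, 2.0])
        probs = aalen_johansen(haz, ds.structure, 0.0)
        assert np.allclose(probs.at(2.0), np.eye(2))

    def test_competing_risks_brute_force_oracle(self):
        ds = competing_dataset()
        haz = nelson_aalen(ds)
        probs = aalen_johansen(haz, ds.structure, 0.0)
        # oracle: explicit increments, dN/Y by hand: t=1 Y=4 cause A;
        # t=2 Y=3 cause B
        def inc(dA1, dA2):
            m = np.eye(3)
            m[0, 1], m[0, 2] = dA1, dA2
            m[0, 0] = 1 - dA1 - dA2
            return m

        oracle = inc(1 / 4, 0) @ inc(0, 1 / 3)
        assert np.allclose(probs.at(2.0), oracle, atol=1e-12)

    def test_row_sums_one(self, small_cohort):
        _, cohort = small_cohort
        haz = nelson_aalen(cohort.dataset)
        probs = aalen_johansen(haz, cohort.dataset.structure, 0.0)
        assert np.allclose(probs.matrices.sum(axis=2), 1.0, atol=1e-10)

    def test_conditioning_time_shifts_the_product(self, toy_surv):
        haz = nelson_aalen(toy_surv)
        probs = aalen_johansen(haz, toy_surv.structure, 1.0)
        assert probs.at(1.0)[0, 0] == 1.0  # P(s, s) = I
        assert probs.at(2.0)[0, 0] == pytest.approx(1 - 1 / 2)


class TestGreenwoodProbtrans:
    def test_pure_survival_matches_km_greenwood(self, toy_surv):
        haz = nelson_aalen(toy_surv)
        probs = greenwood_var_probtrans(haz, toy_surv.structure, 0.0)
        s = (1 - 1 / 3) * (1 - 1 / 2)
        gw = s**2 * (1 / 6 + 1 / 2)
        k = np.searchsorted(probs.grid, 2.0, side="right") - 1
        assert probs.variance[k][0, 0] == pytest.approx(gw, abs=1e-12)

    def test_zero_hazards_zero_variance(self):
        ds = surv_dataset([1.0, 2.0], [0, 0])
        haz = nelson_aalen(ds, extra_times=[2.0])
        probs = greenwood_var_probtrans(haz, ds.structure, 0.0)
        assert np.allclose(probs.variance, 0.0)

    def test_matches_lifelines_km_variance(self):
        rng = np.random.default_rng(11)
        t = rng.exponential(5, 80)
        c = rng.uniform(0, 8, 80)
        obs, status = np.minimum(t, c), (t <= c).astype(int)
        ds = surv_dataset(obs, status)
        probs = greenwood_var_probtrans(nelson_aalen(ds), ds.structure, 0.0)
        kmf = KaplanMeierFitter().fit(obs, status)
        # lifelines' Greenwood variance via its CI is awkward; compare to the
        # classical formula S^2 * sum dN/(Y(Y-dN)) computed from our counts
        est = nelson_aalen(ds)[1]
        ev = (est.n_event > 0) & (est.n_risk > est.n_event)  # classical form only
        gw_inc = est.n_event[ev] / (est.n_risk[ev] * (est.n_risk[ev] - est.n_event[ev]))
        S = np.cumprod(1 - est.n_event[ev] / est.n_risk[ev])
        var_cls = S**2 * np.cumsum(gw_inc)
        times = est.grid[ev]
        for tt, v in zip(times, var_cls):
            k = np.searchsorted(probs.grid, tt, side="right") - 1
            assert probs.variance[k][0, 0] == pytest.approx(v, rel=1e-10)
        # and the KM point estimates agree with lifelines exactly
        for tt in times:
            k = np.searchsorted(probs.grid, tt, side="right") - 1
            assert probs.matrices[k][0, 0] == pytest.approx(
                kmf.survival_function_.loc[tt].iloc[0], abs=1e-12
            )
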