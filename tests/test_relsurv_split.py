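import numpy as np
import pandas as pd
import pytest

from msrelsurv import (
    MultiStateDataset,
    TransitionStructure,
    aalen_johansen,
    clamp_excess,
    extend_structure,
    extended_probtrans,
    nelson_aalen,
    population_cum_hazard_transition,
    split_hazards,
)
from msrelsurv._constants import DAYS_PER_YEAR
from msrelsurv.simulator import illness_death_structure

from conftest import flat_ratetable


def _profiles(ids, sexes, age_years=40.0, year=1995.0):
    return pd.DataFrame(
        {
            "subject_id": ids,
            "age_days": age_years * DAYS_PER_YEAR,
            "sex": sexes,
            "entry_year": year,
        }
    )


class TestExtendStructure:
    def test_illness_death_extension(self):
        smap = extend_structure(illness_death_structure(), ["NRM", "DaR"])
        assert smap.extended.states == ("ARF", "Relapse", "NRM.p", "NRM.e",
                                        "DaR.p", "DaR.e")
        assert smap.extended.n_trans == 5
        assert smap.trans_map == {1: 1, 2: (2, 3), 3: (4, 5)}
        assert all(smap.extended.absorbing[2:])

    def test_no_death_states_is_identity(self):
        s = illness_death_structure()
        smap = extend_structure(s, [])
        assert smap.extended.states == s.states
        assert smap.trans_map == {1: 1, 2: 2, 3: 3}

    def test_two_death_states_counts(self):
        s = TransitionStructure.from_labels(
            ("a", "d1", "d2"), [("a", "d1"), ("a", "d2")]
        )
        smap = extend_structure(s, ["d1", "d2"])
        assert smap.extended.n_states == 5
        assert smap.extended.n_trans == 4

    def test_non_absorbing_death_state_rejected(self):
        s = TransitionStructure.from_labels(
            ("a", "b", "c"), [("a", "b"), ("b", "c")]
        )
        with pytest.raises(ValueError, match="not absorbing"):
            extend_structure(s, ["b"])


def one_state_dataset(tstart, tstop, status, ids=None):
    s = TransitionStructure.from_labels(("alive", "dead"), [("alive", "dead")])
    n = len(tstop)
    rec = pd.DataFrame(
        {
            "id": ids if ids is not None else np.arange(n),
            "trans": 1,
            "Tstart": np.asarray(tstart, float),
            "Tstop": np.asarray(tstop, float),
            "status": np.asarray(status, int),
        }
    )
    return MultiStateDataset(s, rec)


class TestPopulationHazard:
    def test_identical_hazards_cancel_weights(self):
        rt = flat_ratetable(0.001)
        ds = one_state_dataset([0, 0, 0], [30, 80, 100], [0, 0, 0])
        ds.profiles = _profiles(range(3), ["female", "male", "female"])
        est = population_cum_hazard_transition(ds, rt, "alive", np.array([50.0, 100.0]))
        assert est.cum_hazard == pytest.approx([0.05, 0.1], abs=1e-12)

    def test_zero_ratetable(self):
        rt = flat_ratetable(0.0)
        ds = one_state_dataset([0], [100], [0])
        ds.profiles = _profiles([0], ["male"])
        est = population_cum_hazard_transition(ds, rt, "alive", np.array([100.0]))
        assert est.cum_hazard[0] == 0.0

    def test_two_subject_weighted_hand_sum(self):
        """0.001 and 0.003/day at risk 10 days together, then 0.003 alone:
        10 * 0.002 + 10 * 0.003 = 0.05."""
        rt = flat_ratetable(None, sex_values=(0.001, 0.003))
        ds = one_state_dataset([0, 0], [10, 20], [0, 0])
        ds.profiles = _profiles([0, 1], ["female", "male"])
        est = population_cum_hazard_transition(ds, rt, "alive", np.array([20.0]))
        assert est.cum_hazard[0] == pytest.approx(0.05, abs=1e-12)

    def test_left_truncated_interval(self):
        rt = flat_ratetable(0.001)
        ds = one_state_dataset([5.0], [15.0], [0])
        ds.profiles = _profiles([0], ["male"])
        est = population_cum_hazard_transition(
            ds, rt, "alive", np.array([5.0, 15.0, 20.0])
        )
        assert est.cum_hazard == pytest.approx([0.0, 0.01, 0.01], abs=1e-12)

    def test_fractional_interval_weights(self):
        rt = flat_ratetable(0.001)
        ds = one_state_dataset([2.25], [7.5], [0])
        ds.profiles = _profiles([0], ["male"])
        est = population_cum_hazard_transition(ds, rt, "alive", np.array([10.0]))
        assert est.cum_hazard[0] == pytest.approx(0.001 * (7.5 - 2.25), abs=1e-12)

    def test_missing_profile_is_error(self):
        rt = flat_ratetable(0.001)
        ds = one_state_dataset([0, 0], [10, 20], [0, 0])
        ds.profiles = _profiles([0], ["male"])
        with pytest.raises(ValueError, match="without a profile"):
            population_cum_hazard_transition(ds, rt, "alive", np.array([10.0]))


@pytest.fixture(scope="module")
def fitted(small_cohort):
    cfg, cohort = small_cohort
    smap = extend_structure(illness_death_structure(), ["NRM", "DaR"])
    eval_days = np.array([1, 2, 5, 10.0]) * DAYS_PER_YEAR
    haz = nelson_aalen(cohort.dataset, extra_times=eval_days)
    ext = split_hazards(haz, cohort.dataset, cfg.ratetable, smap)
    return cfg, cohort, smap, haz, ext


class TestSplitHazards:
    def test_additivity_exact(self, fitted):
        _, _, smap, haz, ext = fitted
        for m, target in smap.split_transitions.items():
            mp, me = target
            total = ext[mp].cum_hazard + ext[me].cum_hazard
            assert np.allclose(total, haz[m].cum_hazard, atol=1e-12)

    def test_zero_ratetable_reduces_to_nelson_aalen(self, small_cohort):
        _, cohort = small_cohort
        rt0 = flat_ratetable(0.0)
        smap = extend_structure(illness_death_structure(), ["NRM", "DaR"])
        haz = nelson_aalen(cohort.dataset)
        ext = split_hazards(haz, cohort.dataset, rt0, smap)
        for m, (mp, me) in smap.split_transitions.items():
            assert np.all(ext[mp].cum_hazard == 0)
            assert np.allclose(ext[me].cum_hazard, haz[m].cum_hazard, atol=1e-15)

    def test_negative_excess_kept_and_clampable(self):
        rt = flat_ratetable(0.002)
        s = illness_death_structure()
        smap = extend_structure(s, ["NRM", "DaR"])
        # one subject, never dies: observed hazard 0, population > 0
        rec = pd.DataFrame(
            {
                "id": [0, 0],
                "trans": [1, 2],
                "Tstart": 0.0,
                "Tstop": 200.0,
                "status": 0,
            }
        )
        ds = MultiStateDataset(s, rec, _profiles([0], ["male"]))
        haz = nelson_aalen(ds, extra_times=[100.0, 200.0])
        ext = split_hazards(haz, ds, rt, smap)
        excess = ext[3]
        assert excess.cum_hazard[-1] == pytest.approx(-0.4)
        clamped = clamp_excess(excess)
        assert np.all(clamped.cum_hazard >= 0)

    def test_grid_must_contain_split_event_times(self, fitted):
        cfg, cohort, smap, haz, _ = fitted
        bad_grid = np.array([1.0, 2.0])  # drops the event times
        with pytest.raises(ValueError, match="missing event times"):
            split_hazards(haz, cohort.dataset, cfg.ratetable, smap, grid=bad_grid)


class TestExtendedProbtrans:
    def test_split_sum_reproduces_unsplit_model(self, fitted):
        _, cohort, smap, haz, ext = fitted
        probs = extended_probtrans(ext, smap, 0.0)
        un = aalen_johansen(haz, cohort.dataset.structure, 0.0)
        assert np.array_equal(probs.grid, un.grid)
        # P(ARF -> NRM.p) + P(ARF -> NRM.e) == P(ARF -> NRM), etc.
        for (h_o, j_o), (h_e, jp, je) in (((0, 2), (0, 2, 3)), ((0, 3), (0, 4, 5)),
                                          ((1, 3), (1, 4, 5))):
            merged = probs.matrices[:, h_e, jp] + probs.matrices[:, h_e, je]
            assert np.allclose(merged, un.matrices[:, h_o, j_o], atol=1e-10)
        assert np.allclose(probs.matrices[:, 0, 0], un.matrices[:, 0, 0], atol=1e-10)
        assert np.allclose(probs.matrices.sum(axis=2), 1.0, atol=1e-10)

    def test_zero_ratetable_population_states_empty(self, small_cohort):
        _, cohort = small_cohort
        rt0 = flat_ratetable(0.0)
        smap = extend_structure(illness_death_structure(), ["NRM", "DaR"])
        haz = nelson_aalen(cohort.dataset)
        ext = split_hazards(haz, cohort.dataset, rt0, smap)
        probs = extended_probtrans(ext, smap, 0.0)
        assert np.all(probs.matrices[:, 0, 2] == 0)  # ARF -> NRM.p
        assert np.all(probs.matrices[:, 0, 4] == 0)  # ARF -> DaR.p
        assert np.all(probs.matrices[:, 1, 4] == 0)  # Relapse -> DaR.p

    def test_four_event_toy_brute_force(self):
        """All entries match an explicit product of extended increment
        matrices built by hand on a 4-event toy with a constant table."""
        lam = 0.001
        rt = flat_ratetable(lam)
        s = illness_death_structure()
        smap = extend_structure(s, ["NRM", "DaR"])
        # subjects: 0 relapses at 10 then dies at 30; 1 dies (NRM) at 20;
        # 2 censored at 40
        rec = pd.DataFrame(
            {
                "id": [0, 0, 0, 1, 1, 2, 2],
                "trans": [1, 2, 3, 1, 2, 1, 2],
                "Tstart": [0, 0, 10, 0, 0, 0, 0],
                "Tstop": [10, 10, 30, 20, 20, 40, 40],
                "status": [1, 0, 1, 0, 1, 0, 0],
            }
        )
        ds = MultiStateDataset(
            s, rec, _profiles([0, 1, 2], ["male", "male", "male"])
        )
        haz = nelson_aalen(ds, extra_times=[40.0])
        ext = split_hazards(haz, ds, rt, smap)
        probs = extended_probtrans(ext, smap, 0.0)

        def mat(d):
            m = np.eye(6)
            m[0, 1], m[0, 2], m[0, 3] = d[0], d[1], d[2]
            m[1, 4], m[1, 5] = d[3], d[4]
            m[0, 0] = 1 - d[0] - d[1] - d[2]
            m[1, 1] = 1 - d[3] - d[4]
            return m

        # grid: 10 (relapse, Y=3), 20 (NRM death, Y=2), 30 (DaR, Y=1), 40
        # population parts: ARF risk set gives lam per day while anyone at
        # risk; relapse state occupied over (10, 30]
        p1 = 10 * lam  # ARF population mass lumped at t=10
        expect = (
            mat([1 / 3, p1, -p1, 0, 0])
            @ mat([0, 10 * lam, 1 / 2 - 10 * lam, 10 * lam, -10 * lam])
            @ mat([0, 10 * lam, -10 * lam, 10 * lam, 1 - 10 * lam])
            @ mat([0, 10 * lam, -10 * lam, 0, 0])
        )
        assert np.allclose(probs.at(40.0), expect, atol=1e-12)
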