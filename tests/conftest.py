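import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from msrelsurv import (
    DemographicProfile,
    MultiStateDataset,
    RateTable,
    TransitionStructure,
    make_gompertz_ratetable,
)
from msrelsurv.simulator import illness_death_structure, make_scenario, simulate_cohort

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

N_AGES, N_YEARS = 111, 31
YEARS = (1985, 2015)


def flat_ratetable(value_per_day: float, sex_values=None) -> RateTable:
    """Ratetable with a constant daily hazard (optionally per sex)."""
    haz = np.zeros((N_AGES, N_YEARS, 2))
    if sex_values is None:
        haz[:] = value_per_day
    else:
        haz[..., 0] = sex_values[0]
        haz[..., 1] = sex_values[1]
    return RateTable(np.arange(N_AGES), np.arange(YEARS[0], YEARS[1] + 1),
                     ("female", "male"), haz)


@pytest.fixture(scope="session")
def zero_rt():
    return flat_ratetable(0.0)


@pytest.fixture(scope="session")
def const_rt():
    return flat_ratetable(0.001)


@pytest.fixture(scope="session")
def gompertz_rt():
    return make_gompertz_ratetable()


@pytest.fixture
def profile():
    return DemographicProfile("s1", 40 * 365.241, "female", 1995.5)


@pytest.fixture(scope="session")
def surv_structure():
    return TransitionStructure.from_labels(("alive", "dead"), [("alive", "dead")])


def surv_dataset(times, status, structure=None, tstart=None):
    """Pure-survival dataset: one transition alive -> dead."""
    structure = structure or TransitionStructure.from_labels(
        ("alive", "dead"), [("alive", "dead")]
    )
    n = len(times)
    rec = pd.DataFrame(
        {
            "id": np.arange(n),
            "trans": 1,
            "Tstart": np.zeros(n) if tstart is None else np.asarray(tstart, float),
            "Tstop": np.asarray(times, dtype=float),
            "status": np.asarray(status, dtype=int),
        }
    )
    return MultiStateDataset(structure, rec)


@pytest.fixture
def toy_surv():
    """3 subjects, events at t=1 (Y=3) and t=2 (Y=2), censoring at 3."""
    return surv_dataset([1.0, 2.0, 3.0], [1, 1, 0])


@pytest.fixture(scope="session")
def small_cohort():
    """exp.small cohort, n=250, light censoring, for identity/oracle checks."""
    cfg = make_scenario("exp.small", calibrated=False)
    cfg.censoring_rate = 0.04
    return cfg, simulate_cohort(cfg, 250, seed=42)
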