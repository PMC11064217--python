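import numpy as np
import pytest

from paleotp.datamodel import CoreProfile, LakeCatchment, TimeSeries
from paleotp.synthetic import Scenario, make_cores, make_monitoring, make_tp_history


@pytest.fixture
def lake() -> LakeCatchment:
    return LakeCatchment(
        lake_area_m2=0.154e6, mean_depth_m=6.3, max_depth_m=9.3,
        catchment_area_m2=4.6e6, q_s=2.79,
    )


@pytest.fixture
def simple_core() -> CoreProfile:
    return CoreProfile(
        core_id="T1", collection_year=2018.0,
        depth_cm=np.array([0.5, 1.5, 2.5, 3.5]),
        age_ce=np.array([2015.0, 2005.0, 1995.0, 1985.0]),
        p_conc=np.array([2.0, 1.8, 1.5, 1.4]),
        mar=np.array([0.05, 0.05, 0.05, 0.05]),
    )


@pytest.fixture
def constant_tp() -> TimeSeries:
    t = np.arange(2003.0, 2018.0, 0.25)
    return TimeSeries("monitored TP", t, np.full(len(t), 100.0))


@pytest.fixture(scope="session")
def default_scenario() -> Scenario:
    return Scenario(seed=42)


@pytest.fixture(scope="session")
def default_world(default_scenario):
    """Default synthetic world: (scenario, truth TP, cores, truth, monitoring)."""
    tp = make_tp_history(default_scenario)
    cores, truth = make_cores(tp, default_scenario)
    mon = make_monitoring(tp, default_scenario)
    return default_scenario, tp, cores, truth, mon
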