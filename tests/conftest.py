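import pytest

from dietval import benchmark_report as br
from dietval import cohort_io
from dietval import dlw_engine as de
from dietval import synthetic_cohort as sc


@pytest.fixture(scope="session")
def sim_config():
    return sc.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def study(sim_config):
    return sc.simulate_study(sim_config)


@pytest.fixture(scope="session")
def dlw_results(study, sim_config):
    weights = {p.id: p.weight_start_kg for p in study.participants}
    cfg = de.DLWConfig(rq=sim_config.rq)
    return [de.run_two_point(r, weights[r.participant_id], cfg)
            for r in study.isotopes]


@pytest.fixture(scope="session")
def bundle(study, dlw_results):
    return br.bundle_from_inputs(study.participants, study.occasions,
                                 study.recalls, dlw_results)


@pytest.fixture(scope="session")
def benchmark(bundle):
    return br.run_benchmark(bundle, cohort_io.StudyConfig(seed=1))
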