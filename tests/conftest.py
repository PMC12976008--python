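import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_db():
    """A modest simulated database with one planted signal, analysed once."""
    from pvsignals import (
        DrugDictionary, assemble_cases, deduplicate, select_primary_suspect,
    )
    from pvsignals.simulate import PlantedSignal, SimConfig, generate

    cfg = SimConfig(
        n_cases=4000, seed=11,
        planted_signals=(PlantedSignal("DRUG_00", "event_20", 10.0),),
        rate_overrides={"event_20": 0.01},
    )
    res = generate(cfg)
    demos = deduplicate(res.demos)
    cases = assemble_cases(demos, res.drugs, res.reactions, res.outcomes,
                           res.indications, res.therapies)
    dictionary = DrugDictionary(frozenset([cfg.study_drug]))
    cohort, comparator = select_primary_suspect(cases, dictionary)
    return {"config": cfg, "result": res, "cases": cases,
            "cohort": cohort, "comparator": comparator,
            "dictionary": dictionary}


@pytest.fixture(scope="session")
def start_prior():
    from pvsignals.disprop import DEFAULT_MGPS_START, MgpsHyperParams

    return MgpsHyperParams(*DEFAULT_MGPS_START)
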