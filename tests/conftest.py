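import numpy as np
import pytest

import trastupk as tp


@pytest.fixture(scope="session")
def pp():
    return tp.PopulationParameters()


@pytest.fixture(scope="session")
def spec(pp):
    return tp.RandomEffectSpec.from_parameters(pp, rng_seed=42)


@pytest.fixture(scope="session")
def typical_bc(pp):
    return tp.subject_from_covariates(tp.TYPICAL_BC, pp)


@pytest.fixture(scope="session")
def typical_agc(pp):
    return tp.subject_from_covariates(tp.TYPICAL_AGC, pp)


@pytest.fixture(scope="session")
def small_dataset(pp, spec):
    """12 subjects, rich sampling, default pooled-study structure."""
    design = tp.StudyDesign(n_subjects=12, seed=3)
    data, truth, n_blq = tp.generate_dataset(design, pp, spec)
    return data, truth


@pytest.fixture(scope="session")
def typical_q3w_profile(typical_bc):
    sched = tp.build_schedule(tp.Q3W, 66.0)
    return tp.simulate_subject(typical_bc, sched, 252.0,
                               interval_for_troughs=21.0)
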