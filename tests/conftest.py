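import numpy as np
import pytest

from omtscore import pipeline, synthetic
from omtscore.evaluation import CVPlan, run_internal_cv
from omtscore.model import ModelConfig


@pytest.fixture(scope="session")
def sim_params():
    """Default study conditions: 60 slides, strong planted signal."""
    return synthetic.SimulationParams(n_slides=60, seed=11)


@pytest.fixture(scope="session")
def cohort60(sim_params):
    """In-memory synthetic cohort (cohort table + per-slide mask/nuclei)."""
    return synthetic.simulate_cohort(sim_params)


@pytest.fixture(scope="session")
def features60(cohort60):
    """Per-slide tile feature tables for the 60-slide cohort."""
    cohort, data = cohort60
    return {
        sid: pipeline.extract_slide_features(mask, nuclei, sid)
        for sid, (mask, nuclei) in data.items()
    }


@pytest.fixture(scope="session")
def feature_matrices(features60):
    return {sid: pipeline.feature_matrix(t) for sid, t in features60.items()}


@pytest.fixture(scope="session")
def cv_result(cohort60, feature_matrices):
    """Single-repeat grouped 5-fold CV of the IDaRS MLP on the cohort."""
    cohort, _ = cohort60
    cfg = ModelConfig(seed=5)
    plan = CVPlan(n_folds=5, n_repeats=1, seeds=(0,))
    return run_internal_cv(feature_matrices, cohort, cfg, plan)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
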