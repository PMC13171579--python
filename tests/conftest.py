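import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", message=".*[Cc]onverge.*")


@pytest.fixture(scope="session")
def small_design():
    """Two-ROI, single-subject design used by the signal-level tests."""
    from dbslfp.design import make_design

    return make_design(
        {
            "subjects": 1,
            "datasets_per_subject": 1,
            "trials_per_condition": 30,
            "channels_per_roi": 2,
            "rois": ("lOFC", "rOFC"),
        }
    )


@pytest.fixture(scope="session")
def null_session(small_design):
    """Clean null recording: no planted effects, no random intercepts."""
    from dbslfp.synth import plant_effects, synthesize_session

    effects, _ = plant_effects(
        small_design, "null", sd_trial=0.0, sd_channel=0.0, sd_residual=0.0
    )
    return synthesize_session(small_design, effects, "S01", "d0", seed=11)


@pytest.fixture(scope="session")
def null_power(null_session):
    """Power table + edge scores of the clean null recording."""
    from dbslfp.preprocess import preprocess_session
    from dbslfp.spectral import build_power_table

    epochs = preprocess_session(null_session)
    return build_power_table(epochs, return_edge_scores=True)


@pytest.fixture(scope="session")
def artifact_run(small_design, null_session):
    """Null recording contaminated with strong edge artifacts + its screen inputs."""
    from dbslfp.preprocess import preprocess_session
    from dbslfp.spectral import build_power_table
    from dbslfp.synth import inject_edge_artifacts

    session, labels = inject_edge_artifacts(null_session, fraction=0.2, amplitude=8.0, seed=4)
    table, scores = build_power_table(preprocess_session(session), return_edge_scores=True)
    true_ids = {f"S01/d0/e{i}" for i in labels}
    return table, scores, true_ids


@pytest.fixture(scope="session")
def default_design():
    """The full study design: 3 subjects, 10 trials/condition, 2 contacts/ROI."""
    from dbslfp.design import make_design

    return make_design({"subjects": 3, "trials_per_condition": 10, "channels_per_roi": 2})


@pytest.fixture(scope="session")
def mixed_tables(default_design):
    """Model-level mixed-scenario power table plus planted truth."""
    from dbslfp.synth import plant_effects, simulate_power_table

    effects, truth = plant_effects(default_design, "mixed")
    table = simulate_power_table(default_design, effects, seed=0)
    return table, effects, truth
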