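import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cvnprog.cohort_io import Cohort, OmicsMatrix, RiskLabel, SurvivalRecord, TimeFrame
from cvnprog.synthetic import SimulationConfig, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_cohort() -> Cohort:
    """Eight patients, three features; a hand-checkable block structure.

    Feature f1 separates the classes perfectly (high patients up, low down);
    f2 is noise; f3 is constant-ish.
    """
    pids = [f"P{i}" for i in range(8)]
    values = pd.DataFrame(
        {
            "f1": [5.0, 6.0, 7.0, 8.0, 1.0, 2.0, 3.0, 4.0],
            "f2": [1.0, 9.0, 2.0, 8.0, 3.0, 7.0, 4.0, 6.0],
            "f3": [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 2.0],
        },
        index=pids,
    )
    survival = [
        SurvivalRecord(p, 10.0 if i < 4 else 80.0, i < 4) for i, p in enumerate(pids)
    ]
    labels = {p: (RiskLabel.HIGH if i < 4 else RiskLabel.LOW) for i, p in enumerate(pids)}
    return Cohort(
        matrix=OmicsMatrix(values=values),
        survival=survival,
        labels=labels,
        frame=TimeFrame(3),
    )


@pytest.fixture(scope="session")
def planted_cohort():
    """Medium synthetic cohort with a strongly planted 5-feature signature."""
    config = SimulationConfig(
        n_patients=120, n_features=400, signature_size=5, effect_size=3.0, seed=7
    )
    cohort, signature = generate_cohort(config)
    return cohort, signature, config
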