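import numpy as np
import pytest

from subtypebench import (
    LayerSpec,
    SurvivalTable,
    SyntheticSpec,
    generate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """30-sample, 3-subtype cohort with two small layers; strong signal."""
    spec = SyntheticSpec(
        n_samples=30,
        n_subtypes=3,
        layer_specs=(
            LayerSpec("mrna", 40, separation=5.0),
            LayerSpec("methylation", 30, separation=5.0),
        ),
        survival_hazards=(0.02, 0.08, 0.2),
        seed=7,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_survival(small_cohort):
    surv = small_cohort.survival
    return SurvivalTable(
        sample_ids=surv["sample"].tolist(),
        time=surv["time"].to_numpy(),
        event=surv["event"].to_numpy(),
    )
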