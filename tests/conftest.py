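import numpy as np
import pytest

from symfuse import (
    SimulationConfig,
    SymptomGuidedFusion,
    generate_joint_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture(scope="session")
def fitted_fusion():
    """One moderately-noisy synthetic dataset and its fitted fusion model.

    Session-scoped: several test modules inspect the same fit.
    """
    cfg = SimulationConfig(seed=7, ref_loading_corr=0.6)
    (x1, x2), truth = generate_joint_dataset(cfg)
    model = SymptomGuidedFusion([x1, x2], truth.reference,
                                n_components=8, lambda_ref=0.5, seed=7)
    with np.errstate(all="ignore"):
        results = model.fit()
    return (x1, x2), truth, results
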