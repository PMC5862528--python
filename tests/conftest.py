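import numpy as np
import pytest
from hypothesis import settings

import discquant as dq

settings.register_profile("suite", max_examples=25, deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ph505_params():
    return dq.make_condition_preset("ph505")


@pytest.fixture(scope="session")
def trained_classifier(ph505_params):
    """Voxel classifier trained on 5 ground-truth-labelled tumor phantoms."""
    training = []
    for i in range(5):
        stack, gt = dq.simulate_disc(ph505_params, 1001 + i)
        training.append((dq.compute_voxel_features(stack), dq.ground_truth_labels(gt)))
    return dq.train_voxel_classifier(training, seed=0)


@pytest.fixture(scope="session")
def phantom42(ph505_params):
    """One fixed tumor phantom shared across read-only tests."""
    return dq.simulate_disc(ph505_params, 42)


@pytest.fixture(scope="session")
def recovery_measurements(trained_classifier):
    """Mean tumor-volume percent per preset over 30 phantoms each.

    The protocol mirrors the study: train once on 5 labelled tumor discs,
    then apply the frozen classifier to an independent test set per
    condition. Shared between the parameter-recovery and cohort-statistics
    acceptance tests.
    """
    config = dq.QuantConfig(measure_ph3=False)
    out = {}
    for preset in ("ph505", "ph505_kniKD", "ph505_rescue", "ph505_ato"):
        params = dq.make_condition_preset(preset)
        percents = []
        for i in range(30):
            stack, _ = dq.simulate_disc(params, 20_000 + i)
            meas = dq.measure_disc(stack, trained_classifier, config)
            percents.append(meas.tumor_volume_percent)
        out[preset] = np.asarray(percents)
    return out
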