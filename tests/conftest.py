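"""Shared fixtures.

The expensive artifacts (the 2e4-sample phantom datasets and the
networks trained on them) are session-scoped and shared between the
module tests and the acceptance suite so each is built exactly once.
"""

from dataclasses import replace

import numpy as np
import pytest

from cestquant.ann import NetworkSpec, TrainingConfig, train_network
from cestquant.datagen import generate_training_set, phantom_preset

# problem sizes for the shared artifacts: large enough for the stochastic
# regression targets, small enough to keep the suite fast
N_TRAIN = 20_000
MAX_EPOCHS = 2000


@pytest.fixture(scope="session")
def phantom_ts():
    """Phantom-preset dataset, fixed B1 (the reference training set)."""
    return generate_training_set(phantom_preset(n_samples=N_TRAIN, seed=101))


@pytest.fixture(scope="session")
def phantom_ts_b1var():
    """Same phantom conditions but with B1 sampled 0.5-0.7 uT."""
    cfg = phantom_preset(n_samples=N_TRAIN, seed=102)
    cfg = replace(cfg, ranges=replace(cfg.ranges, b1_ut=(0.5, 0.7)))
    return generate_training_set(cfg)


@pytest.fixture(scope="session")
def phantom_net(phantom_ts):
    """Reference 7x10 network trained on the fixed-B1 phantom dataset."""
    net, report = train_network(
        phantom_ts, NetworkSpec(7, 10), TrainingConfig(seed=7, max_epochs=MAX_EPOCHS)
    )
    return net, report


@pytest.fixture(scope="session")
def phantom_net_b1var(phantom_ts_b1var):
    net, report = train_network(
        phantom_ts_b1var, NetworkSpec(7, 10), TrainingConfig(seed=7, max_epochs=MAX_EPOCHS)
    )
    return net, report


@pytest.fixture(scope="session")
def invivo_net():
    """In-vivo (muscle) network at reduced n: labels include B1."""
    from cestquant.datagen import invivo_preset

    ts = generate_training_set(invivo_preset(n_samples=8000, seed=103))
    net, report = train_network(
        ts, NetworkSpec(7, 10), TrainingConfig(seed=7, max_epochs=1500)
    )
    return net, report


@pytest.fixture(scope="session")
def invivo_net_fixed_field():
    """In-vivo conditions but trained WITHOUT B0/B1 variation."""
    from cestquant.datagen import invivo_preset

    cfg = invivo_preset(n_samples=8000, seed=104)
    cfg = replace(
        cfg, ranges=replace(cfg.ranges, b0_ppm=(0.0, 0.0), b1_ut=(0.6, 0.6))
    )
    ts = generate_training_set(cfg)
    net, report = train_network(
        ts, NetworkSpec(7, 10), TrainingConfig(seed=7, max_epochs=1500)
    )
    return net, report
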