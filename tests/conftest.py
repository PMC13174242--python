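import numpy as np
import pandas as pd
import pytest

from mechanonps import (
    DeviceGeometry,
    TrainingConfig,
    build_feature_table,
    default_population_spec,
    simulate_population,
    train,
)
from mechanonps.mechanoage import _subset
from mechanonps.synthetic_data import AcquisitionSpec


@pytest.fixture(scope="session")
def geometry():
    return DeviceGeometry()


@pytest.fixture(scope="session")
def noiseless_acq():
    return AcquisitionSpec(noise_sigma=0.0)


def make_labelled_cells(n_per_class=500, seed=11):
    """Separable younger/older populations with donor metadata attached."""
    young = simulate_population(default_population_spec("younger", n_per_class,
                                                        seed=seed))
    old = simulate_population(default_population_spec("older", n_per_class,
                                                      seed=seed + 1))
    young["donor_id"], young["age"] = "Y0", 30.0
    old["donor_id"], old["age"] = "O0", 60.0
    return pd.concat([young, old], ignore_index=True)


@pytest.fixture(scope="session")
def separable_features():
    """Ten-feature matrix for 1000 well-separated synthetic cells."""
    return build_feature_table(make_labelled_cells(500, seed=11))


@pytest.fixture(scope="session")
def split_indices(separable_features):
    rng = np.random.default_rng(0)
    idx = rng.permutation(separable_features.n_cells)
    return idx[:700], idx[700:]


@pytest.fixture(scope="session")
def trained_bundle(separable_features, split_indices):
    tr_idx, _ = split_indices
    return train(_subset(separable_features, tr_idx), TrainingConfig.fast(1))
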