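import numpy as np
import pytest

import thymoflow as tf

#: Balanced composition: every population well represented so each gate and
#: its evaluation have comfortable support.
BALANCED_FREQUENCIES = {
    "cTEC": 0.02, "mTEC": 0.02, "FB": 0.02, "EC": 0.02, "LEC": 0.01,
    "DC": 0.02, "MP": 0.02, "B": 0.02, "other": 0.05,
    "thymocyte_immature": 0.50, "thymocyte_CD4SP": 0.20, "thymocyte_CD8SP": 0.10,
}


@pytest.fixture(scope="session")
def balanced_frequencies():
    return dict(BALANCED_FREQUENCIES)


@pytest.fixture(scope="session")
def gated_sample():
    """A 100k-event sample at default separation with its auto-fit gating."""
    spec = tf.build_sample_spec(BALANCED_FREQUENCIES, 100_000, seed=42)
    table, labels = tf.simulate_sample(spec)
    transformed = tf.transform_events(table)
    assignment, stats = tf.apply_gating(transformed, tf.build_thymic_gating_tree())
    return table, transformed, labels, assignment, stats


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
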