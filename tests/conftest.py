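import numpy as np
import pandas as pd
import pytest

from splicerail import (
    PredictorConfig,
    SyntheticConfig,
    build_probe_table,
    generate_dataset,
)


@pytest.fixture(scope="session")
def strong_signal_dataset():
    """27 participants, 50 genes, strong MAL effect at biomarker probes."""
    return generate_dataset(SyntheticConfig(seed=11, effect_beta=2.0, noise_sd=0.5))


@pytest.fixture(scope="session")
def null_dataset():
    """Same layout with no MAL dependence anywhere."""
    return generate_dataset(SyntheticConfig(seed=12, effect_beta=0.0))


@pytest.fixture(scope="session")
def strong_signal_table(strong_signal_dataset):
    table, _ = build_probe_table(
        strong_signal_dataset.raw_intensities, strong_signal_dataset.annotation
    )
    return table


@pytest.fixture(scope="session")
def strong_signal_mal(strong_signal_dataset):
    return strong_signal_dataset.cohort.set_index("participant_id")["mal"]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_predictor_cfg():
    return PredictorConfig(n_repetitions=200, seed=5)
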