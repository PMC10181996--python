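import numpy as np
import pytest

from cuffbp.synthetic import SynthConfig, generate_feature_table


@pytest.fixture(scope="session")
def cohort_126():
    """The default ICU-style cohort: 126 rows, 31 subjects, 2 mmHg label noise."""
    dataset, truth = generate_feature_table(SynthConfig.compromised_cohort(seed=11))
    return dataset, truth


@pytest.fixture(scope="session")
def small_table():
    """A small, quick table for protocol and estimator tests."""
    config = SynthConfig.compromised_cohort(
        seed=7, n_subjects=8, total_records=24
    )
    dataset, truth = generate_feature_table(config)
    return dataset, truth


@pytest.fixture(scope="session")
def strong_coupling():
    """Low-noise table with the log-transformed driving-term design, in which
    the diastolic label is almost exactly linear in the features."""
    config = SynthConfig(
        n_subjects=120, records_per_subject=1, total_records=None,
        noise_sd_bp=0.5, seed=42,
    )
    dataset, _ = generate_feature_table(config, include_log_features=True)
    cols = ["log_pep", "log_pir", "log_ptt", "log_womersley"]
    return dataset.frame[cols].to_numpy(), dataset.frame["dbp_mmhg"].to_numpy()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
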