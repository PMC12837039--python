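import pytest

from crcua.parameters import default_model_config, load_parameters


@pytest.fixture(scope="session")
def params():
    """The shipped parameter mapping."""
    return load_parameters()


@pytest.fixture(scope="session")
def base_config():
    """The base-case model configuration under the calibrated variant."""
    return default_model_config()


@pytest.fixture(scope="session")
def published(params):
    """Published base-case results used as reference points."""
    return params["published_results"]


@pytest.fixture(scope="session")
def calibration_targets(published):
    """Unrounded per-patient totals: the cohort table divided by 747."""
    from crcua.cua import CalibrationTargets

    pub = published["detected_cohort_totals"]
    n = pub["n_detected"]
    return CalibrationTargets(
        cost_with=pub["cost_with"] / n,
        qaly_with=pub["qaly_with"] / n,
        cost_without=pub["cost_without"] / n,
        qaly_without=pub["qaly_without"] / n,
    )
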