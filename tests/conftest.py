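import pytest

from pregquit.outcomes import classify_cohort
from pregquit.simulate import generate_cohort, trial_like_config


@pytest.fixture(scope="session")
def trial_cohort():
    """One trial-like cohort (571/569), reused across tests."""
    return generate_cohort(trial_like_config(seed=2018))


@pytest.fixture(scope="session")
def trial_calls(trial_cohort):
    return classify_cohort(trial_cohort)
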