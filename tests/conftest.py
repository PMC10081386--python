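import numpy as np
import pytest

from vrcfc import pipeline


@pytest.fixture(scope="session")
def tuned_session():
    """One processed post-shock (freeze-tuned) session."""
    return pipeline.run_session("post_shock_shocked", seed=7)


@pytest.fixture(scope="session")
def untuned_session():
    """One processed pre-shock (untuned) session."""
    return pipeline.run_session("pre_shock", seed=11)


@pytest.fixture(scope="session")
def shock_day_session():
    """One processed day-0 session with the six-shock schedule."""
    return pipeline.run_session("shock_day", seed=5)


@pytest.fixture(scope="session")
def encoded_tuned(tuned_session):
    """Encoding-model fit on the tuned session."""
    return pipeline.encode_session(tuned_session)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
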