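import numpy as np
import pytest

from rodribbon.presets import get_preset


@pytest.fixture(scope="session")
def wt():
    return get_preset("wt")


@pytest.fixture(scope="session")
def ko():
    return get_preset("ko")


@pytest.fixture(scope="session")
def wt_step_bundle():
    """Noise-free wt 10 mM EGTA step series (the core experiment)."""
    from rodribbon.synth import synthesize_step_series
    return synthesize_step_series("wt", 10.0, durations_ms=(0.5, 1, 3, 9))


@pytest.fixture(scope="session")
def wt_step_analysis(wt_step_bundle):
    from rodribbon.analysis import analyze_step_series
    return analyze_step_series(wt_step_bundle)


@pytest.fixture(scope="session")
def wt_iv_bundle():
    from rodribbon.synth import synthesize_iv_series
    return synthesize_iv_series("wt", 10.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
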