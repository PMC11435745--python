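import hypothesis
import pytest

import fishres as fr

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=100, deadline=None
)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def consumption():
    return fr.load_consumption_table()


@pytest.fixture(scope="session")
def lufenuron_summary():
    """The study's single finding: one 10 ng/g lufenuron detection among 20
    eel tests, eel-matrix LOQ 5 ng/g."""
    return fr.DetectionSummary(
        pesticide="lufenuron", species="eel", n_tests=20, detections=(10.0,), loq=5.0
    )


@pytest.fixture(scope="session")
def lufenuron_tox():
    return fr.ToxRef(pesticide="lufenuron", adi=0.015, body_weight=60.0)
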