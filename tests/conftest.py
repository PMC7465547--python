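import pytest

from crctriage import build_validation_fixture


@pytest.fixture(scope="session")
def validation_cohort():
    """The deterministic 281-record confirmed-CRC validation cohort."""
    return build_validation_fixture()
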