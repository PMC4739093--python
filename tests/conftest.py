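from datetime import date

import pytest

from fgmc import group_counts_2013, load_profiles

REFERENCE_DATE = date(2013, 1, 1)


@pytest.fixture(scope="session")
def profiles():
    return load_profiles()


@pytest.fixture(scope="session")
def published_counts():
    return group_counts_2013()
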