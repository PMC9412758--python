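import pytest

from fhhkit import FHHEntry, default_lexicon


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture
def worked_entry():
    """The canonical worked example: coded CANCER/AUNT corrected by the comment."""
    return FHHEntry(
        patient_id="P1",
        entry_id="E1",
        condition_code="CANCER",
        relative_code="AUNT",
        onset_age=None,
        comment="Breast, great-aunt, dx at age of 52",
    )
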