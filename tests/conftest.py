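import pytest

from allelemeta import load_rs966221_table, study_effects


@pytest.fixture(scope="session")
def fixture_table():
    """The packaged 14-study rs966221 / ischemic-stroke table."""
    return load_rs966221_table()


@pytest.fixture(scope="session")
def fixture_estimates(fixture_table):
    return study_effects(fixture_table.records)


@pytest.fixture(scope="session")
def region_estimates(fixture_table):
    """Per-region effect estimates (multi-region study excluded)."""

    def _get(region):
        return study_effects([r for r in fixture_table.records if r.region == region])

    return _get
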