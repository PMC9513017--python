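import pytest

from foodscape import MatcherConfig, load_rules
from foodscape.data_model import OutletRecord, Source


@pytest.fixture(scope="session")
def rules():
    return load_rules()


@pytest.fixture(scope="session")
def matcher_cfg():
    # load the lexicon once for the whole session
    return MatcherConfig()


def make_record(
    record_id="r1",
    source=Source.REGISTER,
    name="Netto",
    branch_code="DD.47.10.99",
    lat=55.68,
    lon=12.57,
    **kwargs,
):
    return OutletRecord(
        record_id=record_id,
        source=source,
        raw_name=name,
        branch_code=branch_code,
        latitude=lat,
        longitude=lon,
        **kwargs,
    )


@pytest.fixture
def record_factory():
    return make_record
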