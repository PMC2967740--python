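import pytest

from pgxcds.fixtures import table2_rules, warfarin_rule
from pgxcds.knowledge_engine import default_supporting_knowledge


@pytest.fixture()
def worked_catalog():
    return table2_rules()


@pytest.fixture()
def warfarin():
    return warfarin_rule()


@pytest.fixture(scope="session")
def sk_rules():
    return default_supporting_knowledge()
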