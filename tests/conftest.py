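import pytest

from dotcyto import import_document, parse_dot
from dotcyto.examples import FOUR_NODE_EXAMPLE, TOY_EXAMPLE


@pytest.fixture()
def toy_doc():
    return parse_dot(TOY_EXAMPLE)


@pytest.fixture()
def toy_result(toy_doc):
    return import_document(toy_doc)[0]


@pytest.fixture()
def four_node_result():
    return import_document(parse_dot(FOUR_NODE_EXAMPLE))[0]
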