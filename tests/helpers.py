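"""Shared assertions for round-trip model equivalence."""

from __future__ import annotations

import re

import pytest

from dotcyto.importer import ImportResult
from dotcyto.model import VisualPropertyKey as K, effective_value

#: Exported node ids carry a ``§SUID`` suffix; comparisons across an
#: export/import cycle strip it.
_SUID_SUFFIX = re.compile(r"(§\d+)+$")


def strip_suid(name: str) -> str:
    return _SUID_SUFFIX.sub("", name)


_NODE_EXACT = [
    K.NODE_LABEL,
    K.NODE_BORDER_PAINT,
    K.NODE_FILL_COLOR,
    K.NODE_SHAPE,
    K.NODE_LABEL_FONT_FACE,
    K.NODE_LABEL_FONT_COLOR,
    K.NODE_BORDER_LINE_TYPE,
    K.NODE_VISIBLE,
    K.NODE_TRANSPARENCY,
    K.NODE_TOOLTIP,
]
_NODE_SIZES = [K.NODE_WIDTH, K.NODE_HEIGHT, K.NODE_BORDER_WIDTH, K.NODE_LABEL_FONT_SIZE]
_NODE_POSITIONS = [K.NODE_X_POSITION, K.NODE_Y_POSITION]
_EDGE_EXACT = [
    K.EDGE_LABEL,
    K.EDGE_UNSELECTED_PAINT,
    K.EDGE_LABEL_FONT_FACE,
    K.EDGE_LABEL_FONT_COLOR,
    K.EDGE_LINE_TYPE,
    K.EDGE_VISIBLE,
    K.EDGE_TOOLTIP,
]
_EDGE_SIZES = [K.EDGE_WIDTH, K.EDGE_LABEL_FONT_SIZE]
_ARROWS = [K.EDGE_TARGET_ARROW_SHAPE, K.EDGE_SOURCE_ARROW_SHAPE]

POSITION_TOL = 1e-3  # points
SIZE_TOL = 1e-4  # points


def _node_effective(result: ImportResult) -> dict[str, dict]:
    out = {}
    for node in result.network.nodes:
        name = strip_suid(node.shared_name)
        assert name not in out, f"duplicate node name {name!r}"
        view = result.views.get(node.suid)
        out[name] = {
            key: effective_value(result.style, view, key)
            for key in list(K)
            if key.value.startswith("NODE_")
        }
    return out


def _edge_effective(result: ImportResult) -> dict[tuple[str, str], dict]:
    by_suid = {n.suid: strip_suid(n.shared_name) for n in result.network.nodes}
    out = {}
    for edge in result.network.edges:
        key = (by_suid[edge.source_suid], by_suid[edge.target_suid])
        assert key not in out, f"duplicate edge {key!r}"
        view = result.views.get(edge.suid)
        out[key] = {
            k: effective_value(result.style, view, k)
            for k in list(K)
            if k.value.startswith("EDGE_")
        }
    return out


def assert_model_equivalent(before: ImportResult, after: ImportResult) -> None:
    """Effective-value equivalence after an export/import cycle.

    Positions to 1e-3 pt, sizes to 1e-4 pt, colors and enumerated
    vocabularies exactly.  Arrow shapes are compared only on directed
    networks (undirected DOT edges cannot carry arrows), and the edge
    table's weight column is not compared (table data is lost on
    export by design).
    """
    assert after.network.name == before.network.name
    assert after.network.directed == before.network.directed
    assert effective_value(after.style, None, K.NETWORK_BACKGROUND_PAINT) == effective_value(
        before.style, None, K.NETWORK_BACKGROUND_PAINT
    )

    nodes_before, nodes_after = _node_effective(before), _node_effective(after)
    assert set(nodes_after) == set(nodes_before)
    for name, expected in nodes_before.items():
        got = nodes_after[name]
        for key in _NODE_EXACT:
            assert got[key] == expected[key], f"node {name!r}: {key.value}"
        for key in _NODE_SIZES:
            assert got[key] == pytest.approx(expected[key], abs=SIZE_TOL), f"node {name!r}: {key.value}"
        for key in _NODE_POSITIONS:
            assert got[key] == pytest.approx(expected[key], abs=POSITION_TOL), f"node {name!r}: {key.value}"

    edges_before, edges_after = _edge_effective(before), _edge_effective(after)
    assert set(edges_after) == set(edges_before)
    for pair, expected in edges_before.items():
        got = edges_after[pair]
        for key in _EDGE_EXACT:
            assert got[key] == expected[key], f"edge {pair!r}: {key.value}"
        for key in _EDGE_SIZES:
            assert got[key] == pytest.approx(expected[key], abs=SIZE_TOL), f"edge {pair!r}: {key.value}"
        if before.network.directed:
            for key in _ARROWS:
                assert got[key] == expected[key], f"edge {pair!r}: {key.value}"
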