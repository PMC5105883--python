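"""DOT grammar: parsing, serialization, default-attribute resolution."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dotcyto.dotlang import (
    DefaultStmt,
    DotEdgeStmt,
    DotHtmlError,
    DotNodeStmt,
    DotParseError,
    format_id,
    parse_dot,
    resolve_attrs,
    serialize_dot,
)
from dotcyto.examples import FOUR_NODE_EXAMPLE, TOY_EXAMPLE
from dotcyto.fixtures import FixtureSpec, generate_fixture


class TestParse:
    def test_toy_example_counts(self, toy_doc):
        """The laid-out sample file: one undirected graph, 4 nodes,
        5 edges, one node-default statement carrying the grey fill."""
        assert len(toy_doc.graphs) == 1
        g = toy_doc.graphs[0]
        assert g.name == "toy_example"
        assert not g.directed
        assert sorted(g.nodes) == ["1", "2", "3", "4"]
        assert len(g.edges()) == 5
        node_defaults = g.defaults("node")
        assert len(node_defaults) == 1
        assert node_defaults[0].attrs == {
            "fillcolor": "#888888",
            "label": "\\N",
            "style": "filled",
        }

    def test_four_node_example_counts(self):
        g = parse_dot(FOUR_NODE_EXAMPLE).graphs[0]
        assert len(g.nodes) == 4
        assert len(g.edges()) == 3
        assert g.graph_attrs["pad"] == "2"
        assert g.nodes["Node 1§64"].attrs["pos"] == "-243.000000,42.000000"

    def test_minimal_digraph(self):
        g = parse_dot("digraph g { a -> b }").graphs[0]
        assert g.directed
        assert sorted(g.nodes) == ["a", "b"]  # implicit creation
        edges = g.edges()
        assert len(edges) == 1
        assert (edges[0].source_id, edges[0].target_id) == ("a", "b")

    def test_html_label_rejected(self):
        with pytest.raises(DotHtmlError):
            parse_dot("graph g { a [label=<<b>x</b>>] }")

    def test_edge_operator_must_match_directedness(self):
        with pytest.raises(DotParseError):
            parse_dot("digraph g { a -- b }")
        with pytest.raises(DotParseError):
            parse_dot("graph g { a -> b }")

    def test_parse_error_carries_line_and_column(self):
        with pytest.raises(DotParseError) as exc:
            parse_dot("graph g {\n  a [x ]\n}")
        assert exc.value.line == 2

    def test_edge_chain_expands_pairwise(self):
        g = parse_dot("graph g { a -- b -- c [w=1] }").graphs[0]
        pairs = [(e.source_id, e.target_id) for e in g.edges()]
        assert pairs == [("a", "b"), ("b", "c")]
        assert all(e.attrs == {"w": "1"} for e in g.edges())

    def test_repeated_node_declaration_merges_last_wins(self):
        g = parse_dot("graph g { a [x=1, y=2]; a [y=3, z=4] }").graphs[0]
        assert len([s for s in g.statements if isinstance(s, DotNodeStmt)]) == 1
        assert g.nodes["a"].attrs == {"x": "1", "y": "3", "z": "4"}

    def test_comments_consumed(self):
        text = (
            "# preprocessor line\n"
            "graph g { // one\n"
            "  a /* inline */ [x=1]\n"
            "  /* multi\n     line */ b\n"
            "}\n"
        )
        g = parse_dot(text).graphs[0]
        assert sorted(g.nodes) == ["a", "b"]

    def test_ports_discarded_with_warning(self):
        doc = parse_dot("digraph g { a:n -> b:se }")
        g = doc.graphs[0]
        assert [(e.source_id, e.target_id) for e in g.edges()] == [("a", "b")]
        assert any("port" in w for w in doc.warnings)

    def test_strict_and_multiple_graphs_preserve_order(self):
        doc = parse_dot("strict graph a {}\ndigraph b {}")
        assert [g.name for g in doc.graphs] == ["a", "b"]
        assert doc.graphs[0].strict and not doc.graphs[1].strict

    def test_quoted_string_concatenation(self):
        g = parse_dot('graph g { a [label="foo" + "bar"] }').graphs[0]
        assert g.nodes["a"].attrs["label"] == "foobar"

    def test_subgraph_nodes_belong_to_graph(self):
        g = parse_dot("graph g { subgraph s { a; b } c }").graphs[0]
        assert sorted(g.nodes) == ["a", "b", "c"]

    def test_subgraph_edge_endpoint_expands(self):
        g = parse_dot("digraph g { {a; b} -> c }").graphs[0]
        pairs = {(e.source_id, e.target_id) for e in g.edges()}
        assert pairs == {("a", "c"), ("b", "c")}

    def test_escaped_quote_in_value(self):
        g = parse_dot(r'graph g { a [label="say \"hi\""] }').graphs[0]
        assert g.nodes["a"].attrs["label"] == 'say "hi"'

    def test_backslash_sequences_kept_verbatim(self):
        # \N must survive parsing: it means "the node name" downstream
        g = parse_dot(r'graph g { a [label="\N"] }').graphs[0]
        assert g.nodes["a"].attrs["label"] == "\\N"


class TestResolveAttrs:
    def test_toy_node_1_resolved(self, toy_doc):
        g = toy_doc.graphs[0]
        assert resolve_attrs(g, g.nodes["1"]) == {
            "fillcolor": "#888888",
            "label": "\\N",
            "style": "filled",
            "height": "0.5",
            "pos": "-58.648,-8.4777",
            "width": "0.75",
        }

    def test_no_applicable_defaults(self):
        g = parse_dot("graph g { a [x=1] }").graphs[0]
        assert resolve_attrs(g, g.nodes["a"]) == {"x": "1"}

    def test_subgraph_defaults_ignored(self):
        g = parse_dot("graph g { subgraph s { node [shape=box] } c }").graphs[0]
        assert resolve_attrs(g, g.nodes["c"]) == {}

    def test_defaults_after_element_do_not_apply(self):
        g = parse_dot("graph g { a; node [shape=box]; b }").graphs[0]
        assert resolve_attrs(g, g.nodes["a"]) == {}
        assert resolve_attrs(g, g.nodes["b"]) == {"shape": "box"}

    def test_later_defaults_override_earlier(self):
        g = parse_dot("graph g { node [shape=box]; node [shape=diamond]; a }").graphs[0]
        assert resolve_attrs(g, g.nodes["a"]) == {"shape": "diamond"}

    def test_edge_defaults_apply_to_edges(self):
        g = parse_dot("graph g { edge [penwidth=3]; a -- b [color=red] }").graphs[0]
        assert resolve_attrs(g, g.edges()[0]) == {"penwidth": "3", "color": "red"}


class TestSerialize:
    def test_empty_graph(self):
        doc = parse_dot("graph {}")
        assert serialize_dot(doc) == "graph {\n}\n"

    def test_id_quoting(self):
        assert format_id("Node 1§64") == '"Node 1§64"'
        assert format_id("plain_id") == "plain_id"
        assert format_id("-3.5") == "-3.5"
        assert format_id("node") == '"node"'  # keyword must be quoted
        assert format_id('a"b') == '"a\\"b"'

    def test_directed_uses_arrow_operator(self):
        text = serialize_dot(parse_dot("digraph g { a -> b }"))
        assert "a -> b" in text
        text = serialize_dot(parse_dot("graph g { a -- b }"))
        assert "a -- b" in text

    @pytest.mark.parametrize("source", [TOY_EXAMPLE, FOUR_NODE_EXAMPLE])
    def test_examples_roundtrip(self, source):
        doc = parse_dot(source)
        assert parse_dot(serialize_dot(doc)) == doc

    @pytest.mark.parametrize("seed", range(25))
    def test_fixture_roundtrip(self, seed):
        doc = parse_dot(generate_fixture(FixtureSpec(seed=seed, directed=bool(seed % 2))))
        assert parse_dot(serialize_dot(doc)) == doc


_id_strategy = st.text(
    alphabet=st.characters(
        codec="utf-8",
        categories=("L", "N", "P", "S", "Zs"),
        exclude_characters="\\",
    ),
    min_size=1,
    max_size=12,
)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    directed=st.booleans(),
    name=_id_strategy,
    nodes=st.lists(
        st.tuples(_id_strategy, st.dictionaries(_id_strategy, _id_strategy, max_size=3)),
        max_size=6,
    ),
)
def test_parse_serialize_identity_property(directed, name, nodes):
    """parse(serialize(doc)) == doc for arbitrary ids and attribute maps
    (backslash excluded: a trailing backslash is not representable in a
    quoted DOT string)."""
    from dotcyto.dotlang import DotDocument, DotGraph

    graph = DotGraph(name=name, directed=directed)
    index = 0
    for node_id, attrs in nodes:
        if node_id in graph.nodes:
            continue
        stmt = DotNodeStmt(id=node_id, attrs=attrs, index=index)
        index += 1
        graph.statements.append(stmt)
        graph.nodes[node_id] = stmt
    ids = list(graph.nodes)
    for i in range(len(ids) - 1):
        graph.statements.append(
            DotEdgeStmt(source_id=ids[i], target_id=ids[i + 1], attrs={}, index=index)
        )
        index += 1
    doc = DotDocument(graphs=[graph])
    assert parse_dot(serialize_dot(doc)) == doc
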