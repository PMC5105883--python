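"""DOT-to-network attribute mapping and whole-document import."""

import pytest

from dotcyto import import_document, parse_dot
from dotcyto.importer import (
    EDGE_PAINT_SEED,
    apply_style_keywords,
    import_graph,
    inches_to_points,
    map_arrow_shape,
    map_edge_attrs,
    map_node_attrs,
    map_node_shape,
    parse_pos,
)
from dotcyto.model import (
    RGBA,
    VisualPropertyKey as K,
    cytoscape_default_style,
    dot_implicit_style,
    effective_value,
)


class TestUnitAndPosParsing:
    @pytest.mark.parametrize("inches, points", [(0.5, 36.0), (0.75, 54.0), (0.0, 0.0)])
    def test_inches_to_points(self, inches, points):
        assert inches_to_points(inches) == points

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            inches_to_points(-1.0)

    @pytest.mark.parametrize(
        "value, expected",
        [
            ("-58.648,-8.4777", (-58.648, 8.4777)),  # y axis flips
            ("0,0", (0.0, 0.0)),
            ("8.8474,55.497", (8.8474, -55.497)),
            ("1,2!", (1.0, -2.0)),  # pin flag discarded
        ],
    )
    def test_parse_pos(self, value, expected):
        assert parse_pos(value) == pytest.approx(expected)

    @pytest.mark.parametrize("value", ["", "1", "1,2,3", "a,b"])
    def test_malformed_pos(self, value):
        assert parse_pos(value) is None


class TestVocabularies:
    @pytest.mark.parametrize(
        "dot_name, model_name",
        [
            ("box", "rectangle"),
            ("rect", "rectangle"),
            ("Mdiamond", "diamond"),
            ("Msquare", "square"),
            ("Mcircle", "ellipse"),
            ("circle", "ellipse"),
            ("hexagon", "hexagon"),
            ("star", None),
            ("cylinder", None),
        ],
    )
    def test_node_shapes(self, dot_name, model_name):
        assert map_node_shape(dot_name) == model_name

    @pytest.mark.parametrize(
        "dot_name, model_name",
        [
            ("tee", "tee"),
            ("onormal", "normal"),
            ("odot", "dot"),
            ("odiamond", "diamond"),
            ("crow", None),
        ],
    )
    def test_arrow_shapes(self, dot_name, model_name):
        assert map_arrow_shape(dot_name) == model_name


class TestStyleKeywords:
    def test_filled_node(self):
        overrides, skipped = apply_style_keywords("filled", "node", "ellipse")
        assert overrides[K.NODE_TRANSPARENCY] == 255
        assert not skipped

    def test_unfilled_node_is_hollow(self):
        overrides, _ = apply_style_keywords("solid", "node", None)
        assert overrides[K.NODE_TRANSPARENCY] == 0

    def test_invis_edge(self):
        overrides, _ = apply_style_keywords("invis", "edge")
        assert overrides == {K.EDGE_VISIBLE: False}

    def test_rounded_requires_rectangle_family(self):
        overrides, _ = apply_style_keywords("rounded", "node", "ellipse")
        assert K.NODE_SHAPE not in overrides
        overrides, _ = apply_style_keywords("rounded", "node", "box")
        assert overrides[K.NODE_SHAPE] == "round-rectangle"

    def test_unknown_keywords_skipped_and_logged(self):
        overrides, skipped = apply_style_keywords("bold,dashed,tapered", "edge")
        assert overrides[K.EDGE_LINE_TYPE] == "dashed"
        assert {entry[1] for entry in skipped} == {"bold", "tapered"}

    def test_duplicate_keyword_last_wins(self):
        overrides, _ = apply_style_keywords("dashed,dotted", "node", None)
        assert overrides[K.NODE_BORDER_LINE_TYPE] == "dotted"


class TestNodeAttrMapping:
    def test_height_width_converted(self):
        overrides, ignored = map_node_attrs({"height": "0.5", "width": "0.75"})
        assert overrides[K.NODE_HEIGHT] == 36.0
        assert overrides[K.NODE_WIDTH] == 54.0
        assert not ignored

    def test_label_backslash_n_resolves_to_node_name(self):
        overrides, _ = map_node_attrs({"label": "\\N"}, node_name="2")
        assert overrides[K.NODE_LABEL] == "2"

    def test_label_backslash_n_stays_literal_without_name(self):
        overrides, _ = map_node_attrs({"label": "\\N"})
        assert overrides[K.NODE_LABEL] == "\\N"

    def test_unsupported_shape_logged_not_mapped(self):
        overrides, ignored = map_node_attrs({"shape": "star"})
        assert K.NODE_SHAPE not in overrides
        assert ignored == [("shape", "star", "unsupported node shape")]

    def test_unknown_attribute_logged(self):
        overrides, ignored = map_node_attrs({"rankdir": "LR"})
        assert not overrides
        assert ignored[0][0] == "rankdir"

    def test_fontsize_and_penwidth_points_one_to_one(self):
        overrides, _ = map_node_attrs({"fontsize": "14", "penwidth": "2.5"})
        assert overrides[K.NODE_LABEL_FONT_SIZE] == 14.0
        assert overrides[K.NODE_BORDER_WIDTH] == 2.5


class TestEdgeAttrMapping:
    def test_weight_goes_to_table_not_visual(self):
        overrides, weight, ignored = map_edge_attrs({"weight": "3"})
        assert weight == 3.0
        assert not overrides and not ignored

    def test_edge_pos_ignored(self):
        _, _, ignored = map_edge_attrs({"pos": "10.278,0.079128 -2.8626,-1.5522"})
        assert ignored[0][0] == "pos"

    def test_open_arrow_equivalence(self):
        overrides, _, _ = map_edge_attrs({"arrowhead": "odot"})
        assert overrides[K.EDGE_TARGET_ARROW_SHAPE] == "dot"

    def test_color_list_logged(self):
        overrides, _, ignored = map_edge_attrs({"color": "red:blue"})
        assert K.EDGE_UNSELECTED_PAINT not in overrides
        assert ignored[0][2] == "unconvertible color value"


class TestImportDocument:
    def test_toy_example(self, toy_result):
        network, style, views = toy_result.network, toy_result.style, toy_result.views
        assert not network.directed
        assert network.name == "toy_example"
        assert [n.shared_name for n in network.nodes] == ["1", "2", "3", "4"]
        assert len(network.edges) == 5
        # root node-default statement overlays the style
        assert style[K.NODE_FILL_COLOR] == RGBA(136, 136, 136, 255)
        assert style[K.NODE_LABEL] == "\\N"
        node1 = network.nodes[0]
        overrides = views[node1.suid].overrides
        assert overrides[K.NODE_LABEL] == "1"
        assert overrides[K.NODE_HEIGHT] == 36.0
        assert overrides[K.NODE_WIDTH] == 54.0
        assert overrides[K.NODE_X_POSITION] == pytest.approx(-58.648)
        assert overrides[K.NODE_Y_POSITION] == pytest.approx(8.4777)
        # fill equals the (overlaid) default: no per-node override
        assert K.NODE_FILL_COLOR not in overrides

    def test_toy_edges_seeded_with_view_paint(self, toy_result):
        for edge in toy_result.network.edges:
            assert toy_result.views[edge.suid].overrides[K.EDGE_UNSELECTED_PAINT] == EDGE_PAINT_SEED

    def test_toy_ignored_log(self, toy_result):
        entries = {(e.element, e.attribute) for e in toy_result.log.entries}
        assert ("graph", "bb") in entries
        assert sum(1 for e in toy_result.log.entries if e.attribute == "pos") == 5

    def test_four_node_positions_pass_through(self, four_node_result):
        node = next(
            n for n in four_node_result.network.nodes if n.shared_name == "Node 1§64"
        )
        view = four_node_result.views[node.suid]
        assert effective_value(four_node_result.style, view, K.NODE_X_POSITION) == -243.0
        assert effective_value(four_node_result.style, view, K.NODE_Y_POSITION) == -42.0

    def test_empty_graph(self):
        result = import_document(parse_dot("graph {}"))[0]
        assert not result.network.nodes and not result.network.edges
        assert result.style.defaults == cytoscape_default_style().defaults

    def test_multiple_graphs_one_result_each(self):
        results = import_document(parse_dot("graph a { x } digraph b { y -> z }"))
        assert [r.network.name for r in results] == ["a", "b"]
        assert results[1].network.directed

    def test_import_is_total_on_strange_attributes(self):
        text = (
            'digraph g { bgcolor="/blues3/1"; a [shape=record, label="x", colorscheme=accent3];'
            ' a -> b [arrowhead=crow, style=tapered, color="0.1 0.2 0.3"] }'
        )
        result = import_document(parse_dot(text))[0]
        assert len(result.network.nodes) == 2
        reasons = {e.reason for e in result.log.entries}
        assert len(result.log.entries) >= 5
        assert "unsupported arrow shape" in reasons

    def test_attribute_free_node_with_implicit_base_style(self):
        result = import_graph(
            parse_dot("graph g { a }").graphs[0], base_style=dot_implicit_style()
        )
        view = result.views[result.network.nodes[0].suid]
        # everything rides on the style defaults
        assert all(k in (K.EDGE_UNSELECTED_PAINT,) for k in view.overrides)
        assert effective_value(result.style, view, K.NODE_SHAPE) == "ellipse"

    def test_weight_default_statement_applies(self):
        result = import_document(parse_dot("graph g { edge [weight=2]; a -- b; c -- d [weight=5] }"))[0]
        weights = [result.network.edge_table[e.suid]["weight"] for e in result.network.edges]
        assert weights == [2.0, 5.0]

    def test_graph_bgcolor_and_label(self):
        result = import_document(parse_dot('graph g { bgcolor="#112233"; label="Title"; a }'))[0]
        assert result.style[K.NETWORK_BACKGROUND_PAINT] == RGBA(17, 34, 51, 255)
        assert result.style[K.NETWORK_TITLE] == "Title"
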