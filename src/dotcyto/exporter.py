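"""Network-to-DOT export.

Serializes ``Network + VisualStyle + views`` into DOT text following the
converter's fixed output conventions:

* header block in fixed order — ``bgcolor``, ``splines``,
  ``outputorder = "edgesfirst"``, ``esep = "0"``, ``pad = "2"`` (a 2-inch
  padding so labels are not cut off), optional network ``label``/
  ``labelloc``;
* one ``node [...]`` and one ``edge [...]`` default statement built from
  the style defaults;
* per-element statements carrying only the attributes whose effective
  value differs from the defaults, in a fixed attribute order;
* node ids written as ``name§SUID``; reals with exactly six decimals;
  colors as ``#RRGGBBAA``; heights/widths converted back to inches;
  stored y positions negated back into DOT's upward-growing axis.

Elements are emitted in reverse insertion order (a Cytoscape iteration
artifact preserved for byte-stable output).  Whatever the model cannot
express in DOT (the edge-table data, per-element label placement) is
reported in :class:`DotOutput.warnings` rather than dropped silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

from .colors import format_color
from .dotlang import format_id
from .model import (
    ElementView,
    ExportOptions,
    Network,
    VisualPropertyKey as K,
    VisualStyle,
    effective_value,
)

POINTS_PER_INCH = 72.0


@dataclass
class DotOutput:
    text: str
    warnings: list[str] = field(default_factory=list)


def points_to_inches(x: float) -> float:
    """Exact inverse of the import conversion (1 in = 72 pt)."""
    return x / POINTS_PER_INCH


def format_real(x: float) -> str:
    """Reals are rendered with exactly six decimal places."""
    return f"{x:.6f}"


def format_fontsize(x: float) -> str:
    """Font sizes use the shortest exact decimal (``12``, ``10.5``)."""
    return format(x, "g")


def make_node_id(name: str, suid: int) -> str:
    """The exported node identifier: ``name§SUID``."""
    return f"{name}§{suid}"


def splines_value(edge_style: str) -> str:
    """The ``splines`` graph attribute for each edge-style option."""
    return {"straight": "false", "curved": "curved", "routed": "true"}[edge_style]


def compose_node_style(
    shape: str, border_line_type: str, visible: bool, transparency: int
) -> str:
    """Node ``style`` keywords in fixed order: line type, ``rounded``
    for round rectangles, ``invis`` when hidden, ``filled`` when opaque."""
    parts = [border_line_type]
    if shape == "round-rectangle":
        parts.append("rounded")
    if not visible:
        parts.append("invis")
    if transparency > 0:
        parts.append("filled")
    return ",".join(parts)


def compose_edge_style(line_type: str, visible: bool) -> str:
    parts = [line_type]
    if not visible:
        parts.append("invis")
    return ",".join(parts)


def node_label_attrs(label: str, loc: str) -> tuple[str, str, Optional[str]]:
    """Which label attribute to write and the default ``labelloc``.

    center/top/bottom keep the ``label`` attribute and set ``labelloc``
    to c/t/b in the node default list; ``external`` switches every node
    to ``xlabel`` (placed clear of other nodes) with an empty ``label``.
    Returns ``(attr_name, default_label, labelloc or None)``.
    """
    if loc == "external":
        return ("xlabel", "", None)
    return ("label", label, {"center": "c", "top": "t", "bottom": "b"}[loc])


def _dot_shape(shape: str) -> str:
    return "rectangle" if shape == "round-rectangle" else shape


def _attr_string(pairs: list[tuple[str, str]]) -> str:
    return ",".join(f'{name} = "{value}"' for name, value in pairs)


def _quote(name: str) -> str:
    return '"' + name.replace('"', '\\"') + '"'


def export_network(
    network: Network,
    style: VisualStyle,
    views: dict[int, ElementView],
    options: Optional[ExportOptions] = None,
) -> DotOutput:
    """Serialize the network, its style and its views to DOT text."""
    options = options or ExportOptions()
    warnings: list[str] = []
    label_attr, default_label, labelloc = node_label_attrs(
        str(style[K.NODE_LABEL]), options.node_label_loc
    )

    lines = []
    head = "digraph" if network.directed else "graph"
    name_part = f" {format_id(network.name)}" if network.name else ""
    lines.append(f"{head}{name_part} {{")
    lines.append(f'bgcolor = "{format_color(style[K.NETWORK_BACKGROUND_PAINT])}"')
    lines.append(f'splines = "{splines_value(options.edge_style)}"')
    lines.append('outputorder = "edgesfirst"')
    lines.append('esep = "0"')
    lines.append('pad = "2"')
    if options.network_label_loc != "none":
        loc = {"top": "t", "bottom": "b"}[options.network_label_loc]
        lines.append(f'label = "{network.name}"')
        lines.append(f'labelloc = "{loc}"')

    # node default statement, attribute order fixed
    node_defaults: list[tuple[str, str]] = [
        ("label", default_label),
        ("penwidth", format_real(style[K.NODE_BORDER_WIDTH])),
        ("height", format_real(points_to_inches(style[K.NODE_HEIGHT]))),
        ("width", format_real(points_to_inches(style[K.NODE_WIDTH]))),
        ("tooltip", str(style[K.NODE_TOOLTIP])),
        ("color", format_color(style[K.NODE_BORDER_PAINT])),
        ("fillcolor", format_color(style[K.NODE_FILL_COLOR])),
        ("shape", _dot_shape(style[K.NODE_SHAPE])),
        (
            "style",
            compose_node_style(
                style[K.NODE_SHAPE],
                style[K.NODE_BORDER_LINE_TYPE],
                bool(style[K.NODE_VISIBLE]),
                int(style[K.NODE_TRANSPARENCY]),
            ),
        ),
        ("fontname", str(style[K.NODE_LABEL_FONT_FACE])),
        ("fontsize", format_fontsize(style[K.NODE_LABEL_FONT_SIZE])),
        ("fontcolor", format_color(style[K.NODE_LABEL_FONT_COLOR])),
        ("fixedsize", "true"),
    ]
    if labelloc is not None:
        node_defaults.append(("labelloc", labelloc))
    lines.append(f"node [{_attr_string(node_defaults)}]")

    # edge default statement
    if network.directed:
        arrowhead = str(style[K.EDGE_TARGET_ARROW_SHAPE])
        arrowtail = str(style[K.EDGE_SOURCE_ARROW_SHAPE])
    else:
        arrowhead = arrowtail = "none"
    edge_defaults: list[tuple[str, str]] = [
        ("label", str(style[K.EDGE_LABEL])),
        ("penwidth", format_real(style[K.EDGE_WIDTH])),
        ("tooltip", str(style[K.EDGE_TOOLTIP])),
        ("arrowhead", arrowhead),
        ("arrowtail", arrowtail),
        ("color", format_color(style[K.EDGE_UNSELECTED_PAINT])),
        ("fontname", str(style[K.EDGE_LABEL_FONT_FACE])),
        ("fontsize", format_fontsize(style[K.EDGE_LABEL_FONT_SIZE])),
        ("fontcolor", format_color(style[K.EDGE_LABEL_FONT_COLOR])),
        ("style", compose_edge_style(style[K.EDGE_LINE_TYPE], bool(style[K.EDGE_VISIBLE]))),
        ("dir", "both"),
    ]
    lines.append(f"edge [{_attr_string(edge_defaults)}]")

    node_ids = {
        node.suid: make_node_id(node.shared_name, node.suid) for node in network.nodes
    }

    for node in reversed(network.nodes):
        view = views.get(node.suid)
        pairs = _node_deviation_attrs(node, style, view, label_attr, default_label)
        attrs = f" [{_attr_string(pairs)}]" if pairs else ""
        lines.append(f"{_quote(node_ids[node.suid])}{attrs}")

    edgeop = "->" if network.directed else "--"
    any_weight = False
    for edge in reversed(network.edges):
        view = views.get(edge.suid)
        pairs = _edge_deviation_attrs(edge, style, view, network.directed)
        attrs = f" [{_attr_string(pairs)}]" if pairs else ""
        lines.append(
            f"{_quote(node_ids[edge.source_suid])} {edgeop} "
            f"{_quote(node_ids[edge.target_suid])}{attrs}"
        )
        if network.edge_table.get(edge.suid, {}).get("weight") is not None:
            any_weight = True
    lines.append("}")

    if any_weight:
        warnings.append("edge table data (weight column) is not representable in the output")
    if options.node_label_loc == "external":
        warnings.append("external labels use xlabel; per-node label placement is not preserved")

    return DotOutput(text="\n".join(lines) + "\n", warnings=warnings)


def _node_deviation_attrs(
    node, style: VisualStyle, view: Optional[ElementView], label_attr: str, default_label: str
) -> list[tuple[str, str]]:
    def eff(key: K) -> Any:
        return effective_value(style, view, key)

    overrides = view.overrides if view is not None else {}
    pairs: list[tuple[str, str]] = []

    label = str(eff(K.NODE_LABEL))
    if label_attr == "xlabel":
        pairs.append(("xlabel", label))
    elif label != default_label:
        pairs.append(("label", label))
    if K.NODE_BORDER_WIDTH in overrides:
        pairs.append(("penwidth", format_real(eff(K.NODE_BORDER_WIDTH))))
    if K.NODE_HEIGHT in overrides:
        pairs.append(("height", format_real(points_to_inches(eff(K.NODE_HEIGHT)))))
    if K.NODE_WIDTH in overrides:
        pairs.append(("width", format_real(points_to_inches(eff(K.NODE_WIDTH)))))
    if K.NODE_X_POSITION in overrides or K.NODE_Y_POSITION in overrides:
        x = float(eff(K.NODE_X_POSITION))
        y = -float(eff(K.NODE_Y_POSITION))  # back to DOT's upward axis
        pairs.append(("pos", f"{format_real(x)},{format_real(y)}"))
    if K.NODE_BORDER_PAINT in overrides:
        pairs.append(("color", format_color(eff(K.NODE_BORDER_PAINT))))
    if K.NODE_FILL_COLOR in overrides:
        pairs.append(("fillcolor", format_color(eff(K.NODE_FILL_COLOR))))
    if K.NODE_TOOLTIP in overrides:
        pairs.append(("tooltip", str(eff(K.NODE_TOOLTIP))))
    if K.NODE_SHAPE in overrides:
        pairs.append(("shape", _dot_shape(eff(K.NODE_SHAPE))))
    if (
        K.NODE_SHAPE in overrides
        or K.NODE_BORDER_LINE_TYPE in overrides
        or K.NODE_VISIBLE in overrides
        or K.NODE_TRANSPARENCY in overrides
    ):
        pairs.append(
            (
                "style",
                compose_node_style(
                    eff(K.NODE_SHAPE),
                    eff(K.NODE_BORDER_LINE_TYPE),
                    bool(eff(K.NODE_VISIBLE)),
                    int(eff(K.NODE_TRANSPARENCY)),
                ),
            )
        )
    if K.NODE_LABEL_FONT_FACE in overrides:
        pairs.append(("fontname", str(eff(K.NODE_LABEL_FONT_FACE))))
    if K.NODE_LABEL_FONT_SIZE in overrides:
        pairs.append(("fontsize", format_fontsize(eff(K.NODE_LABEL_FONT_SIZE))))
    if K.NODE_LABEL_FONT_COLOR in overrides:
        pairs.append(("fontcolor", format_color(eff(K.NODE_LABEL_FONT_COLOR))))
    return pairs


def _edge_deviation_attrs(
    edge, style: VisualStyle, view: Optional[ElementView], directed: bool
) -> list[tuple[str, str]]:
    def eff(key: K) -> Any:
        return effective_value(style, view, key)

    overrides = view.overrides if view is not None else {}
    pairs: list[tuple[str, str]] = []
    if K.EDGE_LABEL in overrides:
        pairs.append(("label", str(eff(K.EDGE_LABEL))))
    if K.EDGE_WIDTH in overrides:
        pairs.append(("penwidth", format_real(eff(K.EDGE_WIDTH))))
    if K.EDGE_TOOLTIP in overrides:
        pairs.append(("tooltip", str(eff(K.EDGE_TOOLTIP))))
    if K.EDGE_TARGET_ARROW_SHAPE in overrides and directed:
        pairs.append(("arrowhead", str(eff(K.EDGE_TARGET_ARROW_SHAPE))))
    if K.EDGE_SOURCE_ARROW_SHAPE in overrides and directed:
        pairs.append(("arrowtail", str(eff(K.EDGE_SOURCE_ARROW_SHAPE))))
    if K.EDGE_UNSELECTED_PAINT in overrides:
        pairs.append(("color", format_color(eff(K.EDGE_UNSELECTED_PAINT))))
    if K.EDGE_LABEL_FONT_FACE in overrides:
        pairs.append(("fontname", str(eff(K.EDGE_LABEL_FONT_FACE))))
    if K.EDGE_LABEL_FONT_SIZE in overrides:
        pairs.append(("fontsize", format_fontsize(eff(K.EDGE_LABEL_FONT_SIZE))))
    if K.EDGE_LABEL_FONT_COLOR in overrides:
        pairs.append(("fontcolor", format_color(eff(K.EDGE_LABEL_FONT_COLOR))))
    if K.EDGE_LINE_TYPE in overrides or K.EDGE_VISIBLE in overrides:
        pairs.append(
            ("style", compose_edge_style(eff(K.EDGE_LINE_TYPE), bool(eff(K.EDGE_VISIBLE))))
        )
    return pairs


__all__ = [
    "DotOutput",
    "export_network",
    "make_node_id",
    "compose_node_style",
    "compose_edge_style",
    "splines_value",
    "node_label_attrs",
    "format_real",
    "format_fontsize",
    "format_color",
    "points_to_inches",
]
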