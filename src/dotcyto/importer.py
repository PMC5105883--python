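"""DOT-to-network import.

Converts a parsed :class:`~dotcyto.dotlang.DotDocument` into one
``(Network, VisualStyle, views, IgnoredAttrLog)`` tuple per top-level
graph.  Root-graph default statements overlay the base visual style;
per-element resolved attributes that differ from the style defaults
become view overrides; everything unmapped or unconvertible is logged,
never fatal — import is total on parseable documents.

Conversion rules:

* ``height``/``width`` are in inches in DOT and points in the model;
  converted at 1 in = 72 pt.
* ``pos`` is already in points and passes through unscaled; the y value
  is negated because the model's y axis grows downward while DOT's
  grows upward (the flip is self-inverse, export negates back).
* ``weight`` has no visual property; it fills the edge table's weight
  column.
* ``pos`` on an *edge* (spline control points) is ignored and logged:
  edges are rendered as straight lines only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

from .colors import parse_color
from .dotlang import DotDocument, DotGraph, resolve_attrs
from .model import (
    ARROW_SHAPES,
    ElementView,
    Network,
    RGBA,
    VisualPropertyKey as K,
    VisualStyle,
    cytoscape_default_style,
)

#: Cytoscape's property-level default edge paint.  A freshly imported
#: edge view carries this value explicitly unless the DOT file assigns a
#: color, which is why re-exported imports print a per-edge ``color``
#: while natively-built networks do not.
EDGE_PAINT_SEED = RGBA(0x40, 0x40, 0x40, 255)

POINTS_PER_INCH = 72.0


@dataclass
class IgnoredEntry:
    element: str
    attribute: str
    value: str
    reason: str


@dataclass
class IgnoredAttrLog:
    """Append-only record of every ignored attribute occurrence."""

    entries: list[IgnoredEntry] = field(default_factory=list)

    def add(self, element: str, attribute: str, value: str, reason: str) -> None:
        self.entries.append(IgnoredEntry(element, attribute, value, reason))

    def extend(self, element: str, entries: list[tuple[str, str, str]]) -> None:
        for attribute, value, reason in entries:
            self.add(element, attribute, value, reason)

    def to_tsv(self) -> str:
        lines = ["element\tattribute\tvalue\treason"]
        for e in self.entries:
            lines.append(f"{e.element}\t{e.attribute}\t{e.value}\t{e.reason}")
        return "\n".join(lines) + "\n"


@dataclass
class ImportResult:
    network: Network
    style: VisualStyle
    views: dict[int, ElementView]
    log: IgnoredAttrLog


def inches_to_points(x: float) -> float:
    """Exact unit conversion, 1 in = 72 pt."""
    if x < 0:
        raise ValueError(f"negative length: {x}")
    return x * POINTS_PER_INCH


def parse_pos(value: str) -> Optional[tuple[float, float]]:
    """Decode a node ``pos`` value ``"x,y"`` (optional trailing ``!``
    pin flag, discarded).  x passes through; y is negated into the
    downward-growing convention.  Returns None when malformed."""
    body = value.strip()
    if body.endswith("!"):
        body = body[:-1]
    parts = body.split(",")
    if len(parts) != 2:
        return None
    try:
        x, y = float(parts[0]), float(parts[1])
    except ValueError:
        return None
    return (x, -y)


_SHAPE_MAP = {
    "triangle": "triangle",
    "diamond": "diamond",
    "ellipse": "ellipse",
    "circle": "ellipse",
    "oval": "ellipse",
    "hexagon": "hexagon",
    "octagon": "octagon",
    "parallelogram": "parallelogram",
    "rectangle": "rectangle",
    "rect": "rectangle",
    "box": "rectangle",
    "square": "square",
    # The M* variants render the same as their plain counterparts.
    "Msquare": "square",
    "Mcircle": "ellipse",
    "Mdiamond": "diamond",
}

_RECTANGLE_FAMILY = {"rectangle", "rect", "box"}

_ARROW_MAP = {name: name for name in ARROW_SHAPES}
_ARROW_MAP.update({"odot": "dot", "onormal": "normal", "odiamond": "diamond"})


def map_node_shape(value: str) -> Optional[str]:
    """Map a DOT shape name into the model vocabulary, or None."""
    return _SHAPE_MAP.get(value)


def map_arrow_shape(value: str) -> Optional[str]:
    """Map a DOT arrowhead/arrowtail name, or None if unsupported."""
    return _ARROW_MAP.get(value)


_LINE_KEYWORDS = {"solid", "dashed", "dotted"}


def apply_style_keywords(
    style_value: str, element_kind: str, shape_attr: Optional[str] = None
) -> tuple[dict[K, Any], list[tuple[str, str, str]]]:
    """Apply the comma-separated ``style`` keyword list.

    solid/dashed/dotted set the border or edge line type; ``invis``
    hides the element; ``rounded`` turns the shape into a round
    rectangle, but only when the shape attribute is rectangle-family;
    ``filled`` makes the node opaque (transparency 255) and its absence
    leaves it hollow (0).  Unknown keywords (bold, tapered, diagonals,
    striped, wedged, ...) are skipped and reported.
    """
    overrides: dict[K, Any] = {}
    skipped: list[tuple[str, str, str]] = []
    is_node = element_kind == "node"
    if is_node:
        overrides[K.NODE_TRANSPARENCY] = 0  # hollow unless 'filled' appears
    for raw in style_value.split(","):
        keyword = raw.strip()
        if not keyword:
            continue
        if keyword in _LINE_KEYWORDS:
            overrides[K.NODE_BORDER_LINE_TYPE if is_node else K.EDGE_LINE_TYPE] = keyword
        elif keyword == "invis":
            overrides[K.NODE_VISIBLE if is_node else K.EDGE_VISIBLE] = False
        elif keyword == "rounded" and is_node:
            if shape_attr in _RECTANGLE_FAMILY:
                overrides[K.NODE_SHAPE] = "round-rectangle"
        elif keyword == "filled" and is_node:
            overrides[K.NODE_TRANSPARENCY] = 255
        else:
            skipped.append(("style", keyword, "unsupported style keyword"))
    return overrides, skipped


def _parse_float(value: str) -> Optional[float]:
    try:
        return float(value)
    except ValueError:
        return None


def map_node_attrs(
    attrs: dict[str, str], node_name: Optional[str] = None
) -> tuple[dict[K, Any], list[tuple[str, str, str]]]:
    """Map resolved node attributes to visual-property overrides.

    A ``label`` of ``\\N`` resolves to the node's name when one is
    given (for per-element mapping); without a name it stays literal
    (for style defaults).  Returns the overrides and a list of
    ``(attribute, value, reason)`` entries for everything ignored.
    """
    overrides: dict[K, Any] = {}
    ignored: list[tuple[str, str, str]] = []

    def color_into(key: K, name: str, value: str) -> None:
        rgba = parse_color(value)
        if rgba is None:
            ignored.append((name, value, "unconvertible color value"))
        else:
            overrides[key] = rgba

    for name, value in attrs.items():
        if name in ("label", "xlabel"):
            overrides[K.NODE_LABEL] = (
                node_name if value == "\\N" and node_name is not None else value
            )
        elif name == "color":
            color_into(K.NODE_BORDER_PAINT, name, value)
        elif name == "fillcolor":
            color_into(K.NODE_FILL_COLOR, name, value)
        elif name == "fontcolor":
            color_into(K.NODE_LABEL_FONT_COLOR, name, value)
        elif name == "penwidth":
            width = _parse_float(value)
            if width is None:
                ignored.append((name, value, "unconvertible number"))
            else:
                overrides[K.NODE_BORDER_WIDTH] = width
        elif name in ("width", "height"):
            size = _parse_float(value)
            if size is None or size < 0:
                ignored.append((name, value, "unconvertible length"))
            else:
                key = K.NODE_WIDTH if name == "width" else K.NODE_HEIGHT
                overrides[key] = inches_to_points(size)
        elif name == "shape":
            shape = map_node_shape(value)
            if shape is None:
                ignored.append((name, value, "unsupported node shape"))
            else:
                overrides[K.NODE_SHAPE] = shape
        elif name == "fontname":
            overrides[K.NODE_LABEL_FONT_FACE] = value
        elif name == "fontsize":
            size = _parse_float(value)
            if size is None:
                ignored.append((name, value, "unconvertible number"))
            else:
                overrides[K.NODE_LABEL_FONT_SIZE] = size
        elif name == "style":
            style_overrides, skipped = apply_style_keywords(value, "node", attrs.get("shape"))
            overrides.update(style_overrides)
            ignored.extend(skipped)
        elif name == "pos":
            pos = parse_pos(value)
            if pos is None:
                ignored.append((name, value, "malformed position"))
            else:
                overrides[K.NODE_X_POSITION], overrides[K.NODE_Y_POSITION] = pos
        elif name == "tooltip":
            overrides[K.NODE_TOOLTIP] = value
        else:
            ignored.append((name, value, "no corresponding visual property"))
    return overrides, ignored


def map_edge_attrs(
    attrs: dict[str, str],
) -> tuple[dict[K, Any], Optional[float], list[tuple[str, str, str]]]:
    """Map resolved edge attributes; also returns the parsed ``weight``
    for the edge table (or None)."""
    overrides: dict[K, Any] = {}
    ignored: list[tuple[str, str, str]] = []
    weight: Optional[float] = None

    for name, value in attrs.items():
        if name in ("label", "xlabel"):
            overrides[K.EDGE_LABEL] = value
        elif name == "weight":
            parsed = _parse_float(value)
            if parsed is None:
                ignored.append((name, value, "unconvertible number"))
            else:
                weight = parsed
        elif name == "color":
            rgba = parse_color(value)
            if rgba is None:
                ignored.append((name, value, "unconvertible color value"))
            else:
                overrides[K.EDGE_UNSELECTED_PAINT] = rgba
        elif name == "fontcolor":
            rgba = parse_color(value)
            if rgba is None:
                ignored.append((name, value, "unconvertible color value"))
            else:
                overrides[K.EDGE_LABEL_FONT_COLOR] = rgba
        elif name == "penwidth":
            width = _parse_float(value)
            if width is None:
                ignored.append((name, value, "unconvertible number"))
            else:
                overrides[K.EDGE_WIDTH] = width
        elif name == "fontname":
            overrides[K.EDGE_LABEL_FONT_FACE] = value
        elif name == "fontsize":
            size = _parse_float(value)
            if size is None:
                ignored.append((name, value, "unconvertible number"))
            else:
                overrides[K.EDGE_LABEL_FONT_SIZE] = size
        elif name == "style":
            style_overrides, skipped = apply_style_keywords(value, "edge")
            overrides.update(style_overrides)
            ignored.extend(skipped)
        elif name == "arrowhead" or name == "arrowtail":
            arrow = map_arrow_shape(value)
            if arrow is None:
                ignored.append((name, value, "unsupported arrow shape"))
            else:
                key = K.EDGE_TARGET_ARROW_SHAPE if name == "arrowhead" else K.EDGE_SOURCE_ARROW_SHAPE
                overrides[key] = arrow
        elif name == "tooltip":
            overrides[K.EDGE_TOOLTIP] = value
        elif name == "pos":
            ignored.append((name, value, "edge pos ignored; edges are straight lines"))
        else:
            ignored.append((name, value, "no corresponding visual property"))
    return overrides, weight, ignored


def _apply_graph_attrs(
    graph: DotGraph, style: VisualStyle, network: Network, log: IgnoredAttrLog
) -> None:
    for name, value in graph.graph_attrs.items():
        if name == "bgcolor":
            rgba = parse_color(value)
            if rgba is None:
                log.add("graph", name, value, "unconvertible color value")
            else:
                style[K.NETWORK_BACKGROUND_PAINT] = rgba
        elif name == "label":
            style[K.NETWORK_TITLE] = value
        else:
            log.add("graph", name, value, "no corresponding visual property")


def import_graph(graph: DotGraph, base_style: Optional[VisualStyle] = None) -> ImportResult:
    """Import one DOT graph into the network model."""
    style = (base_style or cytoscape_default_style()).copy()
    network = Network(name=graph.name, directed=graph.directed)
    views: dict[int, ElementView] = {}
    log = IgnoredAttrLog()

    _apply_graph_attrs(graph, style, network, log)

    # Root default statements overlay the style defaults.  \N in a node
    # default stays literal: it resolves per node, not per style.
    node_defaults: dict[str, str] = {}
    for stmt in graph.defaults("node"):
        node_defaults.update(stmt.attrs)
    defaults_overrides, skipped = map_node_attrs(node_defaults, node_name=None)
    # positions are per-element, never style defaults: a default `pos`
    # still reaches every node through attribute resolution
    defaults_overrides.pop(K.NODE_X_POSITION, None)
    defaults_overrides.pop(K.NODE_Y_POSITION, None)
    style.defaults.update(defaults_overrides)
    log.extend("node-defaults", skipped)

    edge_defaults: dict[str, str] = {}
    for stmt in graph.defaults("edge"):
        edge_defaults.update(stmt.attrs)
    edge_default_overrides, default_weight, skipped = map_edge_attrs(edge_defaults)
    style.defaults.update(edge_default_overrides)
    log.extend("edge-defaults", skipped)

    suids: dict[str, int] = {}
    for node_id, stmt in graph.nodes.items():
        record = network.add_node(node_id)
        suids[node_id] = record.suid
        resolved = resolve_attrs(graph, stmt)
        overrides, ignored = map_node_attrs(resolved, node_name=node_id)
        log.extend(f"node {node_id}", ignored)
        view = ElementView(element_suid=record.suid)
        for key, value in overrides.items():
            if value != style[key]:
                view.overrides[key] = value
        views[record.suid] = view

    for stmt in graph.edges():
        resolved = resolve_attrs(graph, stmt)
        overrides, weight, ignored = map_edge_attrs(resolved)
        element = f"edge {stmt.source_id} -> {stmt.target_id}"
        log.extend(element, ignored)
        edge = network.add_edge(
            suids[stmt.source_id],
            suids[stmt.target_id],
            weight=weight if weight is not None else default_weight,
        )
        view = ElementView(element_suid=edge.suid)
        if K.EDGE_UNSELECTED_PAINT not in overrides:
            # Cytoscape seeds freshly created edge views with the
            # property-level paint, not the style default.
            overrides[K.EDGE_UNSELECTED_PAINT] = EDGE_PAINT_SEED
        for key, value in overrides.items():
            if key == K.EDGE_UNSELECTED_PAINT or value != style[key]:
                view.overrides[key] = value
        views[edge.suid] = view

    return ImportResult(network=network, style=style, views=views, log=log)


def import_document(
    doc: DotDocument, base_style: Optional[VisualStyle] = None
) -> list[ImportResult]:
    """Import every top-level graph of a parsed document."""
    return [import_graph(graph, base_style) for graph in doc.graphs]


__all__ = [
    "IgnoredAttrLog",
    "IgnoredEntry",
    "ImportResult",
    "EDGE_PAINT_SEED",
    "import_document",
    "import_graph",
    "map_node_attrs",
    "map_edge_attrs",
    "apply_style_keywords",
    "map_node_shape",
    "map_arrow_shape",
    "inches_to_points",
    "parse_pos",
    "parse_color",
]
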