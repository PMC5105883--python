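"""Cytoscape-side data model.

Topology (:class:`Network`), the per-edge data table with its ``weight``
column, visual-property defaults (:class:`VisualStyle`) and per-element
view overrides (:class:`ElementView`).

Two fully-populated base styles are provided:

* :func:`cytoscape_default_style` — the factory defaults of a fresh
  Cytoscape session (35 pt x 75 pt rounded rectangles, 12 pt SansSerif,
  2 pt grey edges).  This is the base style a DOT import overlays, and
  it is what makes re-exported files carry explicit ``height``/``width``
  strings for Graphviz-default-sized nodes.
* :func:`dot_implicit_style` — Graphviz's documented implicit attribute
  values mapped through the import rules (ellipse, 14 pt Times,
  0.5 in x 0.75 in, 1 pt black border), for callers who want an import
  that renders the way Graphviz itself would.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Optional


class VisualPropertyKey(str, Enum):
    NODE_LABEL = "NODE_LABEL"
    NODE_BORDER_PAINT = "NODE_BORDER_PAINT"
    NODE_FILL_COLOR = "NODE_FILL_COLOR"
    NODE_BORDER_WIDTH = "NODE_BORDER_WIDTH"
    NODE_WIDTH = "NODE_WIDTH"
    NODE_HEIGHT = "NODE_HEIGHT"
    NODE_SHAPE = "NODE_SHAPE"
    NODE_LABEL_FONT_FACE = "NODE_LABEL_FONT_FACE"
    NODE_LABEL_FONT_SIZE = "NODE_LABEL_FONT_SIZE"
    NODE_LABEL_FONT_COLOR = "NODE_LABEL_FONT_COLOR"
    NODE_X_POSITION = "NODE_X_POSITION"
    NODE_Y_POSITION = "NODE_Y_POSITION"
    NODE_TOOLTIP = "NODE_TOOLTIP"
    NODE_BORDER_LINE_TYPE = "NODE_BORDER_LINE_TYPE"
    NODE_VISIBLE = "NODE_VISIBLE"
    NODE_TRANSPARENCY = "NODE_TRANSPARENCY"
    EDGE_LABEL = "EDGE_LABEL"
    EDGE_UNSELECTED_PAINT = "EDGE_UNSELECTED_PAINT"
    EDGE_WIDTH = "EDGE_WIDTH"
    EDGE_LABEL_FONT_FACE = "EDGE_LABEL_FONT_FACE"
    EDGE_LABEL_FONT_SIZE = "EDGE_LABEL_FONT_SIZE"
    EDGE_LABEL_FONT_COLOR = "EDGE_LABEL_FONT_COLOR"
    EDGE_LINE_TYPE = "EDGE_LINE_TYPE"
    EDGE_VISIBLE = "EDGE_VISIBLE"
    EDGE_TARGET_ARROW_SHAPE = "EDGE_TARGET_ARROW_SHAPE"
    EDGE_SOURCE_ARROW_SHAPE = "EDGE_SOURCE_ARROW_SHAPE"
    EDGE_TOOLTIP = "EDGE_TOOLTIP"
    NETWORK_BACKGROUND_PAINT = "NETWORK_BACKGROUND_PAINT"
    NETWORK_TITLE = "NETWORK_TITLE"


K = VisualPropertyKey

#: Closed vocabularies for the enumerated visual properties.
NODE_SHAPES = frozenset(
    {
        "triangle",
        "diamond",
        "ellipse",
        "hexagon",
        "octagon",
        "parallelogram",
        "rectangle",
        "square",
        "round-rectangle",
    }
)
ARROW_SHAPES = frozenset({"vee", "lvee", "rvee", "dot", "normal", "diamond", "none", "tee"})
LINE_TYPES = frozenset({"solid", "dashed", "dotted"})


@dataclass(frozen=True)
class RGBA:
    """A color as four 0-255 channels; serialized as ``#RRGGBBAA``."""

    r: int
    g: int
    b: int
    a: int = 255

    def __post_init__(self) -> None:
        for channel in (self.r, self.g, self.b, self.a):
            if not (0 <= channel <= 255):
                raise ValueError(f"color channel out of range: {self!r}")


@dataclass
class NodeRecord:
    suid: int
    shared_name: str  # the DOT node id, preserved verbatim on import


@dataclass
class EdgeRecord:
    suid: int
    source_suid: int
    target_suid: int


@dataclass
class Network:
    """Topology container with a per-edge data table.

    Every edge has a slot in ``edge_table`` whose ``weight`` entry is a
    float or ``None``; DOT's ``weight`` attribute has no visual-property
    counterpart and lands here as data.
    """

    name: str = ""
    directed: bool = False
    nodes: list[NodeRecord] = field(default_factory=list)
    edges: list[EdgeRecord] = field(default_factory=list)
    edge_table: dict[int, dict[str, Any]] = field(default_factory=dict)
    next_suid: int = 1

    def node_by_suid(self, suid: int) -> NodeRecord:
        for node in self.nodes:
            if node.suid == suid:
                return node
        raise KeyError(suid)

    def add_node(self, shared_name: str, suid: Optional[int] = None) -> NodeRecord:
        node = NodeRecord(suid=fresh_suid(self) if suid is None else self._claim(suid), shared_name=shared_name)
        self.nodes.append(node)
        return node

    def add_edge(
        self,
        source_suid: int,
        target_suid: int,
        suid: Optional[int] = None,
        weight: Optional[float] = None,
    ) -> EdgeRecord:
        known = {n.suid for n in self.nodes}
        if source_suid not in known or target_suid not in known:
            raise ValueError(f"edge endpoints {source_suid}->{target_suid} reference unknown nodes")
        edge = EdgeRecord(
            suid=fresh_suid(self) if suid is None else self._claim(suid),
            source_suid=source_suid,
            target_suid=target_suid,
        )
        self.edges.append(edge)
        self.edge_table[edge.suid] = {"weight": weight}
        return edge

    def _claim(self, suid: int) -> int:
        if suid <= 0:
            raise ValueError("SUIDs are positive integers")
        if suid >= self.next_suid:
            self.next_suid = suid + 1
        return suid


def fresh_suid(network: Network) -> int:
    """Allocate the next unused SUID; successive calls strictly increase."""
    suid = network.next_suid
    network.next_suid = suid + 1
    return suid


@dataclass
class VisualStyle:
    """Default value for every visual-property key.

    Sizes and widths are in points, colors are :class:`RGBA`, and shape,
    line-type and arrow values come from the closed vocabularies above.
    """

    defaults: dict[VisualPropertyKey, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [k.value for k in VisualPropertyKey if k not in self.defaults]
        if missing:
            raise ValueError(f"VisualStyle is missing defaults for: {', '.join(missing)}")

    def copy(self) -> "VisualStyle":
        return VisualStyle(defaults=dict(self.defaults))

    def __getitem__(self, key: VisualPropertyKey) -> Any:
        return self.defaults[key]

    def __setitem__(self, key: VisualPropertyKey, value: Any) -> None:
        self.defaults[key] = value


@dataclass
class ElementView:
    """Per-element deviations from the style defaults."""

    element_suid: int
    overrides: dict[VisualPropertyKey, Any] = field(default_factory=dict)


def effective_value(style: VisualStyle, view: Optional[ElementView], key: VisualPropertyKey) -> Any:
    """Style default plus overrides fully determine every element's
    effective visual value; this lookup is total."""
    if view is not None and key in view.overrides:
        return view.overrides[key]
    return style[key]


_BLACK = RGBA(0, 0, 0, 255)
_WHITE = RGBA(255, 255, 255, 255)


def cytoscape_default_style() -> VisualStyle:
    """Factory visual defaults of a fresh Cytoscape session."""
    return VisualStyle(
        defaults={
            K.NODE_LABEL: "",
            K.NODE_BORDER_PAINT: RGBA(0xCC, 0xCC, 0xCC, 255),
            K.NODE_FILL_COLOR: RGBA(0x89, 0xD0, 0xF5, 255),
            K.NODE_BORDER_WIDTH: 0.0,
            K.NODE_WIDTH: 75.0,
            K.NODE_HEIGHT: 35.0,
            K.NODE_SHAPE: "round-rectangle",
            K.NODE_LABEL_FONT_FACE: "SansSerif.plain",
            K.NODE_LABEL_FONT_SIZE: 12.0,
            K.NODE_LABEL_FONT_COLOR: _BLACK,
            K.NODE_X_POSITION: 0.0,
            K.NODE_Y_POSITION: 0.0,
            K.NODE_TOOLTIP: "",
            K.NODE_BORDER_LINE_TYPE: "solid",
            K.NODE_VISIBLE: True,
            K.NODE_TRANSPARENCY: 255,
            K.EDGE_LABEL: "",
            K.EDGE_UNSELECTED_PAINT: RGBA(0x84, 0x84, 0x84, 255),
            K.EDGE_WIDTH: 2.0,
            K.EDGE_LABEL_FONT_FACE: "Dialog.plain",
            K.EDGE_LABEL_FONT_SIZE: 10.0,
            K.EDGE_LABEL_FONT_COLOR: _BLACK,
            K.EDGE_LINE_TYPE: "solid",
            K.EDGE_VISIBLE: True,
            K.EDGE_TARGET_ARROW_SHAPE: "none",
            K.EDGE_SOURCE_ARROW_SHAPE: "none",
            K.EDGE_TOOLTIP: "",
            K.NETWORK_BACKGROUND_PAINT: _WHITE,
            K.NETWORK_TITLE: "",
        }
    )


def dot_implicit_style() -> VisualStyle:
    """Graphviz's implicit attribute defaults mapped through the import
    rules: shape ellipse, 0.5 in x 0.75 in (36 pt x 54 pt), 1 pt black
    border, lightgrey fill (shown only when filled), 14 pt Times fonts,
    label ``\\N`` (the node name), solid lines, normal head arrow.

    Nodes are unfilled by default in Graphviz, hence NODE_TRANSPARENCY 0.
    """
    return VisualStyle(
        defaults={
            K.NODE_LABEL: "\\N",
            K.NODE_BORDER_PAINT: _BLACK,
            K.NODE_FILL_COLOR: RGBA(0xD3, 0xD3, 0xD3, 255),  # X11 lightgrey
            K.NODE_BORDER_WIDTH: 1.0,
            K.NODE_WIDTH: 0.75 * 72.0,
            K.NODE_HEIGHT: 0.5 * 72.0,
            K.NODE_SHAPE: "ellipse",
            K.NODE_LABEL_FONT_FACE: "Times-Roman",
            K.NODE_LABEL_FONT_SIZE: 14.0,
            K.NODE_LABEL_FONT_COLOR: _BLACK,
            K.NODE_X_POSITION: 0.0,
            K.NODE_Y_POSITION: 0.0,
            K.NODE_TOOLTIP: "",
            K.NODE_BORDER_LINE_TYPE: "solid",
            K.NODE_VISIBLE: True,
            K.NODE_TRANSPARENCY: 0,
            K.EDGE_LABEL: "",
            K.EDGE_UNSELECTED_PAINT: _BLACK,
            K.EDGE_WIDTH: 1.0,
            K.EDGE_LABEL_FONT_FACE: "Times-Roman",
            K.EDGE_LABEL_FONT_SIZE: 14.0,
            K.EDGE_LABEL_FONT_COLOR: _BLACK,
            K.EDGE_LINE_TYPE: "solid",
            K.EDGE_VISIBLE: True,
            K.EDGE_TARGET_ARROW_SHAPE: "normal",
            K.EDGE_SOURCE_ARROW_SHAPE: "none",
            K.EDGE_TOOLTIP: "",
            K.NETWORK_BACKGROUND_PAINT: _WHITE,
            K.NETWORK_TITLE: "",
        }
    )


_EDGE_STYLES = ("straight", "curved", "routed")
_NODE_LABEL_LOCS = ("center", "top", "bottom", "external")
_NETWORK_LABEL_LOCS = ("none", "top", "bottom")


@dataclass(frozen=True)
class ExportOptions:
    """The three user choices offered at export time."""

    edge_style: str = "straight"
    node_label_loc: str = "center"
    network_label_loc: str = "none"

    def __post_init__(self) -> None:
        if self.edge_style not in _EDGE_STYLES:
            raise ValueError(f"edge_style must be one of {_EDGE_STYLES}")
        if self.node_label_loc not in _NODE_LABEL_LOCS:
            raise ValueError(f"node_label_loc must be one of {_NODE_LABEL_LOCS}")
        if self.network_label_loc not in _NETWORK_LABEL_LOCS:
            raise ValueError(f"network_label_loc must be one of {_NETWORK_LABEL_LOCS}")


__all__ = [
    "VisualPropertyKey",
    "RGBA",
    "NodeRecord",
    "EdgeRecord",
    "Network",
    "VisualStyle",
    "ElementView",
    "ExportOptions",
    "NODE_SHAPES",
    "ARROW_SHAPES",
    "LINE_TYPES",
    "fresh_suid",
    "effective_value",
    "cytoscape_default_style",
    "dot_implicit_style",
]
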