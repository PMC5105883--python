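"""Cytoscape.js JSON (.cyjs) network I/O and the JSON visual-style sidecar.

The ``.cyjs`` format carries topology, node positions (points) and a
per-element ``data`` block; it has no style section, so style defaults
travel in a sidecar JSON document (``{"defaults": {KEY: value}}``).
Per-element visual overrides other than position are stored under the
``vp`` key of each element's data block — Cytoscape itself ignores
unknown data keys, so the files stay loadable elsewhere while
``read . write`` remains the identity on the model.

Colors are encoded as ``#RRGGBBAA`` strings, lengths as numbers in
points.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Union

from .colors import format_color
from .model import (
    ElementView,
    Network,
    RGBA,
    VisualPropertyKey as K,
    VisualStyle,
)

PathLike = Union[str, Path]


class CyjsError(ValueError):
    """Schema violation; the message names the offending JSON path."""


_COLOR_KEYS = {
    K.NODE_BORDER_PAINT,
    K.NODE_FILL_COLOR,
    K.NODE_LABEL_FONT_COLOR,
    K.EDGE_UNSELECTED_PAINT,
    K.EDGE_LABEL_FONT_COLOR,
    K.NETWORK_BACKGROUND_PAINT,
}
_FLOAT_KEYS = {
    K.NODE_BORDER_WIDTH,
    K.NODE_WIDTH,
    K.NODE_HEIGHT,
    K.NODE_LABEL_FONT_SIZE,
    K.NODE_X_POSITION,
    K.NODE_Y_POSITION,
    K.EDGE_WIDTH,
    K.EDGE_LABEL_FONT_SIZE,
}
_INT_KEYS = {K.NODE_TRANSPARENCY}
_BOOL_KEYS = {K.NODE_VISIBLE, K.EDGE_VISIBLE}


def _encode_value(key: K, value: Any) -> Any:
    if key in _COLOR_KEYS:
        return format_color(value)
    if key in _FLOAT_KEYS:
        return float(value)
    if key in _INT_KEYS:
        return int(value)
    if key in _BOOL_KEYS:
        return bool(value)
    return str(value)


def _decode_value(key: K, raw: Any, path: str) -> Any:
    try:
        if key in _COLOR_KEYS:
            digits = str(raw).lstrip("#")
            channels = [int(digits[i : i + 2], 16) for i in (0, 2, 4)]
            alpha = int(digits[6:8], 16) if len(digits) == 8 else 255
            return RGBA(*channels, alpha)
        if key in _FLOAT_KEYS:
            return float(raw)
        if key in _INT_KEYS:
            return int(raw)
        if key in _BOOL_KEYS:
            return bool(raw)
        return str(raw)
    except (ValueError, IndexError) as exc:
        raise CyjsError(f"invalid value for {key.value} at {path}: {raw!r}") from exc


def _req(obj: dict, key: str, path: str) -> Any:
    if not isinstance(obj, dict) or key not in obj:
        raise CyjsError(f"missing required key at {path}.{key}")
    return obj[key]


# ---------------------------------------------------------------------------
# .cyjs network files
# ---------------------------------------------------------------------------


def write_cyjs(network: Network, views: dict[int, ElementView], path: PathLike) -> None:
    """Write network + views as a Cytoscape.js JSON document."""
    nodes = []
    for node in network.nodes:
        view = views.get(node.suid)
        overrides = dict(view.overrides) if view else {}
        data: dict[str, Any] = {
            "id": str(node.suid),
            "SUID": node.suid,
            "name": node.shared_name,
            "shared_name": node.shared_name,
        }
        element: dict[str, Any] = {"data": data, "selected": False}
        if K.NODE_X_POSITION in overrides or K.NODE_Y_POSITION in overrides:
            element["position"] = {
                "x": float(overrides.pop(K.NODE_X_POSITION, 0.0)),
                "y": float(overrides.pop(K.NODE_Y_POSITION, 0.0)),
            }
        data["vp"] = {key.value: _encode_value(key, val) for key, val in overrides.items()}
        nodes.append(element)

    edges = []
    for edge in network.edges:
        view = views.get(edge.suid)
        overrides = view.overrides if view else {}
        data = {
            "id": str(edge.suid),
            "SUID": edge.suid,
            "source": str(edge.source_suid),
            "target": str(edge.target_suid),
            "weight": network.edge_table.get(edge.suid, {}).get("weight"),
            "vp": {key.value: _encode_value(key, val) for key, val in overrides.items()},
        }
        edges.append({"data": data, "selected": False})

    document = {
        "format_version": "1.0",
        "generated_by": "dotcyto",
        "target_cytoscapejs_version": "~2.1",
        "data": {"name": network.name, "shared_name": network.name, "directed": network.directed},
        "elements": {"nodes": nodes, "edges": edges},
    }
    Path(path).write_text(json.dumps(document, indent=2) + "\n", encoding="utf-8")


def read_cyjs(path: PathLike) -> tuple[Network, dict[int, ElementView]]:
    """Read a Cytoscape.js JSON document into the network model.

    Files written by other tools (no ``vp`` block) get the conventional
    name-to-label passthrough so exported labels are not empty.
    """
    try:
        document = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise CyjsError(f"malformed JSON at $ (line {exc.lineno}, column {exc.colno})") from exc

    data = document.get("data", {})
    network = Network(
        name=str(data.get("name", "")), directed=bool(data.get("directed", False))
    )
    views: dict[int, ElementView] = {}
    elements = _req(document, "elements", "$")

    for i, element in enumerate(_req(elements, "nodes", "$.elements")):
        path_ = f"$.elements.nodes[{i}]"
        edata = _req(element, "data", path_)
        suid = int(_req(edata, "id", path_ + ".data"))
        name = str(edata.get("name", edata.get("shared_name", str(suid))))
        network.add_node(name, suid=suid)
        view = ElementView(element_suid=suid)
        position = element.get("position")
        if position is not None:
            view.overrides[K.NODE_X_POSITION] = float(_req(position, "x", path_ + ".position"))
            view.overrides[K.NODE_Y_POSITION] = float(_req(position, "y", path_ + ".position"))
        if "vp" in edata:
            for raw_key, raw_val in edata["vp"].items():
                key = _vp_key(raw_key, path_ + ".data.vp")
                view.overrides[key] = _decode_value(key, raw_val, path_ + ".data.vp")
        else:
            view.overrides[K.NODE_LABEL] = name  # passthrough for foreign files
        views[suid] = view

    for i, element in enumerate(_req(elements, "edges", "$.elements")):
        path_ = f"$.elements.edges[{i}]"
        edata = _req(element, "data", path_)
        suid = int(_req(edata, "id", path_ + ".data"))
        source = int(_req(edata, "source", path_ + ".data"))
        target = int(_req(edata, "target", path_ + ".data"))
        weight = edata.get("weight")
        try:
            network.add_edge(
                source, target, suid=suid, weight=None if weight is None else float(weight)
            )
        except ValueError as exc:
            raise CyjsError(f"{exc} at {path_}.data") from exc
        view = ElementView(element_suid=suid)
        for raw_key, raw_val in edata.get("vp", {}).items():
            key = _vp_key(raw_key, path_ + ".data.vp")
            view.overrides[key] = _decode_value(key, raw_val, path_ + ".data.vp")
        views[suid] = view

    return network, views


def _vp_key(raw: str, path: str) -> K:
    try:
        return K(raw)
    except ValueError as exc:
        raise CyjsError(f"unknown visual property {raw!r} at {path}") from exc


# ---------------------------------------------------------------------------
# visual-style sidecar
# ---------------------------------------------------------------------------


def write_style(style: VisualStyle, path: PathLike) -> None:
    document = {
        "defaults": {key.value: _encode_value(key, val) for key, val in style.defaults.items()}
    }
    Path(path).write_text(json.dumps(document, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def read_style(path: PathLike) -> VisualStyle:
    try:
        document = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise CyjsError(f"malformed JSON at $ (line {exc.lineno}, column {exc.colno})") from exc
    defaults_raw = _req(document, "defaults", "$")
    defaults = {}
    for raw_key, raw_val in defaults_raw.items():
        key = _vp_key(raw_key, "$.defaults")
        defaults[key] = _decode_value(key, raw_val, "$.defaults")
    try:
        return VisualStyle(defaults=defaults)
    except ValueError as exc:
        raise CyjsError(f"incomplete style at $.defaults: {exc}") from exc


__all__ = ["CyjsError", "read_cyjs", "write_cyjs", "read_style", "write_style"]
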