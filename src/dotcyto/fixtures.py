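"""Deterministic DOT fixture generation.

Produces random graphs restricted to the supported attribute subset —
everything a generated file contains survives import without a single
ignored-attribute log entry, which makes the generator suitable for
round-trip and oracle-agreement testing.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .dotlang import (
    DefaultStmt,
    DotDocument,
    DotEdgeStmt,
    DotGraph,
    DotNodeStmt,
    GraphAttrStmt,
    serialize_dot,
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one generated graph; generation is deterministic
    given ``seed``."""

    seed: int
    n_nodes: int = 8
    edge_prob: float = 0.3
    directed: bool = False
    attr_density: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.edge_prob <= 1.0 and 0.0 <= self.attr_density <= 1.0):
            raise ValueError("edge_prob and attr_density must lie in [0, 1]")
        if self.n_nodes < 0:
            raise ValueError("n_nodes must be non-negative")


_WORDS = ["alpha", "beta", "gamma", "delta", "kinase", "ligand", "receptor", "complex"]
_COLORS = ["#888888", "#FF0000", "#1A2B3CFF", "red", "blue", "lightgrey", "navy", "gold"]
_SHAPES = ["ellipse", "box", "rect", "rectangle", "diamond", "triangle", "hexagon",
           "octagon", "parallelogram", "square", "Mdiamond", "Msquare", "Mcircle", "circle"]
_ARROWS = ["normal", "vee", "lvee", "rvee", "dot", "diamond", "none", "tee",
           "odot", "onormal", "odiamond"]
_FONTS = ["Helvetica", "Times-Roman", "Courier"]
_LINE_TYPES = ["solid", "dashed", "dotted"]


def _node_attrs(rng: random.Random, density: float) -> dict[str, str]:
    attrs: dict[str, str] = {}

    def maybe(name: str, value: str) -> None:
        if rng.random() < density:
            attrs[name] = value

    shape = rng.choice(_SHAPES)
    maybe("label", rng.choice(_WORDS))
    maybe("color", rng.choice(_COLORS))
    maybe("fillcolor", rng.choice(_COLORS))
    maybe("penwidth", f"{rng.uniform(0.5, 5):.2f}")
    maybe("width", f"{rng.uniform(0.2, 3):.3f}")
    maybe("height", f"{rng.uniform(0.2, 3):.3f}")
    maybe("shape", shape)
    maybe("fontname", rng.choice(_FONTS))
    maybe("fontsize", str(rng.randint(8, 24)))
    maybe("fontcolor", rng.choice(_COLORS))
    maybe("tooltip", rng.choice(_WORDS))
    maybe("pos", f"{rng.uniform(-300, 300):.2f},{rng.uniform(-300, 300):.2f}")
    if rng.random() < density:
        keywords = [rng.choice(_LINE_TYPES)]
        if shape in ("box", "rect", "rectangle") and rng.random() < 0.5:
            keywords.append("rounded")
        if rng.random() < 0.7:
            keywords.append("filled")
        attrs["style"] = ",".join(keywords)
    return attrs


def _edge_attrs(rng: random.Random, density: float, directed: bool) -> dict[str, str]:
    attrs: dict[str, str] = {}

    def maybe(name: str, value: str) -> None:
        if rng.random() < density:
            attrs[name] = value

    maybe("label", rng.choice(_WORDS))
    maybe("weight", f"{rng.uniform(0, 10):.2f}")
    maybe("penwidth", f"{rng.uniform(0.5, 5):.2f}")
    maybe("color", rng.choice(_COLORS))
    maybe("fontname", rng.choice(_FONTS))
    maybe("fontsize", str(rng.randint(8, 24)))
    maybe("fontcolor", rng.choice(_COLORS))
    maybe("style", rng.choice(_LINE_TYPES))
    if directed:  # arrows have no DOT representation on undirected edges
        maybe("arrowhead", rng.choice(_ARROWS))
        maybe("arrowtail", rng.choice(_ARROWS))
    maybe("tooltip", rng.choice(_WORDS))
    return attrs


def generate_fixture(spec: FixtureSpec) -> str:
    """Generate DOT text for *spec*; identical specs yield identical text."""
    rng = random.Random(spec.seed)
    graph = DotGraph(name=f"fixture_{spec.seed}", directed=spec.directed)
    index = 0

    def nxt() -> int:
        nonlocal index
        index += 1
        return index - 1

    if rng.random() < 0.5:
        stmt = GraphAttrStmt(name="bgcolor", value=rng.choice(_COLORS), index=nxt())
        graph.statements.append(stmt)
        graph.graph_attrs[stmt.name] = stmt.value
    if rng.random() < 0.3:
        stmt = GraphAttrStmt(name="label", value=rng.choice(_WORDS), index=nxt())
        graph.statements.append(stmt)
        graph.graph_attrs[stmt.name] = stmt.value
    if rng.random() < 0.5:
        graph.statements.append(
            DefaultStmt(target="node", attrs=_node_attrs(rng, 0.4), index=nxt())
        )
    if rng.random() < 0.5:
        graph.statements.append(
            DefaultStmt(target="edge", attrs=_edge_attrs(rng, 0.4, spec.directed), index=nxt())
        )

    names = []
    for i in range(spec.n_nodes):
        style_pick = rng.random()
        if style_pick < 0.2:
            name = f"node {i}"  # forces quoting
        elif style_pick < 0.4:
            name = str(i)  # numeral id
        else:
            name = f"n{i}"
        names.append(name)
        stmt = DotNodeStmt(id=name, attrs=_node_attrs(rng, spec.attr_density), index=nxt())
        graph.statements.append(stmt)
        graph.nodes[name] = stmt

    for i in range(spec.n_nodes):
        for j in range(i + 1, spec.n_nodes):
            if rng.random() < spec.edge_prob:
                graph.statements.append(
                    DotEdgeStmt(
                        source_id=names[i],
                        target_id=names[j],
                        attrs=_edge_attrs(rng, spec.attr_density, spec.directed),
                        index=nxt(),
                    )
                )

    return serialize_dot(DotDocument(graphs=[graph]))


__all__ = ["FixtureSpec", "generate_fixture"]
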