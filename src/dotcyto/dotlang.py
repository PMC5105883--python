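"""Parsing and serialization of the Graphviz DOT language.

This module implements an attribute-preserving document model for DOT
text: tokenizer, recursive-descent parser, serializer, and resolution of
default-attribute statements (``node [...]``, ``edge [...]``,
``graph [...]``).

Supported grammar: quoted / unquoted / numeral IDs, string concatenation
with ``+``, attribute lists, edge chains (``a -- b -- c``, expanded to
pairwise edges at parse time), subgraphs (including as edge endpoints),
``strict``, ports/compass suffixes (parsed, discarded with a warning),
and all three comment forms.  HTML-like strings (``<...>``) are
tokenized but rejected with a dedicated error, since HTML-like labels
have no counterpart on the network-model side.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Union

__all__ = [
    "DotParseError",
    "DotHtmlError",
    "DotDocument",
    "DotGraph",
    "DotSubgraph",
    "DotNodeStmt",
    "DotEdgeStmt",
    "DefaultStmt",
    "GraphAttrStmt",
    "parse_dot",
    "serialize_dot",
    "resolve_attrs",
]


class DotParseError(ValueError):
    """Malformed DOT input; carries 1-based line and column."""

    def __init__(self, message: str, line: int, col: int):
        super().__init__(f"{message} (line {line}, column {col})")
        self.line = line
        self.col = col


class DotHtmlError(DotParseError):
    """HTML-like string encountered; these are not convertible."""


# ---------------------------------------------------------------------------
# Document model
# ---------------------------------------------------------------------------


@dataclass
class DotNodeStmt:
    """A node declaration. Repeated declarations of the same id merge
    into one statement (later attributes win)."""

    id: str
    attrs: dict[str, str] = field(default_factory=dict)
    index: int = 0  # position of first declaration in statement order


@dataclass
class DotEdgeStmt:
    source_id: str
    target_id: str
    attrs: dict[str, str] = field(default_factory=dict)
    index: int = 0


@dataclass
class DefaultStmt:
    """``node [...]``, ``edge [...]`` or ``graph [...]``.

    ``scope_depth`` is 0 for statements directly inside a top-level
    graph; only depth-0 defaults participate in attribute resolution.
    """

    target: str  # "node" | "edge" | "graph"
    attrs: dict[str, str] = field(default_factory=dict)
    scope_depth: int = 0
    index: int = 0


@dataclass
class GraphAttrStmt:
    """A bare ``name = value`` statement at graph scope."""

    name: str
    value: str
    scope_depth: int = 0
    index: int = 0


Statement = Union[DotNodeStmt, DotEdgeStmt, DefaultStmt, GraphAttrStmt, "DotSubgraph"]


@dataclass
class DotSubgraph:
    name: str
    statements: list[Statement] = field(default_factory=list)
    index: int = 0


@dataclass
class DotGraph:
    name: str = ""
    directed: bool = False
    strict: bool = False
    statements: list[Statement] = field(default_factory=list)
    # All nodes of the graph keyed by id, in first-appearance order;
    # includes nodes created implicitly by edge statements.
    nodes: dict[str, DotNodeStmt] = field(default_factory=dict)
    # Root-level graph attributes (from `name = value` statements and
    # root `graph [...]` default statements, in document order).
    graph_attrs: dict[str, str] = field(default_factory=dict)

    def edges(self) -> list[DotEdgeStmt]:
        return [s for s in _flatten(self.statements) if isinstance(s, DotEdgeStmt)]

    def defaults(self, target: str) -> list[DefaultStmt]:
        """Root-scope default statements for *target*, in document order."""
        return [
            s
            for s in _flatten(self.statements)
            if isinstance(s, DefaultStmt) and s.target == target and s.scope_depth == 0
        ]


@dataclass
class DotDocument:
    graphs: list[DotGraph] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list, compare=False)


def _flatten(statements: list[Statement]) -> Iterator[Statement]:
    for s in statements:
        yield s
        if isinstance(s, DotSubgraph):
            yield from _flatten(s.statements)


# ---------------------------------------------------------------------------
# Tokenizer
# ---------------------------------------------------------------------------

_KEYWORDS = {"graph", "digraph", "subgraph", "node", "edge", "strict"}
_UNQUOTED_RE = re.compile(r"[A-Za-z_\200-￿][A-Za-z0-9_\200-￿]*")
_NUMERAL_RE = re.compile(r"-?(\.\d+|\d+(\.\d*)?)")
_PUNCT = {"{", "}", "[", "]", ";", ",", "=", ":"}


@dataclass
class _Token:
    kind: str  # "id" | "punct" | "edgeop" | "html" | "eof"
    value: str
    line: int
    col: int
    quoted: bool = False


class _Tokenizer:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0
        self.line = 1
        self.col = 1

    def _advance(self, n: int = 1) -> None:
        for _ in range(n):
            if self.pos < len(self.text):
                if self.text[self.pos] == "\n":
                    self.line += 1
                    self.col = 1
                else:
                    self.col += 1
                self.pos += 1

    def _error(self, msg: str) -> DotParseError:
        return DotParseError(msg, self.line, self.col)

    def _skip_trivia(self) -> None:
        text = self.text
        while self.pos < len(text):
            c = text[self.pos]
            if c in " \t\r\n":
                self._advance()
            elif text.startswith("//", self.pos):
                while self.pos < len(text) and text[self.pos] != "\n":
                    self._advance()
            elif text.startswith("/*", self.pos):
                end = text.find("*/", self.pos + 2)
                if end < 0:
                    raise self._error("unterminated block comment")
                self._advance(end + 2 - self.pos)
            elif c == "#" and self.col == 1:
                while self.pos < len(text) and text[self.pos] != "\n":
                    self._advance()
            else:
                return

    def _read_quoted(self) -> str:
        # positioned at the opening quote
        self._advance()
        out: list[str] = []
        text = self.text
        while True:
            if self.pos >= len(text):
                raise self._error("unterminated quoted string")
            c = text[self.pos]
            if c == '"':
                self._advance()
                return "".join(out)
            if c == "\\" and self.pos + 1 < len(text):
                nxt = text[self.pos + 1]
                if nxt == '"':
                    out.append('"')
                    self._advance(2)
                    continue
                if nxt == "\n":  # line continuation
                    self._advance(2)
                    continue
            out.append(c)
            self._advance()

    def _read_html(self) -> str:
        # positioned at '<'; read a balanced angle-bracket string
        line, col = self.line, self.col
        depth = 0
        out: list[str] = []
        while self.pos < len(self.text):
            c = self.text[self.pos]
            out.append(c)
            if c == "<":
                depth += 1
            elif c == ">":
                depth -= 1
                if depth == 0:
                    self._advance()
                    return "".join(out)
            self._advance()
        raise DotParseError("unterminated HTML-like string", line, col)

    def tokens(self) -> Iterator[_Token]:
        while True:
            self._skip_trivia()
            line, col = self.line, self.col
            if self.pos >= len(self.text):
                yield _Token("eof", "", line, col)
                return
            text = self.text
            c = text[self.pos]
            if text.startswith("->", self.pos) or text.startswith("--", self.pos):
                op = text[self.pos : self.pos + 2]
                self._advance(2)
                yield _Token("edgeop", op, line, col)
            elif c in _PUNCT:
                self._advance()
                yield _Token("punct", c, line, col)
            elif c == '"':
                value = self._read_quoted()
                value = self._maybe_concat(value)
                yield _Token("id", value, line, col, quoted=True)
            elif c == "<":
                value = self._read_html()
                yield _Token("html", value, line, col)
            else:
                m = _NUMERAL_RE.match(text, self.pos) if (c.isdigit() or c in "-.") else None
                if m and m.group(0):
                    self._advance(len(m.group(0)))
                    yield _Token("id", m.group(0), line, col)
                    continue
                m = _UNQUOTED_RE.match(text, self.pos)
                if not m:
                    raise self._error(f"unexpected character {c!r}")
                self._advance(len(m.group(0)))
                yield _Token("id", m.group(0), line, col)

    def _maybe_concat(self, value: str) -> str:
        """Handle DOT's ``"a" + "b"`` string concatenation."""
        while True:
            save = (self.pos, self.line, self.col)
            self._skip_trivia()
            if self.pos < len(self.text) and self.text[self.pos] == "+":
                self._advance()
                self._skip_trivia()
                if self.pos < len(self.text) and self.text[self.pos] == '"':
                    value += self._read_quoted()
                    continue
                raise self._error("expected quoted string after '+'")
            self.pos, self.line, self.col = save
            return value


# ---------------------------------------------------------------------------
# Parser
# ---------------------------------------------------------------------------


class _Parser:
    def __init__(self, text: str):
        self._stream = _Tokenizer(text).tokens()
        self._peeked: list[_Token] = []
        self.warnings: list[str] = []

    def _next(self) -> _Token:
        if self._peeked:
            return self._peeked.pop(0)
        return next(self._stream)

    def _peek(self, ahead: int = 0) -> _Token:
        while len(self._peeked) <= ahead:
            self._peeked.append(next(self._stream))
        return self._peeked[ahead]

    def _expect_punct(self, value: str) -> _Token:
        tok = self._next()
        if tok.kind != "punct" or tok.value != value:
            raise DotParseError(f"expected {value!r}, got {tok.value!r}", tok.line, tok.col)
        return tok

    def _expect_id(self) -> _Token:
        tok = self._next()
        if tok.kind == "html":
            raise DotHtmlError("HTML-like labels are not supported", tok.line, tok.col)
        if tok.kind != "id":
            raise DotParseError(f"expected identifier, got {tok.value!r}", tok.line, tok.col)
        return tok

    @staticmethod
    def _is_kw(tok: _Token, kw: str) -> bool:
        return tok.kind == "id" and not tok.quoted and tok.value.lower() == kw

    # -- grammar ------------------------------------------------------------

    def parse(self) -> DotDocument:
        doc = DotDocument()
        while self._peek().kind != "eof":
            doc.graphs.append(self._graph())
        doc.warnings = self.warnings
        return doc

    def _graph(self) -> DotGraph:
        graph = DotGraph()
        tok = self._next()
        if self._is_kw(tok, "strict"):
            graph.strict = True
            tok = self._next()
        if self._is_kw(tok, "digraph"):
            graph.directed = True
        elif not self._is_kw(tok, "graph"):
            raise DotParseError(
                f"expected 'graph' or 'digraph', got {tok.value!r}", tok.line, tok.col
            )
        if self._peek().kind == "id":
            graph.name = self._next().value
        self._expect_punct("{")
        self._counter = 0
        self._stmt_list(graph, graph.statements, depth=0)
        return graph

    def _new_index(self) -> int:
        i = self._counter
        self._counter += 1
        return i

    def _stmt_list(self, graph: DotGraph, out: list[Statement], depth: int) -> None:
        while True:
            tok = self._peek()
            if tok.kind == "punct" and tok.value == "}":
                self._next()
                return
            if tok.kind == "punct" and tok.value == ";":
                self._next()
                continue
            if tok.kind == "eof":
                raise DotParseError("unexpected end of input, expected '}'", tok.line, tok.col)
            self._statement(graph, out, depth)

    def _statement(self, graph: DotGraph, out: list[Statement], depth: int) -> None:
        tok = self._peek()
        # default-attribute statement
        if any(self._is_kw(tok, kw) for kw in ("node", "edge", "graph")):
            target_tok = self._next()
            target = target_tok.value.lower()
            attrs = self._attr_list()
            stmt = DefaultStmt(target=target, attrs=attrs, scope_depth=depth, index=self._new_index())
            out.append(stmt)
            if target == "graph" and depth == 0:
                graph.graph_attrs.update(attrs)
            return
        # subgraph (possibly an edge endpoint)
        if self._is_kw(tok, "subgraph") or (tok.kind == "punct" and tok.value == "{"):
            sub = self._subgraph(graph, depth)
            if self._peek().kind == "edgeop":
                self._edge_chain(graph, out, depth, first=sub)
            else:
                out.append(sub)
            return
        # plain ID: node statement, edge chain, or name = value
        id_tok = self._expect_id()
        self._maybe_port(id_tok.value)
        nxt = self._peek()
        if nxt.kind == "punct" and nxt.value == "=":
            self._next()
            value_tok = self._expect_id()
            stmt = GraphAttrStmt(
                name=id_tok.value, value=value_tok.value, scope_depth=depth, index=self._new_index()
            )
            out.append(stmt)
            if depth == 0:
                graph.graph_attrs[id_tok.value] = value_tok.value
            return
        if nxt.kind == "edgeop":
            self._edge_chain(graph, out, depth, first=id_tok.value)
            return
        # node statement
        attrs = self._attr_list() if (nxt.kind == "punct" and nxt.value == "[") else {}
        self._declare_node(graph, out, id_tok.value, attrs)

    def _declare_node(
        self, graph: DotGraph, out: list[Statement], node_id: str, attrs: dict[str, str]
    ) -> None:
        existing = graph.nodes.get(node_id)
        if existing is not None:
            existing.attrs.update(attrs)  # repeated declaration: last wins
            self._new_index()
            return
        stmt = DotNodeStmt(id=node_id, attrs=attrs, index=self._new_index())
        graph.nodes[node_id] = stmt
        out.append(stmt)

    def _implicit_node(self, graph: DotGraph, node_id: str, index: int) -> None:
        if node_id not in graph.nodes:
            graph.nodes[node_id] = DotNodeStmt(id=node_id, attrs={}, index=index)

    def _maybe_port(self, node_id: str) -> None:
        while self._peek().kind == "punct" and self._peek().value == ":":
            self._next()
            port = self._expect_id()
            self.warnings.append(
                f"port/compass suffix ':{port.value}' on {node_id!r} discarded (record nodes unsupported)"
            )

    def _subgraph(self, graph: DotGraph, depth: int) -> DotSubgraph:
        name = ""
        if self._is_kw(self._peek(), "subgraph"):
            self._next()
            if self._peek().kind == "id":
                name = self._next().value
        sub = DotSubgraph(name=name, index=self._new_index())
        self._expect_punct("{")
        self._stmt_list(graph, sub.statements, depth + 1)
        return sub

    def _endpoint_nodes(self, graph: DotGraph, endpoint, index: int) -> list[str]:
        if isinstance(endpoint, DotSubgraph):
            ids = [s.id for s in _flatten(endpoint.statements) if isinstance(s, DotNodeStmt)]
            for s in _flatten(endpoint.statements):
                if isinstance(s, DotEdgeStmt):
                    for nid in (s.source_id, s.target_id):
                        if nid not in ids:
                            ids.append(nid)
            return ids
        self._implicit_node(graph, endpoint, index)
        return [endpoint]

    def _edge_chain(self, graph: DotGraph, out: list[Statement], depth: int, first) -> None:
        endpoints = [first]
        ops: list[_Token] = []
        while self._peek().kind == "edgeop":
            op = self._next()
            expected = "->" if graph.directed else "--"
            if op.value != expected:
                raise DotParseError(
                    f"edge operator {op.value!r} not allowed in "
                    f"{'directed' if graph.directed else 'undirected'} graph",
                    op.line,
                    op.col,
                )
            ops.append(op)
            tok = self._peek()
            if self._is_kw(tok, "subgraph") or (tok.kind == "punct" and tok.value == "{"):
                endpoints.append(self._subgraph(graph, depth))
            else:
                ep = self._expect_id()
                self._maybe_port(ep.value)
                endpoints.append(ep.value)
        attrs = {}
        if self._peek().kind == "punct" and self._peek().value == "[":
            attrs = self._attr_list()
        if isinstance(first, DotSubgraph):
            out.append(first)
        for a, b in zip(endpoints, endpoints[1:]):
            if isinstance(b, DotSubgraph):
                out.append(b)
            index = self._new_index()
            for src in self._endpoint_nodes(graph, a, index):
                for dst in self._endpoint_nodes(graph, b, index):
                    out.append(
                        DotEdgeStmt(source_id=src, target_id=dst, attrs=dict(attrs), index=index)
                    )
                    index = self._new_index()
            self._counter -= 1  # last allocation unused

    def _attr_list(self) -> dict[str, str]:
        attrs: dict[str, str] = {}
        while self._peek().kind == "punct" and self._peek().value == "[":
            self._next()
            while True:
                tok = self._peek()
                if tok.kind == "punct" and tok.value == "]":
                    self._next()
                    break
                if tok.kind == "punct" and tok.value in (",", ";"):
                    self._next()
                    continue
                name = self._expect_id()
                self._expect_punct("=")
                value = self._expect_id()
                attrs[name.value] = value.value
        return attrs


def parse_dot(text: str) -> DotDocument:
    """Parse DOT text into a :class:`DotDocument`.

    Nodes referenced only in edge statements are created implicitly
    with empty attribute maps.  Raises :class:`DotParseError` (with line
    and column) on malformed input, and the subclass
    :class:`DotHtmlError` when an HTML-like string is encountered.
    """
    return _Parser(text).parse()


# ---------------------------------------------------------------------------
# Default-attribute resolution
# ---------------------------------------------------------------------------


def resolve_attrs(graph: DotGraph, element: DotNodeStmt | DotEdgeStmt) -> dict[str, str]:
    """Merged attributes for *element*: root-scope default statements of
    the matching kind that appear before the element, in document order,
    overlaid by the element's own attributes.

    Defaults declared inside subgraphs never participate: only the
    default attribute values set within the root graph are considered.
    """
    target = "node" if isinstance(element, DotNodeStmt) else "edge"
    merged: dict[str, str] = {}
    for stmt in graph.defaults(target):
        if stmt.index < element.index:
            merged.update(stmt.attrs)
    merged.update(element.attrs)
    return merged


# ---------------------------------------------------------------------------
# Serializer
# ---------------------------------------------------------------------------

_SAFE_ID_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*\Z")


def format_id(value: str) -> str:
    """Render an ID, quoting whenever required by the grammar."""
    if value and (_SAFE_ID_RE.match(value) or _NUMERAL_RE.fullmatch(value)):
        if value.lower() not in _KEYWORDS:
            return value
    return '"' + value.replace('"', '\\"') + '"'


def _format_attrs(attrs: dict[str, str]) -> str:
    inner = ",".join(f"{format_id(k)}={format_id(v)}" for k, v in attrs.items())
    return f" [{inner}]"


def _serialize_stmt(stmt: Statement, edgeop: str, indent: str) -> list[str]:
    if isinstance(stmt, DotNodeStmt):
        attrs = _format_attrs(stmt.attrs) if stmt.attrs else ""
        return [f"{indent}{format_id(stmt.id)}{attrs};"]
    if isinstance(stmt, DotEdgeStmt):
        attrs = _format_attrs(stmt.attrs) if stmt.attrs else ""
        return [f"{indent}{format_id(stmt.source_id)} {edgeop} {format_id(stmt.target_id)}{attrs};"]
    if isinstance(stmt, DefaultStmt):
        return [f"{indent}{stmt.target}{_format_attrs(stmt.attrs)};"]
    if isinstance(stmt, GraphAttrStmt):
        return [f"{indent}{format_id(stmt.name)}={format_id(stmt.value)};"]
    if isinstance(stmt, DotSubgraph):
        head = f"{indent}subgraph {format_id(stmt.name)} {{" if stmt.name else f"{indent}subgraph {{"
        lines = [head]
        for child in stmt.statements:
            lines.extend(_serialize_stmt(child, edgeop, indent + "  "))
        lines.append(f"{indent}}}")
        return lines
    raise TypeError(f"unknown statement type: {stmt!r}")


def serialize_dot(doc: DotDocument) -> str:
    """Serialize a document to grammar-valid DOT text.

    ``parse_dot(serialize_dot(doc))`` is structurally equal to *doc*.
    """
    chunks: list[str] = []
    for graph in doc.graphs:
        head = "strict " if graph.strict else ""
        head += "digraph" if graph.directed else "graph"
        if graph.name:
            head += f" {format_id(graph.name)}"
        lines = [head + " {"]
        edgeop = "->" if graph.directed else "--"
        for stmt in graph.statements:
            lines.extend(_serialize_stmt(stmt, edgeop, "  "))
        lines.append("}")
        chunks.append("\n".join(lines))
    return "\n".join(chunks) + "\n"
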