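# Methods

## The two models

**DOT side.** A document is an ordered list of top-level graphs; each graph an
ordered list of statements (node, edge, default-attribute, graph-attribute,
subgraph). The parser is a hand-written tokenizer + recursive-descent parser
covering quoted/unquoted/numeral IDs, `"a" + "b"` concatenation, all three
comment forms, edge chains (expanded to pairwise edges at parse time),
subgraphs (including as edge endpoints, expanded over their node sets), ports
(parsed, discarded with a warning) and `strict` (parsed, no conversion
effect). Repeated node declarations merge, last value wins. Nodes referenced
only by edges are created implicitly. HTML-like strings raise a dedicated
error: they have no counterpart on the other side. Quoted values are
unescaped minimally — `\"` and backslash-newline only — so sequences such as
`\N` survive verbatim. One consequence: an ID whose last character is a
backslash is not representable in a quoted DOT string and does not round-trip;
the serializer makes no attempt to repair this.

**Network side.** A `Network` (SUID-keyed nodes and edges plus an edge data
table with a nullable `weight` column), a `VisualStyle` holding a default for
*every* visual-property key, and per-element `ElementView` overrides. Lookup
is total: default + override determine every effective value. Sizes and
widths are points, colors RGBA 0–255, shapes/line types/arrows closed
vocabularies.

## Attribute resolution

Only default-attribute statements in the **root graph** participate; defaults
inside subgraphs are recorded (with their scope depth) but ignored. Defaults
apply in document order to the elements that follow them; the element's own
attributes win. Whether defaults appearing *after* an element should apply to
it is genuinely open; standard Graphviz document-order semantics were chosen.

## Import conventions

* Base style: the **factory defaults of a Cytoscape session**
  (35 pt × 75 pt round-rectangles, 12 pt SansSerif, penwidth 0, fill
  `#89D0F5`, 2 pt `#848484` edges). This is what reproduces the reference
  export byte patterns: a Graphviz-default 0.5 in node differs from the 35 pt
  default and is therefore written explicitly on re-export.
  `dot_implicit_style()` (ellipse, 0.5 in × 0.75 in, 1 pt black border, 14 pt
  Times, unfilled) is available as an alternative base for callers who want
  an import that renders the way Graphviz itself would.
* Unit conversion applies to `height`/`width` only (1 in = 72 pt exactly);
  `fontsize`, `penwidth` and `pos` are already points and map 1:1.
* Coordinates: stored y = −(DOT y). The flip is self-inverse; export negates
  back, so round-tripped `pos` strings are bit-identical at 6 decimals.
  Positions are always per-element: a `pos` inside a node-default statement
  reaches nodes through resolution but never becomes a style default (the
  exported default statement has no `pos` slot).
* `label` value `\N` denotes the node's own name: resolved per node; kept
  literal when it appears in a default statement (the style default).
* `style` keywords: `solid`/`dashed`/`dotted` → line type, `invis` → hidden,
  `filled` → transparency 255, its absence (when a `style` attribute is
  present) → 0, `rounded` → round-rectangle but only for rectangle-family
  shapes. Unknown keywords (`bold`, `tapered`, `diagonals`, `striped`,
  `wedged`, ...) are logged and skipped. Duplicates: last wins.
* Colors: `#RRGGBB`, `#RRGGBBAA`, X11 names. The name table is matplotlib's
  CSS4 set with the four X11/CSS divergences overridden (green `#00FF00`,
  gray/grey `#BEBEBE`, maroon `#B03060`, purple `#A020F0`) plus the
  `gray0`–`gray100`/`grey0`–`grey100` ramps; numbered variants (`green3`) and
  every Brewer/HSV/color-list value are treated as unconvertible and logged.
* Graph level: `bgcolor` → background paint, `label` → network title;
  everything else (`bb`, `overlap`, `rankdir`, `splines`, ...) logged.
* Edge views are seeded with an explicit unselected-paint of `#404040FF`
  when the file assigns no `color`. This mirrors the host platform's
  property-level default (which per-edge views report even though the style
  default prints as `#848484FF`) and is what makes re-exported imports carry
  a per-edge `color` while natively-built networks export bare edges.
  Round-trip equivalence is stated over networks produced by DOT import,
  where the seed makes it exact.

## Export conventions

Fixed header order (`bgcolor`, `splines`, `outputorder`, `esep`, `pad`,
optional network `label`/`labelloc`), then the node and edge default
statements in the fixed attribute orders observed in reference output, then
elements in reverse insertion order (an iteration artifact of the reference
implementation, kept for byte-stable golden comparison; a second cycle
reverses back — statement *content* is cycle-stable). Per-element statements
carry only attributes whose effective value differs from the default
statement. Reals print with exactly six decimals; font sizes as the shortest
exact decimal; colors as uppercase `#RRGGBBAA`. `fixedsize = "true"` is
always written so Graphviz honors the exported sizes; `bgcolor` is always
written, even when default white; `dir = "both"` is always present in the
edge defaults (harmless when arrows are `none`). Undirected networks emit
`--` with `arrowhead`/`arrowtail` forced to `none`; directed networks emit
`->` and the style's arrow shapes. The node-label location option applies
globally: c/t/b set `labelloc` in the node defaults, `external` switches
every node to `xlabel`. Information the DOT format cannot carry (the edge
table's weight column, per-node label placement under `external`) is returned
as warnings rather than dropped silently.

## Cytoscape.js interchange

`.cyjs` carries topology, positions (points, y down) and the `weight` column;
the style defaults travel in a JSON sidecar because `.cyjs` has no style
section. Per-element overrides other than position are stored under a `vp`
data key (ignored by other consumers), which makes write→read the identity on
the model. Files written by other tools (no `vp` marker) get the conventional
name→label passthrough so their exports are not label-less. Schema errors
name the offending JSON path.

## Fixture generator

`generate_fixture(FixtureSpec(...))` emits graphs restricted to the supported
subset — every attribute it writes is convertible, so importing a fixture
produces an empty ignored-attribute log. Defaults: 8 nodes, edge probability
0.3 (sparse biological-network-like density), attribute density 0.5, a mix of
alphanumeric, numeral and space-containing node names to exercise quoting.
Generation is deterministic per seed (`random.Random`). What fixtures do *not*
contain — HTML labels, subgraphs, clusters, record nodes, color lists — is
exactly what the converter ignores or rejects, so green round-trip tests
establish fidelity of the supported subset only.

## Numerical choices

* 6-decimal output formatting bounds round-trip error: positions within
  10⁻³ pt, sizes within 10⁻⁴ pt (a 35 pt default prints as 0.486111 in and
  re-imports as 34.999992 pt); colors, vocabularies and strings are exact.
* SUIDs are allocated sequentially from 1 per import, making runs
  byte-reproducible; exported ids append `§SUID`, and comparisons across
  cycles treat trailing `§<digits>` as session-dependent.

## Known limitations

No layout computation; edges are straight lines (spline `pos` values on edges
are discarded); no clusters, record labels, gradients, parallel/segmented
multicolor edges, or per-subgraph defaults; arrows on undirected edges are
not expressible in the output; the edge-table `weight` column is import-only.
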