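# dotcyto

Bidirectional conversion between **Graphviz DOT files** (`.dot`/`.gv`) and a
**Cytoscape-compatible network + visual-style model** (Cytoscape.js `.cyjs`
plus a JSON style sidecar).

Graphviz-family tools (dot, neato, Gephi, Tulip, NetworkX, ...) excel at graph
layout and styling; network-analysis platforms in bioinformatics work with a
different model — a topology table, a data table, a *visual style* of default
visual-property values, and per-element overrides. Moving a network between
the two worlds by hand, or through a lossy intermediate format, discards
layout and styling. dotcyto performs the direct translation and accounts for
everything it cannot carry over.

## What the converter does

**Import** (`DOT → model`): the DOT file is parsed into an
attribute-preserving document model; each top-level graph becomes a network.
Root-graph default statements (`node [...]`, `edge [...]`) overlay the style
defaults; each element's resolved attributes that differ from the defaults
become view overrides; the rest rides on the style. Mappings follow the
fixed tables — `label`→NODE_LABEL, `fillcolor`→NODE_FILL_COLOR,
`penwidth`→NODE_BORDER_WIDTH, `pos`→(x, y), `arrowhead`→target arrow, and so
on — with three conversions worth noting:

* node `height`/`width` are **inches** in DOT and **points** in the model:
  converted at exactly 1 in = 72 pt, both directions;
* `pos` is already in points and passes through unscaled; the y value is
  negated (DOT's y grows upward, the model's downward) and negated back on
  export, so a round trip reproduces the original coordinates;
* edge `weight` has no visual property: it fills the network's edge-table
  `weight` column as data.

Whatever cannot be converted — unsupported shapes, Brewer colorschemes,
HSV triples, color lists, spline control points on edges, unknown
attributes — is *ignored and logged*, never fatal. Import is total on
parseable files (HTML-like labels are the one rejected construct).

**Export** (`model → DOT`): a fixed header block (`bgcolor`, `splines`,
`outputorder = "edgesfirst"`, `esep = "0"`, `pad = "2"`), one node and one
edge default statement built from the style, then per-element statements
carrying only the attributes that deviate from the defaults. Node ids are
written as `name§SUID`. Three user options control the output: edge style
(`splines` false/curved/true), node label location (`labelloc` c/t/b, or
`xlabel` for external), and network label location.

## Worked example

```python
from dotcyto import parse_dot, import_document, export_network
from dotcyto.examples import TOY_EXAMPLE   # a neato-laid-out 4-node graph

result = import_document(parse_dot(TOY_EXAMPLE))[0]
print(len(result.network.nodes), len(result.network.edges))   # 4 5
print(result.style.defaults["NODE_FILL_COLOR"])   # RGBA(r=136, g=136, b=136, a=255)
print(export_network(result.network, result.style, result.views).text)
```

prints (abridged):

```
graph toy_example {
bgcolor = "#FFFFFFFF"
splines = "false"
outputorder = "edgesfirst"
esep = "0"
pad = "2"
node [label = "\N",penwidth = "0.000000",height = "0.486111",width = "1.041667",...]
edge [label = "",penwidth = "2.000000",...,color = "#848484FF",...,dir = "both"]
"4§4" [label = "4",height = "0.500000",width = "0.750000",pos = "8.847400,55.497000"]
...
"2§2" -- "1§1" [color = "#404040FF"]
}
```

The grey fill from the input's `node [fillcolor="#888888",...]` default landed
in the style; node 4 kept its coordinates exactly (`pos` passed through, the
y-flip is self-inverse); the 0.5 in × 0.75 in node size survived the
inch↔point conversions; and the per-node lines carry only what differs from
the defaults.

The same pipeline from the shell:

```sh
dotcyto import toy.gv -o toy.cyjs --style toy-style.json --log ignored.tsv
dotcyto export toy.cyjs --style toy-style.json -o out.gv --edge-style curved
dotcyto roundtrip toy.gv
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the reference conversion quantities: the x
coordinate of node "1" and y coordinate of node "4" written after
round-tripping the bundled toy network, the imported x position of
"Node 1§64" in the bundled four-node example, and the height (in inches)
written for node "1" — all by running parse → import → export → re-parse and
reading the values off the output.

See `docs/methods.md` for the conversion rules, the coordinate and seeding
conventions, and known limitations.
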