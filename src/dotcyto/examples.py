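r"""Bundled sample networks.

Two small DOT files used throughout the documentation and tests:

* :data:`TOY_EXAMPLE` — a four-node undirected graph laid out with
  Graphviz's ``neato`` (node positions baked into ``pos`` attributes,
  grey filled nodes via a root node-default statement).
* :data:`FOUR_NODE_EXAMPLE` — a four-node undirected network in the
  exact form this converter's exporter writes (header block, default
  statements, ``name§SUID`` node ids).
"""

TOY_EXAMPLE = r"""graph toy_example {
graph [bb="-85.648,-58.068,63.891,73.497",outputorder=edgesfirst, overlap=false];
node [fillcolor="#888888",label="\N",style=filled];
   1     [height=0.5,pos="-58.648,-8.4777",width=0.75];
   2     [height=0.5,pos="36.891,3.383",width=0.75];
   2 -- 1     [pos="10.278,0.079128 -2.8626,-1.5522 -18.68,-3.5159 -31.846,-5.1504"];
   3     [height=0.5,pos="12.665,-40.068",width=0.75];
   3 -- 1     [pos="-9.8989,-30.072 -18.223,-26.385 -27.653,-22.208 -35.986,-18.516"];
   3 -- 2     [pos="22.24,-22.895 23.933,-19.858 25.695,-16.698 27.386,-13.665"];
   4     [height=0.5,pos="8.8474,55.497",width=0.75];
   4 -- 2     [pos="18.03,38.433 21.097,32.734 24.516,26.38 27.592,20.664"];
   4 -- 3     [pos="9.5835,37.071 10.264,20.041 11.269,-5.1139 11.944,-22.022"];
}
"""

FOUR_NODE_EXAMPLE = r"""graph example {
bgcolor = "#FFFFFFFF"
splines = "false"
outputorder = "edgesfirst"
esep = "0"
pad = "2"
node [label = "",penwidth = "0.000000",height = "0.486111",width = "1.041667",tooltip = "",color = "#CCCCCCFF",fillcolor = "#89D0F5FF",shape = "rectangle",style = "solid,rounded,filled",fontname = "SansSerif.plain",fontsize = "12",fontcolor = "#000000FF",fixedsize = "true",labelloc = "c"]
edge [label = "",penwidth = "2.000000",tooltip = "",arrowhead = "none",arrowtail = "none",color = "#848484FF",fontname = "Dialog.plain",fontsize = "10",fontcolor = "#000000FF",style = "solid",dir = "both"]
"Node 1§64" [label = "Node 1",pos = "-243.000000,42.000000"]
"Node 2§66" [label = "Node 2",pos = "-70.975037,42.014648"]
"Node 3§68" [label = "Node 3",pos = "-159.020569,-41.005199"]
"Node 4§70" [label = "Node 4",pos = "-243.001038,-123.001381"]
"Node 1§64" -- "Node 2§66"
"Node 2§66" -- "Node 4§70"
"Node 1§64" -- "Node 3§68"
}
"""

__all__ = ["TOY_EXAMPLE", "FOUR_NODE_EXAMPLE"]
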