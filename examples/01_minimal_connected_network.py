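"""Build a minimal connected network (MCN) from a gene list, with and
without external linker nodes, and print its node statistics.

The scaffold is a hand-made toy interactome; the module's members a, b
and c are only fully connected once the non-member hub x is admitted.
"""

import networkx as nx

from mcnet import ScaffoldInteractome, build_mcn, node_params

g = nx.Graph()
for u, v in [("a", "x"), ("x", "b"), ("a", "c"), ("x", "d"), ("d", "e")]:
    g.add_edge(u, v, evidence=frozenset({"y2h"}))
scaffold = ScaffoldInteractome(g)

for allow_external in (False, True):
    mcn = build_mcn({"a", "b", "c"}, scaffold, allow_external=allow_external)
    p = node_params(mcn)
    mode = "extended" if allow_external else "base"
    print(f"{mode} MCN: nodes={sorted(mcn.nodes)} external={sorted(mcn.external)}")
    print(f"  components={p.n_components}")
    for v in sorted(mcn.nodes):
        print(
            f"  {v}: degree={p.degree[v]} clustering={p.clustering[v]:.2f}"
            f" rel_betweenness={p.rel_betweenness[v]:.2f}"
        )

# The base MCN splits into two components (a-c, and the isolated b);
# allowing one external node admits x (adjacent to members a and b),
# reconnecting the module into a single component and giving x the
# highest betweenness — the signature of a linker hub.
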