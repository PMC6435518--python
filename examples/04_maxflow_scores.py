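"""Score component-effect relations by maximum flow on the worked example.

Each pair is scored in isolation: all other component and effect nodes are
removed, and the max flow from the component through the GO layer to the
effect is the relation score z_ij.  GOI arcs let flow detour through
related terms (component c2 reaches effect e1 at 1.0, above its direct
0.6 bottleneck, via the g3-g1 similarity arc).
"""

from trimodenet import maxflow_score, score_matrix, worked_example

net, content = worked_example()
print("arcs:")
for (u, v), cap in sorted(net.arcs.items()):
    print(f"  {u} -> {v}: {cap}")

print("\nz(c2, e1) =", maxflow_score(net, "c2", "e1"))

zm = score_matrix(net)
print("\nflow matrix z:")
print(zm.to_frame())
# Rows are components, columns effects; each entry is the bottleneck-limited
# functional throughput between the pair.
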