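"""Exact parameter-graph sizes of the EMT network.

The 42-dimensional parameter space of the 6-gene, 12-edge EMT circuit
decomposes into finitely many inequality regions.  Their number is the
product of the per-gene factor-graph sizes: over 21 billion in total, about
21 million when every gene is restricted to essential regions.
"""

from switchgraph import (
    ParameterGraph,
    StateSpace,
    enumerate_factor_graph,
    make_emt_network,
    parameter_dimension,
)

net = make_emt_network()
print(f"EMT network: {net.n_nodes()} genes, {net.n_edges()} edges")
print(f"parameter-space dimension: {parameter_dimension(net)}")
print(f"phase-space cells: {StateSpace(net).size}\n")

factors = {g: enumerate_factor_graph(net, g) for g in net.nodes}
for g, fg in factors.items():
    print(
        f"{g:7s}: {len(fg):5d} regions ({len(fg.essential_indices):4d} essential), "
        f"{fg.n_layers:2d} layers"
    )

full = ParameterGraph(net, factors=factors)
essential = ParameterGraph(net, default_mode="essential", factors=factors)
print(f"\nfull parameter graph:      {full.size:,} nodes")
print(f"essential parameter graph: {essential.size:,} nodes")
print(f"reduction factor:          {full.size / essential.size:,.0f}x")
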