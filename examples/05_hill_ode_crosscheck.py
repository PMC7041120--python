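"""Cross-checking combinatorial predictions against a smooth Hill model.

Every inequality region corresponds to real parameter values; steep Hill
functions (here coefficient 50) approximate the switching nonlinearity.
This script instantiates parameters inside the toggle switch's bistable
region, confirms numerically derived wall directions equal the
combinatorial state transition graph, and integrates the ODE from both
predicted attractor cells to show each is a genuine steady state.
"""

from switchgraph import (
    DynamicsEngine,
    ParameterGraph,
    instantiate_parameters,
    make_toggle_switch,
    ode_attractor_check,
)
from switchgraph.fixtures import numeric_stg_edges

net = make_toggle_switch()
pg = ParameterGraph(net)
address = (1, 1)  # the bistable central region
regions = dict(zip(net.nodes, pg.regions(address)))

params = instantiate_parameters(net, regions)
for (src, tgt), (L, U, theta) in sorted(params.edge.items()):
    print(f"edge {src} -> {tgt}: L={L:.3f}  U={U:.3f}  theta={theta:.3f}")

stg = DynamicsEngine(net).stg(pg.regions(address))
combinatorial = set(zip(stg.rows.tolist(), stg.cols.tolist()))
numeric = numeric_stg_edges(net, params)
print(f"\ncombinatorial STG edges == numeric STG edges: {combinatorial == numeric}")

result = ode_attractor_check(net, params, hill_n=50, initial_cells=[(0, 1), (1, 0)])
for start, end in result.items():
    print(f"ODE from cell {start} settles in cell {end}")

print(
    "\nBoth predicted fixed-point cells trap the smooth dynamics: the"
    "\ncombinatorial bistability is realized by the Hill model at these"
    "\nparameter values."
)
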