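"""State transition graphs and Morse graphs."""

import networkx as nx
import numpy as np
import pytest

from switchgraph.dynamics import DynamicsEngine, input_combination, morse_graph
from switchgraph.fixtures import (
    instantiate_parameters,
    numeric_stg_edges,
    random_network,
)
from switchgraph.product import ParameterGraph

# Stable fixed points of all nine toggle-switch parameter nodes, keyed by
# (region of X, region of Y) with regions ordered low < middle < high
# actuation.  Mutual repression: an all-below factor pins its gene at 0, an
# all-above factor drives it high unless repressed, and the doubly middle
# node is the bistable one.
TOGGLE_FPS = {
    (0, 0): [(0, 0)],
    (0, 1): [(0, 1)],
    (0, 2): [(0, 1)],
    (1, 0): [(1, 0)],
    (1, 1): [(0, 1), (1, 0)],
    (1, 2): [(0, 1)],
    (2, 0): [(1, 0)],
    (2, 1): [(1, 0)],
    (2, 2): [(1, 1)],
}


def test_toggle_switch_morse_graphs(toggle):
    pg = ParameterGraph(toggle)
    eng = DynamicsEngine(toggle)
    for addr, expected in TOGGLE_FPS.items():
        mg = eng.morse(pg.regions(addr))
        assert mg.stable_fixed_points() == expected
        assert all(m.annotation == "FP" for m in mg.nodes)


def test_toggle_central_region_is_bistable(toggle):
    pg = ParameterGraph(toggle)
    eng = DynamicsEngine(toggle)
    mg = eng.morse(pg.regions((1, 1)))
    assert sorted(m.label for m in mg.stable_nodes) == ["FP(0,1)", "FP(1,0)"]


def test_input_combination_examples(emt, toggle, emt_factors):
    tog_pg = ParameterGraph(toggle)
    regions = dict(zip(toggle.nodes, tog_pg.regions((1, 1))))
    # at the origin each repressor is below threshold, so both genes read U
    assert input_combination(toggle, regions, "X", (0, 0)) == 1
    assert input_combination(toggle, regions, "Y", (0, 0)) == 1

    emt_pg = ParameterGraph(emt, default_mode="essential", factors=emt_factors)
    regions = dict(zip(emt.nodes, emt_pg.regions((0,) * 6)))
    # Ovol2's single input is the repressing Zeb1 edge: high Zeb1 -> L active
    assert input_combination(emt, regions, "Ovol2", (3, 0, 0, 0, 0, 0)) == 0
    assert input_combination(emt, regions, "Ovol2", (0, 0, 0, 0, 0, 0)) == 1
    # Snail1 reads (TGFb activator, miR34a repressor): TGFb above, miR34a
    # below -> both high levels active
    rank = regions["TGFb"].rank_of_edge()[0]
    cell = [0, 0, 0, 0, rank + 1, 0]
    assert input_combination(emt, regions, "Snail1", tuple(cell)) == 0b11


def test_emt_all_below_address_decays_to_origin(emt, emt_factors):
    pg = ParameterGraph(emt, factors=emt_factors)
    eng = DynamicsEngine(emt)
    mg = eng.morse(pg.regions((0,) * 6))  # first full-mode region = all-below
    assert [m.label for m in mg.nodes] == ["FP(0,0,0,0,0,0)"]
    assert mg.nodes[0].stable


def test_every_face_carries_exactly_one_edge(emt, emt_factors):
    pg = ParameterGraph(emt, default_mode="essential", factors=emt_factors)
    eng = DynamicsEngine(emt)
    space = eng.space
    n_faces = sum(
        space.size // space.shape[i] * (space.shape[i] - 1)
        for i in range(len(space.shape))
    )
    for addr in pg.sample(25, seed=9):
        stg = eng.stg(pg.regions(addr))
        assert len(stg.rows) == n_faces
        # no duplicate directed edges and no two-way faces
        pairs = set(zip(stg.rows.tolist(), stg.cols.tolist()))
        assert len(pairs) == n_faces
        assert not any((b, a) in pairs for a, b in pairs)


def test_morse_graph_is_acyclic_with_a_stable_node(emt, emt_factors):
    pg = ParameterGraph(emt, default_mode="essential", factors=emt_factors)
    eng = DynamicsEngine(emt)
    for addr in pg.sample(25, seed=10):
        mg = eng.morse(pg.regions(addr))
        assert mg.n_stable() >= 1
        g = mg.to_networkx(reduce=False)
        assert nx.is_directed_acyclic_graph(g)
        # stability = no reachable other recurrent component
        for i, m in enumerate(mg.nodes):
            assert m.stable == (g.out_degree(i) == 0)


def test_recurrent_components_match_networkx(emt, emt_factors):
    """Dual route: scipy-based condensation vs a networkx recomputation."""
    pg = ParameterGraph(emt, default_mode="essential", factors=emt_factors)
    eng = DynamicsEngine(emt)
    for addr in pg.sample(5, seed=12):
        stg = eng.stg(pg.regions(addr))
        g = stg.to_networkx()
        expected = set()
        for comp in nx.strongly_connected_components(g):
            sub = g.subgraph(comp)
            if sub.number_of_edges() > 0:
                expected.add(frozenset(comp))
        mg = morse_graph(stg)
        ours = {
            frozenset(stg.space.index(c) for c in m.cells) for m in mg.nodes
        }
        assert ours == expected


def test_combinatorial_stg_equals_numeric_oracle_on_random_networks():
    for seed in range(20):
        net = random_network(seed)
        pg = ParameterGraph(net)
        rng = np.random.default_rng(seed)
        addr = pg.address_from_index(int(rng.integers(pg.size)))
        regions = dict(zip(net.nodes, pg.regions(addr)))
        params = instantiate_parameters(net, regions)
        stg = DynamicsEngine(net).stg(pg.regions(addr))
        combinatorial = set(zip(stg.rows.tolist(), stg.cols.tolist()))
        assert combinatorial == numeric_stg_edges(net, params)


def test_xc_nodes_have_a_constant_coordinate(emt, emt_factors):
    pg = ParameterGraph(emt, default_mode="essential", factors=emt_factors)
    eng = DynamicsEngine(emt)
    seen_xc = 0
    for addr in pg.sample(40, seed=13):
        mg = eng.morse(pg.regions(addr))
        for m in mg.nodes:
            if m.annotation == "XC":
                seen_xc += 1
                coords = np.array(m.cells)
                assert np.any(coords.min(axis=0) == coords.max(axis=0))
                assert not m.stable  # oscillations are never attracting here
    assert seen_xc > 0  # the ensemble does exhibit unstable cycles


def test_malformed_address_is_rejected(emt, emt_factors):
    pg = ParameterGraph(emt, default_mode="essential", factors=emt_factors)
    with pytest.raises(ValueError):
        pg.regions((0,) * 5)
    with pytest.raises(ValueError):
        pg.regions((10**9,) * 6)
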