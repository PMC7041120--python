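"""Factor parameter graph enumeration, realizability, essentiality, layers."""

import numpy as np
import pytest

from switchgraph.factor import (
    FactorRegion,
    UnsupportedLogicError,
    brute_force_regions,
    enumerate_factor_graph,
    is_essential,
    monotone_upsets,
    realizable,
)
from switchgraph.fixtures import derive_regions, instantiate_parameters
from switchgraph.network import parse_network

# The twelve Ovol2 regions: total orders of {L, U} and the two decay-scaled
# thresholds; A-half = theta(Zeb1) below theta(TGFb), B-half reversed.
OVOL2_EXPECTED = [
    "L < U < g*t(Zeb1<-Ovol2) < g*t(TGFb<-Ovol2)",  # A1
    "L < g*t(Zeb1<-Ovol2) < U < g*t(TGFb<-Ovol2)",  # A2
    "g*t(Zeb1<-Ovol2) < L < U < g*t(TGFb<-Ovol2)",  # A3
    "L < g*t(Zeb1<-Ovol2) < g*t(TGFb<-Ovol2) < U",  # A4
    "g*t(Zeb1<-Ovol2) < L < g*t(TGFb<-Ovol2) < U",  # A5
    "g*t(Zeb1<-Ovol2) < g*t(TGFb<-Ovol2) < L < U",  # A6
    "L < U < g*t(TGFb<-Ovol2) < g*t(Zeb1<-Ovol2)",  # B1
    "L < g*t(TGFb<-Ovol2) < U < g*t(Zeb1<-Ovol2)",  # B2
    "g*t(TGFb<-Ovol2) < L < U < g*t(Zeb1<-Ovol2)",  # B3
    "L < g*t(TGFb<-Ovol2) < g*t(Zeb1<-Ovol2) < U",  # B4
    "g*t(TGFb<-Ovol2) < L < g*t(Zeb1<-Ovol2) < U",  # B5
    "g*t(TGFb<-Ovol2) < g*t(Zeb1<-Ovol2) < L < U",  # B6
]


def _network_with_signature(q: int, p: int):
    """A small network giving node G exactly q inputs and p outputs."""
    text = "G : " + "".join(f"(S{e})" for e in range(q)) + "\n"
    for e in range(q):
        text += f"S{e} : (T0)\n"
    for k in range(p):
        text += f"T{k} : (G)\n"
    net = parse_network(text)
    assert net.in_degree("G") == q and net.out_degree("G") == p
    return net


def test_single_in_single_out_node_has_three_regions():
    net = parse_network("A : (B)\nB : (A)")
    fg = enumerate_factor_graph(net, "A")
    assert len(fg) == 3
    strings = {r.inequality_string(net) for r in fg.regions}
    assert strings == {
        "L < U < g*t(B<-A)",
        "L < g*t(B<-A) < U",
        "g*t(B<-A) < L < U",
    }


def test_ovol2_factor_graph_matches_printed_inequality_regions(emt, emt_factors):
    fg = emt_factors["Ovol2"]
    assert len(fg) == 12
    assert [r.inequality_string(emt) for r in fg.regions] == OVOL2_EXPECTED
    # essential subset is exactly {A4, B4}
    assert fg.essential_indices == (3, 9)
    assert fg.n_layers == 5
    assert list(fg.layer_of) == [1, 2, 3, 3, 4, 5] * 2
    # A3 and A4 share a layer under the actuation-count rule
    assert fg.regions[2].layer == fg.regions[3].layer == 3


def test_tgfb_factor_graph_isomorphic_to_ovol2_half(emt_factors):
    import networkx as nx

    tgfb = emt_factors["TGFb"]
    assert len(tgfb) == 6
    assert tgfb.n_layers == 5
    ovol2 = emt_factors["Ovol2"]
    g_t = nx.Graph()
    g_t.add_nodes_from(range(6))
    g_t.add_edges_from((i, j) for i, nbrs in enumerate(tgfb.adjacency) for j in nbrs)
    g_a = nx.Graph()
    g_a.add_nodes_from(range(6))
    g_a.add_edges_from(
        (i, j)
        for i, nbrs in enumerate(ovol2.adjacency[:6])
        for j in nbrs
        if j < 6
    )
    assert nx.is_isomorphic(g_t, g_a)


def test_snail1_and_zeb1_factor_graph_sizes(emt_factors):
    assert len(emt_factors["Snail1"]) == 300
    assert emt_factors["Snail1"].n_layers == 13
    assert len(emt_factors["Zeb1"]) == 4242
    assert emt_factors["Zeb1"].n_layers == 25


def test_realizable_examples(emt_factors):
    # A4 is realizable
    assert realizable(emt_factors["Ovol2"].regions[3])
    # demanding U below a threshold while L is above it contradicts L < U
    assert not realizable(FactorRegion("Ovol2", 1, (0, 1), (1, 0)))
    # two-input cross-constraint: L1*U2 < t1 < U1*L2 and U1*L2 < t2 < L1*U2
    # is an additive contradiction in log space though each row alone is fine
    assert not realizable(FactorRegion("N", 2, (0, 1), (0b1010, 0b1100)))


@pytest.mark.parametrize("q,p", [(1, 1), (1, 2), (2, 1), (2, 2)])
def test_chain_search_equals_brute_force_pattern_enumeration(q, p):
    """The monotone-nested chain search finds exactly the LP-feasible patterns."""
    net = _network_with_signature(q, p)
    fg = enumerate_factor_graph(net, "G")
    chains = {r.above for r in fg.regions if r.order == tuple(range(p))}
    assert chains == set(brute_force_regions(q, p))


def test_essentiality_definition_on_two_input_single_output_node():
    # above set {(U,U)}: both inputs informative -> essential
    assert is_essential(FactorRegion("TGFb", 2, (0,), (0b1000,)))
    # above set {(U,L),(U,U)}: output ignores the second input -> inessential
    assert not is_essential(FactorRegion("TGFb", 2, (0,), (0b1010,)))
    # all-above fails the threshold condition
    assert not is_essential(FactorRegion("TGFb", 2, (0,), (0b1111,)))


def test_essential_regions_are_strict_subset_for_all_emt_genes(emt, emt_factors):
    for g in emt.nodes:
        fg = emt_factors[g]
        assert 0 < len(fg.essential_indices) < len(fg)


def test_input_condition_strictly_shrinks_essential_set(emt, emt_factors):
    """Dropping the every-input-carries-information clause enlarges the set."""
    for g in emt.nodes:
        if emt.in_degree(g) < 2:
            continue
        fg = emt_factors[g]
        nc = 1 << emt.in_degree(g)
        full_mask = (1 << nc) - 1
        only_threshold_condition = {
            i
            for i, r in enumerate(fg.regions)
            if all(m not in (0, full_mask) for m in r.above)
        }
        assert set(fg.essential_indices) < only_threshold_condition


def test_layer_histogram_structure(emt_factors):
    for fg in emt_factors.values():
        counts = np.bincount(fg.layer_of)[1:]
        assert counts.sum() == len(fg)
        n_orders = len({r.order for r in fg.regions})
        # layer 1 holds exactly the all-below region of each threshold order,
        # the top layer exactly the all-above ones
        assert counts[0] == n_orders
        assert counts[-1] == n_orders
        nc = fg.regions[0].n_combos
        for r in fg.regions:
            if r.layer == 1:
                assert all(m == 0 for m in r.above)
            if r.layer == fg.n_layers:
                assert all(m == (1 << nc) - 1 for m in r.above)


def test_every_enumerated_region_is_realizable(emt_factors):
    assert all(realizable(r) for r in emt_factors["Snail1"].regions)


def test_monotone_upsets_counts():
    # Dedekind-type counts for the 1-, 2- and 3-input lattices
    assert len(monotone_upsets(1)) == 3
    assert len(monotone_upsets(2)) == 6
    assert len(monotone_upsets(3)) == 20


def test_sampled_parameters_reproduce_ovol2_inequalities(emt, emt_factors):
    """Random interior points of each Ovol2 region recover its sign pattern."""
    rng = np.random.default_rng(11)
    for region in emt_factors["Ovol2"].regions:
        for _ in range(50):
            params = instantiate_parameters(emt, {"Ovol2": region}, rng=rng)
            assert derive_regions(emt, params)["Ovol2"] == region


def test_nodes_without_inputs_or_outputs_are_unsupported():
    net = parse_network("A : (B)\nB : (A)\nC : (A)")
    with pytest.raises(UnsupportedLogicError):
        enumerate_factor_graph(net, "C")  # C has no outputs


def test_adjacent_regions_differ_by_one_inequality(emt_factors):
    fg = emt_factors["Ovol2"]
    for i, nbrs in enumerate(fg.adjacency):
        for j in nbrs:
            ri, rj = fg.regions[i], fg.regions[j]
            if ri.order == rj.order:
                diff = sum((a ^ b).bit_count() for a, b in zip(ri.above, rj.above))
                assert diff == 1
            else:
                assert ri.above == rj.above
    # A4 and B4 are adjacent (threshold swap with equal sign rows)
    assert 9 in fg.adjacency[3]
    # A2 and B2 are not (their sign rows differ across the swap)
    assert 7 not in fg.adjacency[1]
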