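"""Product parameter graphs: sizes, indexing, modes, and sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from switchgraph.fixtures import make_toggle_switch
from switchgraph.network import parse_network
from switchgraph.product import ParameterGraph, parameter_dimension


def test_toggle_parameter_graph_has_nine_nodes(toggle):
    assert ParameterGraph(toggle).size == 9


def test_parameter_space_dimensions(emt, toggle):
    assert parameter_dimension(emt) == 42  # 6 decay rates + 3 per each of 12 edges
    assert parameter_dimension(toggle) == 8
    assert parameter_dimension(parse_network("X : (X)")) == 4


def test_emt_product_sizes(emt, emt_factors):
    full = ParameterGraph(emt, factors=emt_factors)
    assert full.size == np.prod([len(f) for f in emt_factors.values()], dtype=object)
    assert full.size > 21_000_000_000
    ess = ParameterGraph(emt, default_mode="essential", factors=emt_factors)
    assert 21 * 10**6 <= ess.size < 22 * 10**6  # exactly 21,563,136
    # roughly a thousand-fold reduction
    assert 500 < full.size / ess.size < 2000


def test_x_general_graphs_intersect_in_essential(emt, emt_factors):
    ess = ParameterGraph(emt, default_mode="essential", factors=emt_factors)
    allowed = None
    for gene in ("Ovol2", "Snail1", "TGFb", "Zeb1"):
        pg = ParameterGraph(
            emt, modes={gene: "full"}, default_mode="essential", factors=emt_factors
        )
        sets = {g: set(pg.allowed[g]) for g in emt.nodes}
        allowed = sets if allowed is None else {
            g: allowed[g] & sets[g] for g in emt.nodes
        }
    assert allowed == {g: set(ess.allowed[g]) for g in emt.nodes}


def test_mixed_radix_round_trip(emt, emt_factors):
    pg = ParameterGraph(emt, default_mode="essential", factors=emt_factors)
    rng = np.random.default_rng(3)
    for i in map(int, rng.integers(0, pg.size, size=1000)):
        assert pg.index_from_address(pg.address_from_index(i)) == i
    assert pg.address_from_index(0) == (0,) * 6
    assert pg.address_from_index(pg.size - 1) == tuple(r - 1 for r in pg.radices)
    with pytest.raises(IndexError):
        pg.address_from_index(pg.size)


def test_sampling_is_seed_reproducible(emt, emt_factors):
    pg = ParameterGraph(emt, default_mode="essential", factors=emt_factors)
    assert pg.sample(50, seed=5) == pg.sample(50, seed=5)
    assert pg.sample(50, seed=5) != pg.sample(50, seed=6)


def test_layer_restriction_contract(emt, emt_factors):
    pg = ParameterGraph(
        emt, modes={"TGFb": "full"}, default_mode="essential", factors=emt_factors
    )
    top = emt_factors["TGFb"].n_layers
    gi = emt.index("TGFb")
    for addr in pg.sample(200, seed=2, restrict=("TGFb", top)):
        region = pg.regions(addr)[gi]
        assert region.layer == top
        nc = region.n_combos
        assert all(m == (1 << nc) - 1 for m in region.above)


def test_unrestricted_layer_frequencies_match_layer_sizes(emt, emt_factors):
    """Uniform product sampling projects to the factor's layer-size distribution."""
    pg = ParameterGraph(
        emt, modes={"Ovol2": "full"}, default_mode="essential", factors=emt_factors
    )
    n = 10_000
    addrs = pg.sample(n, seed=4)
    gi = emt.index("Ovol2")
    fg = emt_factors["Ovol2"]
    observed = np.zeros(fg.n_layers + 1)
    for a in addrs:
        observed[fg.layer_of[pg.allowed["Ovol2"][a[gi]]]] += 1
    for lay in range(1, fg.n_layers + 1):
        p = len(fg.indices_in_layer(lay)) / len(fg)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(observed[lay] / n - p) <= 3 * se + 1e-12


def test_empty_restriction_and_unknown_gene_are_rejected(emt, emt_factors):
    pg = ParameterGraph(emt, default_mode="essential", factors=emt_factors)
    with pytest.raises(ValueError, match="empty"):
        # essential Ovol2 regions all sit in layer 3; layer 1 is empty
        pg.sample(5, seed=0, restrict=("Ovol2", 1))
    with pytest.raises(ValueError, match="unknown gene"):
        ParameterGraph(emt, modes={"Nope": "full"}, factors=emt_factors)


def test_exhaustive_iteration_guard(emt, emt_factors, toggle):
    big = ParameterGraph(emt, factors=emt_factors)
    with pytest.raises(RuntimeError, match="work bound"):
        next(big.iter_addresses())
    small = ParameterGraph(toggle)
    assert len(list(small.iter_addresses())) == 9


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(min_value=0, max_value=8))
def test_toggle_index_address_bijection(i):
    pg = ParameterGraph(make_toggle_switch())
    assert pg.index_from_address(pg.address_from_index(i)) == i
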