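"""Shared fixtures: networks, enumerated factor graphs, and sampled ensembles.

The factor-graph enumeration and the 2000-address Morse-graph ensembles are
expensive, so they are computed once per session and shared across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from switchgraph.dynamics import DynamicsEngine
from switchgraph.emt import survey_layers
from switchgraph.factor import enumerate_factor_graph
from switchgraph.fixtures import make_emt_network, make_toggle_switch
from switchgraph.product import ParameterGraph

ENSEMBLE_N = 2000
ENSEMBLE_SEED = 0


@pytest.fixture(scope="session")
def emt():
    return make_emt_network()


@pytest.fixture(scope="session")
def toggle():
    return make_toggle_switch()


@pytest.fixture(scope="session")
def emt_factors(emt):
    return {g: enumerate_factor_graph(emt, g) for g in emt.nodes}


@pytest.fixture(scope="session")
def emt_engine(emt):
    return DynamicsEngine(emt)


def _single_layer(gene, lay, emt, emt_factors, emt_engine):
    survey = survey_layers(
        gene,
        n_per_layer=ENSEMBLE_N,
        seed=ENSEMBLE_SEED,
        net=emt,
        factors=emt_factors,
        engine=emt_engine,
        layers=[lay],
    )
    return survey.layers[0]


@pytest.fixture(scope="session")
def tgfb_top_layer(emt, emt_factors, emt_engine):
    top = emt_factors["TGFb"].n_layers
    return _single_layer("TGFb", top, emt, emt_factors, emt_engine)


@pytest.fixture(scope="session")
def tgfb_bottom_layer(emt, emt_factors, emt_engine):
    return _single_layer("TGFb", 1, emt, emt_factors, emt_engine)


@pytest.fixture(scope="session")
def ovol2_top_layer(emt, emt_factors, emt_engine):
    top = emt_factors["Ovol2"].n_layers
    return _single_layer("Ovol2", top, emt, emt_factors, emt_engine)


@pytest.fixture(scope="session")
def zeb1_bottom_layer(emt, emt_factors, emt_engine):
    return _single_layer("Zeb1", 1, emt, emt_factors, emt_engine)


@pytest.fixture(scope="session")
def snail1_bottom_layer(emt, emt_factors, emt_engine):
    return _single_layer("Snail1", 1, emt, emt_factors, emt_engine)


@pytest.fixture(scope="session")
def essential_sample(emt, emt_factors, emt_engine):
    """Per-address Morse summaries over a uniform essential-ensemble sample."""
    pg = ParameterGraph(emt, default_mode="essential", factors=emt_factors)
    out = []
    for addr in pg.sample(ENSEMBLE_N, seed=ENSEMBLE_SEED):
        mg = emt_engine.morse(pg.regions(addr))
        stable = mg.stable_nodes
        fps = [m.cells[0] for m in stable if m.is_fixed_point()]
        out.append(
            {
                "k": len(stable),
                "only_fp": len(fps) == len(stable),
                "fps": fps,
                "annotations": [m.annotation for m in mg.nodes],
                "stable_flags": [m.stable for m in mg.nodes],
            }
        )
    return out


def _general_sample(gene, emt, emt_factors, emt_engine):
    pg = ParameterGraph(emt, modes={gene: "full"}, default_mode="essential", factors=emt_factors)
    out = []
    for addr in pg.sample(ENSEMBLE_N, seed=ENSEMBLE_SEED):
        mg = emt_engine.morse(pg.regions(addr))
        stable = mg.stable_nodes
        fps = [m.cells[0] for m in stable if m.is_fixed_point()]
        out.append({"k": len(stable), "only_fp": len(fps) == len(stable), "fps": fps})
    return out


@pytest.fixture(scope="session")
def ovol2_general_sample(emt, emt_factors, emt_engine):
    return _general_sample("Ovol2", emt, emt_factors, emt_engine)


@pytest.fixture(scope="session")
def tgfb_general_sample(emt, emt_factors, emt_engine):
    return _general_sample("TGFb", emt, emt_factors, emt_engine)


def binomial_tolerance(p: float, n: int, rounding: float = 0.005) -> float:
    """Three binomial standard errors plus integer-percent rounding slack."""
    return 3.0 * float(np.sqrt(p * (1.0 - p) / n)) + rounding
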