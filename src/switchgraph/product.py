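"""Product parameter graphs: exact sizes, indexing, and uniform sampling.

The parameter graph of a network is the product of the per-gene factor
parameter graphs.  Each product node (a "parameter node") is addressed by a
tuple of per-gene region choices.  Sizes are kept as exact Python integers:
the full EMT product has over twenty billion nodes and is never materialized;
addresses are decoded from big integers by mixed radix, and ensembles are
drawn by independent per-factor uniform choices.

Modes restrict individual factors: ``essential`` keeps only regions in which
every edge of the gene carries information; making exactly one gene ``full``
and the rest ``essential`` yields that gene's "general" parameter graph.
"""

from __future__ import annotations

import math
from typing import Iterator, Mapping, Sequence

import numpy as np

from .factor import FactorParameterGraph, FactorRegion, enumerate_factor_graph
from .network import RegulatoryNetwork

__all__ = ["ParameterGraph", "parameter_dimension", "build_product", "sample_uniform"]

MODES = ("full", "essential")


def parameter_dimension(net: RegulatoryNetwork) -> int:
    """Dimension of real parameter space: one decay rate per node plus
    (low, high, threshold) per edge, i.e. ``n + 3k``."""
    return net.n_nodes() + 3 * net.n_edges()


class ParameterGraph:
    """Product of per-gene factor graphs under a mode map.

    Addresses are tuples of positions into each gene's *allowed* region list
    (mode-relative); :meth:`regions` resolves them to region objects in
    network gene order.
    """

    def __init__(
        self,
        net: RegulatoryNetwork,
        modes: Mapping[str, str] | None = None,
        default_mode: str = "full",
        factors: Mapping[str, FactorParameterGraph] | None = None,
    ):
        self.network = net
        modes = dict(modes or {})
        for g in modes:
            if g not in net.nodes:
                raise ValueError(f"unknown gene {g!r} in modes")
            if modes[g] not in MODES:
                raise ValueError(f"unknown mode {modes[g]!r}")
        if default_mode not in MODES:
            raise ValueError(f"unknown mode {default_mode!r}")
        self.modes = {g: modes.get(g, default_mode) for g in net.nodes}
        self.factors: dict[str, FactorParameterGraph] = {}
        for g in net.nodes:
            fg = factors[g] if factors is not None and g in factors else enumerate_factor_graph(net, g)
            self.factors[g] = fg
        self.allowed: dict[str, tuple[int, ...]] = {}
        for g in net.nodes:
            fg = self.factors[g]
            if self.modes[g] == "essential":
                self.allowed[g] = fg.essential_indices
            else:
                self.allowed[g] = tuple(range(len(fg.regions)))
        self.radices = tuple(len(self.allowed[g]) for g in net.nodes)
        self.size: int = math.prod(self.radices)

    # -- indexing ----------------------------------------------------------
    def address_from_index(self, i: int) -> tuple[int, ...]:
        if not 0 <= i < self.size:
            raise IndexError(f"parameter-node index {i} out of range [0, {self.size})")
        digits = []
        for radix in reversed(self.radices):
            digits.append(int(i % radix))
            i //= radix
        return tuple(reversed(digits))

    def index_from_address(self, address: Sequence[int]) -> int:
        self._check(address)
        i = 0
        for digit, radix in zip(address, self.radices):
            i = i * radix + int(digit)
        return i

    def _check(self, address: Sequence[int]) -> None:
        if len(address) != len(self.radices):
            raise ValueError("address length mismatch")
        for d, radix in zip(address, self.radices):
            if not 0 <= d < radix:
                raise ValueError(f"address component {d} out of range [0, {radix})")

    def regions(self, address: Sequence[int]) -> tuple[FactorRegion, ...]:
        self._check(address)
        return tuple(
            self.factors[g].regions[self.allowed[g][d]]
            for g, d in zip(self.network.nodes, address)
        )

    # -- sampling ----------------------------------------------------------
    def layer_positions(self, gene: str, lay: int) -> tuple[int, ...]:
        """Positions (mode-relative) of ``gene``'s allowed regions in a layer."""
        fg = self.factors[gene]
        return tuple(
            pos for pos, ridx in enumerate(self.allowed[gene]) if fg.layer_of[ridx] == lay
        )

    def sample(
        self,
        n: int,
        seed: int | None = None,
        rng: np.random.Generator | None = None,
        restrict: tuple[str, int] | None = None,
    ) -> list[tuple[int, ...]]:
        """``n`` i.i.d. uniform addresses, optionally with one gene pinned to a layer.

        Uniformity over the product equals independent per-factor uniform
        choices; with ``restrict=(gene, layer)`` the gene's component is
        uniform over its allowed regions in that layer.
        """
        if rng is None:
            rng = np.random.default_rng(seed)
        pools: list[np.ndarray] = []
        for g in self.network.nodes:
            if restrict is not None and restrict[0] == g:
                positions = self.layer_positions(g, restrict[1])
                if not positions:
                    raise ValueError(
                        f"layer {restrict[1]} of {g!r} is empty under mode {self.modes[g]!r}"
                    )
                pools.append(np.array(positions, dtype=np.int64))
            else:
                pools.append(np.arange(self.radices[self.network.index(g)], dtype=np.int64))
        draws = [pool[rng.integers(0, len(pool), size=n)] for pool in pools]
        return [tuple(int(d[i]) for d in draws) for i in range(n)]

    def iter_addresses(self, force: bool = False, work_bound: int = 10**6) -> Iterator[tuple[int, ...]]:
        """Exhaustive address iterator, guarded against cluster-scale products."""
        if self.size > work_bound and not force:
            raise RuntimeError(
                f"exhaustive iteration over {self.size} parameter nodes exceeds the "
                f"work bound {work_bound}; pass force=True to override"
            )
        for i in range(self.size):
            yield self.address_from_index(i)

    def describe(self) -> dict:
        return {
            "modes": dict(self.modes),
            "factor_sizes": {g: len(self.allowed[g]) for g in self.network.nodes},
            "size": self.size,
        }


def build_product(
    net: RegulatoryNetwork,
    modes: Mapping[str, str] | None = None,
    default_mode: str = "full",
    factors: Mapping[str, FactorParameterGraph] | None = None,
) -> ParameterGraph:
    """Product parameter graph with exact big-integer size."""
    return ParameterGraph(net, modes=modes, default_mode=default_mode, factors=factors)


def sample_uniform(
    pg: ParameterGraph,
    n: int,
    seed: int | None = None,
    restrict: tuple[str, int] | None = None,
) -> list[tuple[int, ...]]:
    """Seed-reproducible uniform sample of parameter-node addresses."""
    return pg.sample(n, seed=seed, restrict=restrict)
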