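"""Factor parameter graphs: realizable inequality regions of a single node.

For a node with ``q`` product inputs and ``p`` output thresholds, a region of
its slice of parameter space is determined by (i) an ordering of the ``p``
actuation thresholds on its axis and (ii), for each threshold and each of the
``2^q`` low/high input combinations, whether the production value Lambda
(the product of the chosen per-edge levels) lies above or below the
decay-scaled threshold ``gamma * theta``.

Realizability of such a sign pattern is decided exactly in log space: products
become sums, each ``gamma * theta`` becomes a free variable, and the open
system of strict inequalities is feasible iff a common slack margin can be
made strictly positive, which is a small linear program.

The enumeration never walks the raw ``2^(p * 2^q)`` pattern space: because
``L < U`` per edge, the "above" set of each threshold must be an up-set
(monotone cut) of the Boolean input lattice, and the ``p`` up-sets must be
nested; only those chains are generated and then LP-filtered.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import linprog

from .network import RegulatoryNetwork

MARGIN_TOL = 1e-9

__all__ = [
    "FactorRegion",
    "FactorParameterGraph",
    "UnsupportedLogicError",
    "realizable",
    "is_essential",
    "layer",
    "enumerate_factor_graph",
    "monotone_upsets",
    "brute_force_regions",
]


class UnsupportedLogicError(ValueError):
    """Raised for nodes outside the pure-product scope (no inputs / no outputs)."""


@dataclass(frozen=True)
class FactorRegion:
    """One node of a factor parameter graph.

    ``order`` is the permutation of the node's out-edges by ascending
    threshold: ``order[k]`` is the (0-based) out-edge index whose threshold
    has rank ``k``.  ``above[k]`` is a bitmask over the ``2^q`` input
    combinations; bit ``c`` is set iff Lambda at combination ``c`` exceeds
    the decay-scaled rank-``k`` threshold.  Combination bit ``e`` set means
    the high level ``U`` is chosen for input edge ``e`` (edge order =
    declaration order of the node's inputs).
    """

    gene: str
    n_inputs: int
    order: tuple[int, ...]
    above: tuple[int, ...]

    @property
    def n_outputs(self) -> int:
        return len(self.order)

    @property
    def n_combos(self) -> int:
        return 1 << self.n_inputs

    @property
    def pattern_int(self) -> int:
        val = 0
        for k, mask in enumerate(self.above):
            val |= mask << (k * self.n_combos)
        return val

    @property
    def layer(self) -> int:
        """1 + number of (threshold, combination) pairs with Lambda above."""
        return 1 + sum(int(m).bit_count() for m in self.above)

    def rank_of_edge(self) -> tuple[int, ...]:
        """Inverse of ``order``: threshold rank of each out-edge index."""
        inv = [0] * len(self.order)
        for k, e in enumerate(self.order):
            inv[e] = k
        return tuple(inv)

    def above_matrix(self) -> np.ndarray:
        """Boolean array of shape ``(p, 2^q)``: entry ``[k, c]`` = Lambda above."""
        p, nc = self.n_outputs, self.n_combos
        mat = np.zeros((p, nc), dtype=bool)
        for k, mask in enumerate(self.above):
            for c in range(nc):
                if mask >> c & 1:
                    mat[k, c] = True
        return mat

    def is_essential(self) -> bool:
        return is_essential(self)

    def inequality_string(self, net: RegulatoryNetwork) -> str:
        """Human-readable total order of ``L``, ``U`` and the scaled thresholds.

        Only single-input nodes admit a total order of all the defining
        quantities (with more inputs the Lambda products are incomparable).
        """
        if self.n_inputs != 1:
            raise UnsupportedLogicError(
                "inequality strings are only rendered for single-input nodes"
            )
        outs = net.outputs(self.gene)
        # position of L / U = number of thresholds each value exceeds
        pos = {"L": 0, "U": 0}
        for mask in self.above:
            if mask & 1:  # combo 0 = L
                pos["L"] += 1
            if mask >> 1 & 1:  # combo 1 = U
                pos["U"] += 1
        items: list[tuple[float, int, str]] = [
            (pos["L"], 0, "L"),
            (pos["U"], 1, "U"),
        ]
        for k, edge_idx in enumerate(self.order):
            e = outs[edge_idx]
            items.append((k + 0.5, 0, f"g*t({e.target}<-{e.source})"))
        items.sort()
        return " < ".join(name for _, _, name in items)


# ---------------------------------------------------------------------------
# monotone structure of the input-combination lattice
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def monotone_upsets(q: int) -> tuple[int, ...]:
    """All up-sets of the Boolean lattice ``{L,U}^q`` as bitmasks over combos.

    Bit ``c`` of a mask marks combination ``c`` (binary over edges, 1 = U) as
    a member.  An up-set is closed under raising any input from L to U.
    """
    n = 1 << q
    out = []
    for mask in range(1 << n):
        ok = True
        for c in range(n):
            if mask >> c & 1:
                for e in range(q):
                    sup = c | (1 << e)
                    if not mask >> sup & 1:
                        ok = False
                        break
            if not ok:
                break
        if ok:
            out.append(mask)
    return tuple(out)


def _combo_value_rows(q: int) -> np.ndarray:
    """Coefficient rows of log-Lambda per combination over variables (l_1..l_q, u_1..u_q)."""
    n = 1 << q
    rows = np.zeros((n, 2 * q))
    for c in range(n):
        for e in range(q):
            if c >> e & 1:
                rows[c, q + e] = 1.0  # u_e
            else:
                rows[c, e] = 1.0  # l_e
    return rows


def _slack_lp(q: int, p: int, masks: tuple[int, ...]):
    """Maximize the common slack margin of the log-linear open system.

    Variables: ``l_1..l_q, u_1..u_q, tau_1..tau_p, m`` (all free, m <= 1).
    Constraints (all strict in the original system, with slack ``m``):
    ``u_e - l_e >= m``, ``tau_{k+1} - tau_k >= m`` and, per (threshold k,
    combination c), ``lam(c) - tau_k >= m`` if c is above else
    ``tau_k - lam(c) >= m``.  Returns the scipy result; the optimal ``m`` is
    strictly positive iff the region is realizable.
    """
    nvar = 2 * q + p + 1
    m_idx = nvar - 1
    lam = _combo_value_rows(q)
    rows = []
    for e in range(q):  # l_e - u_e + m <= 0
        r = np.zeros(nvar)
        r[e] = 1.0
        r[q + e] = -1.0
        r[m_idx] = 1.0
        rows.append(r)
    for k in range(p - 1):  # tau_k - tau_{k+1} + m <= 0
        r = np.zeros(nvar)
        r[2 * q + k] = 1.0
        r[2 * q + k + 1] = -1.0
        r[m_idx] = 1.0
        rows.append(r)
    nc = 1 << q
    for k in range(p):
        mask = masks[k]
        for c in range(nc):
            r = np.zeros(nvar)
            if mask >> c & 1:  # tau_k - lam(c) + m <= 0
                r[2 * q + k] = 1.0
                r[: 2 * q] = -lam[c]
            else:  # lam(c) - tau_k + m <= 0
                r[2 * q + k] = -1.0
                r[: 2 * q] = lam[c]
            r[m_idx] = 1.0
            rows.append(r)
    A = np.vstack(rows)
    b = np.zeros(len(rows))
    cvec = np.zeros(nvar)
    cvec[m_idx] = -1.0
    bounds = [(None, None)] * (nvar - 1) + [(None, 1.0)]
    res = linprog(cvec, A_ub=A, b_ub=b, bounds=bounds, method="highs")
    return res


@lru_cache(maxsize=None)
def _chain_realizable(q: int, p: int, masks: tuple[int, ...]) -> bool:
    res = _slack_lp(q, p, masks)
    return bool(res.status == 0 and res.x[-1] > MARGIN_TOL)


def realizable(spec: FactorRegion) -> bool:
    """Whether positive parameters exist satisfying every strict inequality.

    Decided by the log-space slack LP; does not presuppose monotonicity or
    nesting of the sign pattern (non-monotone patterns come out infeasible).
    """
    if spec.n_inputs == 0 or spec.n_outputs == 0:
        raise UnsupportedLogicError("nodes need at least one input and one output")
    return _chain_realizable(spec.n_inputs, spec.n_outputs, tuple(spec.above))


@lru_cache(maxsize=None)
def _feasible_chains(q: int, p: int) -> tuple[tuple[int, ...], ...]:
    """All realizable nested up-set chains for the (q inputs, p outputs) signature."""
    upsets = monotone_upsets(q)
    chains: list[tuple[int, ...]] = []

    def extend(prefix: tuple[int, ...]) -> None:
        if len(prefix) == p:
            if _chain_realizable(q, p, prefix):
                chains.append(prefix)
            return
        cap = prefix[-1] if prefix else (1 << (1 << q)) - 1
        for s in upsets:
            if s & ~cap == 0:  # s subset of previous (nesting)
                extend(prefix + (s,))

    extend(())
    return tuple(chains)


def is_essential(spec: FactorRegion) -> bool:
    """Whether every out-edge and every in-edge of the region carries information.

    (a) each threshold has at least one combination above and one below;
    (b) for each input edge, toggling it between L and U changes the sign
    column of at least one combination pair.  Regions failing either reduce
    the network's dynamics to those of a subnetwork.
    """
    nc = spec.n_combos
    full = (1 << nc) - 1
    for mask in spec.above:
        if mask == 0 or mask == full:
            return False
    for e in range(spec.n_inputs):
        informative = False
        for c in range(nc):
            if c >> e & 1:
                continue
            c_hi = c | (1 << e)
            for mask in spec.above:
                if (mask >> c & 1) != (mask >> c_hi & 1):
                    informative = True
                    break
            if informative:
                break
        if not informative:
            return False
    return True


def layer(spec: FactorRegion) -> int:
    """Layer = 1 + count of (threshold, combination) entries with Lambda above.

    Groups the factor graph by the number of actuation inequalities satisfied,
    a proxy for the node's qualitative expression level; the all-below
    regions form layer 1 and the all-above regions the top layer.
    """
    return spec.layer


class FactorParameterGraph:
    """Canonically ordered realizable regions of one node, with adjacency.

    Two regions are adjacent iff their defining inequality sets differ in the
    sign of exactly one inequality: either a single (threshold, combination)
    entry flips with the threshold order unchanged, or two consecutive
    thresholds with identical sign rows swap ranks.
    """

    def __init__(self, net: RegulatoryNetwork, gene: str, regions: tuple[FactorRegion, ...]):
        self.network = net
        self.gene = gene
        self.regions = regions
        self._index = {(r.order, r.above): i for i, r in enumerate(regions)}
        self.layer_of = np.array([r.layer for r in regions], dtype=np.int64)
        self.n_layers = int(self.layer_of.max())
        self.essential_indices = tuple(
            i for i, r in enumerate(regions) if is_essential(r)
        )
        self.adjacency = self._build_adjacency()

    def __len__(self) -> int:
        return len(self.regions)

    def indices_in_layer(self, lay: int) -> tuple[int, ...]:
        return tuple(int(i) for i in np.flatnonzero(self.layer_of == lay))

    def _build_adjacency(self) -> tuple[frozenset[int], ...]:
        adj: list[set[int]] = [set() for _ in self.regions]
        p = self.regions[0].n_outputs if self.regions else 0
        nc = self.regions[0].n_combos if self.regions else 0
        for i, r in enumerate(self.regions):
            # single sign flip, same threshold order
            for k in range(p):
                for c in range(nc):
                    flipped = list(r.above)
                    flipped[k] ^= 1 << c
                    j = self._index.get((r.order, tuple(flipped)))
                    if j is not None:
                        adj[i].add(j)
                        adj[j].add(i)
            # adjacent transposition of equal-sign consecutive thresholds
            for k in range(p - 1):
                if r.above[k] == r.above[k + 1]:
                    new_order = list(r.order)
                    new_order[k], new_order[k + 1] = new_order[k + 1], new_order[k]
                    j = self._index.get((tuple(new_order), r.above))
                    if j is not None and j != i:
                        adj[i].add(j)
                        adj[j].add(i)
        return tuple(frozenset(s) for s in adj)

    def to_json(self) -> str:
        payload = {
            "gene": self.gene,
            "n_regions": len(self.regions),
            "n_layers": self.n_layers,
            "regions": [
                {
                    "index": i,
                    "order": list(r.order),
                    "above": [int(m) for m in r.above],
                    "layer": int(r.layer),
                    "essential": i in set(self.essential_indices),
                    "adjacent": sorted(self.adjacency[i]),
                    **(
                        {"inequalities": r.inequality_string(self.network)}
                        if r.n_inputs == 1
                        else {}
                    ),
                }
                for i, r in enumerate(self.regions)
            ],
        }
        return json.dumps(payload, indent=2)


def enumerate_factor_graph(net: RegulatoryNetwork, gene: str) -> FactorParameterGraph:
    """All realizable regions of ``gene``'s factor parameter graph.

    Canonical order: threshold orderings lexicographic, then sign pattern as
    an ascending integer; this fixes stable region indices across runs.
    """
    q = net.in_degree(gene)
    p = net.out_degree(gene)
    if q == 0 or p == 0:
        raise UnsupportedLogicError(
            f"node {gene!r} has {q} inputs and {p} outputs; factor graphs need >=1 of each"
        )
    chains = sorted(_feasible_chains(q, p), key=lambda ch: _pattern_int(ch, 1 << q))
    regions = []
    for order in sorted(itertools.permutations(range(p))):
        for ch in chains:
            regions.append(FactorRegion(gene, q, order, ch))
    return FactorParameterGraph(net, gene, tuple(regions))


def _pattern_int(masks: tuple[int, ...], nc: int) -> int:
    val = 0
    for k, m in enumerate(masks):
        val |= m << (k * nc)
    return val


def brute_force_regions(q: int, p: int) -> tuple[tuple[int, ...], ...]:
    """Oracle: LP-filter *all* raw sign patterns, ignoring monotonicity/nesting.

    Exponential in ``p * 2^q``; intended for signatures with at most two
    inputs and two outputs as an independent check of the chain search.
    """
    nc = 1 << q
    full = 1 << nc
    out = []
    for masks in itertools.product(range(full), repeat=p):
        if _chain_realizable(q, p, tuple(masks)):
            out.append(tuple(masks))
    return tuple(sorted(out, key=lambda ch: _pattern_int(ch, nc)))
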