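"""Regulatory networks with pure-product logic and their discretized phase space.

A regulatory network is a signed directed graph: an edge ``j -> i`` activates
and ``j -| i`` represses target ``i``.  Each node's production term is the
product of one step function per input edge (Glass-type switching system),
so the phase space splits into a finite grid of boxes ("cells") by the
actuation thresholds that each node's out-edges place on its concentration
axis.  A node with ``p`` out-edges carries ``p`` thresholds and is discretized
into the states ``0..p``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

ACTIVATION = 1
REPRESSION = -1

__all__ = [
    "Edge",
    "NetworkSpecError",
    "RegulatoryNetwork",
    "StateSpace",
    "parse_network",
]


@dataclass(frozen=True)
class Edge:
    """A signed regulatory interaction from ``source`` onto ``target``."""

    source: str
    target: str
    sign: int  # ACTIVATION or REPRESSION

    def __post_init__(self) -> None:
        if self.sign not in (ACTIVATION, REPRESSION):
            raise ValueError(f"edge sign must be +1 or -1, got {self.sign}")

    def __str__(self) -> str:
        arrow = "->" if self.sign == ACTIVATION else "-|"
        return f"{self.source} {arrow} {self.target}"


class NetworkSpecError(ValueError):
    """Raised when a network specification is malformed or violates model assumptions."""


class RegulatoryNetwork:
    """Signed directed graph with product logic per node.

    Node order is declaration order and fixes the coordinate order of the
    phase space and of all reported state labels.  Input edges of a node are
    kept in declaration order (the order of the factors in its logic line);
    output edges are canonically ordered by the target's position in the node
    order, which fixes the identity of each node's thresholds.
    """

    def __init__(self, nodes: Sequence[str], inputs: dict[str, Sequence[Edge]]):
        self._nodes = tuple(nodes)
        if len(set(self._nodes)) != len(self._nodes):
            raise NetworkSpecError("duplicate node names")
        node_set = set(self._nodes)
        seen_pairs: set[tuple[str, str]] = set()
        self._inputs: dict[str, tuple[Edge, ...]] = {}
        for name in self._nodes:
            edges = tuple(inputs.get(name, ()))
            for e in edges:
                if e.target != name:
                    raise NetworkSpecError(f"edge {e} listed under node {name}")
                if e.source not in node_set:
                    raise NetworkSpecError(f"undeclared regulator {e.source!r} of {name!r}")
                if (e.source, e.target) in seen_pairs:
                    raise NetworkSpecError(f"duplicate edge {e}")
                if e.source == e.target and e.sign == REPRESSION:
                    raise NetworkSpecError(
                        f"negative self-regulation on {name!r} is not admitted"
                    )
                seen_pairs.add((e.source, e.target))
            self._inputs[name] = edges
        self._index = {g: k for k, g in enumerate(self._nodes)}
        # outputs ordered by target position: threshold rank identity
        self._outputs: dict[str, tuple[Edge, ...]] = {g: () for g in self._nodes}
        for g in self._nodes:
            outs = [e for tgt in self._nodes for e in self._inputs[tgt] if e.source == g]
            self._outputs[g] = tuple(sorted(outs, key=lambda e: self._index[e.target]))

    # -- basic accessors ---------------------------------------------------
    @property
    def nodes(self) -> tuple[str, ...]:
        return self._nodes

    @property
    def edges(self) -> tuple[Edge, ...]:
        return tuple(e for g in self._nodes for e in self._inputs[g])

    def index(self, gene: str) -> int:
        return self._index[gene]

    def inputs(self, gene: str) -> tuple[Edge, ...]:
        return self._inputs[gene]

    def outputs(self, gene: str) -> tuple[Edge, ...]:
        return self._outputs[gene]

    def in_degree(self, gene: str) -> int:
        return len(self._inputs[gene])

    def out_degree(self, gene: str) -> int:
        return len(self._outputs[gene])

    def n_nodes(self) -> int:
        return len(self._nodes)

    def n_edges(self) -> int:
        return sum(len(v) for v in self._inputs.values())

    # -- serialization -----------------------------------------------------
    def to_spec_text(self) -> str:
        lines = []
        for g in self._nodes:
            factors = "".join(
                f"({'~' if e.sign == REPRESSION else ''}{e.source})" for e in self._inputs[g]
            )
            lines.append(f"{g} : {factors}")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {
                "nodes": list(self._nodes),
                "edges": [
                    {"source": e.source, "target": e.target, "sign": e.sign}
                    for e in self.edges
                ],
            },
            indent=2,
        )

    def __repr__(self) -> str:
        return f"RegulatoryNetwork({len(self._nodes)} nodes, {self.n_edges()} edges)"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        return self._nodes == other._nodes and self._inputs == other._inputs

    def __hash__(self) -> int:
        return hash((self._nodes, tuple(self._inputs[g] for g in self._nodes)))


_LINE_RE = re.compile(r"^\s*(?P<target>[\w.+-]+)\s*:\s*(?P<body>.*?)\s*$")
_FACTOR_RE = re.compile(r"\(\s*(~?)\s*([\w.+-]+)\s*\)")


def parse_network(text: str) -> RegulatoryNetwork:
    """Parse a network-spec string into a validated :class:`RegulatoryNetwork`.

    One line per node, ``Target : (Reg1)(~Reg2)...`` with ``~`` marking
    repression; the factors multiply.  ``#`` starts a comment; blank lines are
    ignored.  Rejects duplicate nodes/edges, undeclared regulators, and
    negative self-edges, naming the offending line.
    """
    nodes: list[str] = []
    inputs: dict[str, list[Edge]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _LINE_RE.match(line)
        if m is None:
            raise NetworkSpecError(f"line {lineno}: cannot parse {raw!r}")
        target = m.group("target")
        if target in inputs:
            raise NetworkSpecError(f"line {lineno}: duplicate node {target!r}")
        body = m.group("body")
        factors = _FACTOR_RE.findall(body)
        if _FACTOR_RE.sub("", body).strip():
            raise NetworkSpecError(f"line {lineno}: trailing junk in {raw!r}")
        edges = []
        for tilde, source in factors:
            sign = REPRESSION if tilde else ACTIVATION
            if source == target and sign == REPRESSION:
                raise NetworkSpecError(
                    f"line {lineno}: negative self-regulation of {target!r}"
                )
            edges.append(Edge(source, target, sign))
        nodes.append(target)
        inputs[target] = edges
    if not nodes:
        raise NetworkSpecError("empty network specification")
    try:
        return RegulatoryNetwork(nodes, {g: tuple(v) for g, v in inputs.items()})
    except NetworkSpecError:
        raise


class StateSpace:
    """Grid of phase-space cells of a network.

    The state of node ``i`` counts how many of its thresholds lie below its
    concentration; a cell label is the vector of these counts, one per node,
    in network node order.
    """

    def __init__(self, net: RegulatoryNetwork):
        self.network = net
        self.shape = tuple(net.out_degree(g) + 1 for g in net.nodes)
        self.size = int(np.prod(self.shape))
        self._strides = np.array(
            [int(np.prod(self.shape[i + 1 :])) for i in range(len(self.shape))], dtype=np.int64
        )

    def __len__(self) -> int:
        return self.size

    def cells(self) -> np.ndarray:
        """All cell labels as an array of shape ``(size, n_nodes)`` in index order."""
        grids = np.indices(self.shape).reshape(len(self.shape), -1).T
        return np.ascontiguousarray(grids, dtype=np.int64)

    def index(self, cell: Sequence[int]) -> int:
        self._check(cell)
        return int(np.dot(np.asarray(cell, dtype=np.int64), self._strides))

    def label(self, index: int) -> tuple[int, ...]:
        if not 0 <= index < self.size:
            raise ValueError(f"cell index {index} out of range")
        out = []
        for dim, stride in zip(self.shape, self._strides):
            out.append(int(index // stride) % dim)
        return tuple(out)

    def _check(self, cell: Sequence[int]) -> None:
        if len(cell) != len(self.shape):
            raise ValueError(f"cell label {cell} has wrong length")
        for v, dim in zip(cell, self.shape):
            if not 0 <= v < dim:
                raise ValueError(f"cell label {tuple(cell)} out of range for shape {self.shape}")

    def neighbors(self, cell: Sequence[int]) -> list[tuple[tuple[int, ...], int, int]]:
        """Face-adjacent cells of ``cell``.

        Returns triples ``(neighbor, axis, threshold_rank)`` where the shared
        face lies in direction ``axis`` at the axis's threshold of the given
        rank (0-based in the node's threshold ordering).
        """
        self._check(cell)
        cell = tuple(int(v) for v in cell)
        out = []
        for i, dim in enumerate(self.shape):
            if cell[i] + 1 < dim:
                up = cell[:i] + (cell[i] + 1,) + cell[i + 1 :]
                out.append((up, i, cell[i]))
            if cell[i] > 0:
                down = cell[:i] + (cell[i] - 1,) + cell[i + 1 :]
                out.append((down, i, cell[i] - 1))
        return out

    def iter_labels(self) -> Iterator[tuple[int, ...]]:
        for idx in range(self.size):
            yield self.label(idx)

    def to_json(self) -> str:
        return json.dumps(
            {"nodes": list(self.network.nodes), "shape": list(self.shape), "size": self.size}
        )


def state_space(net: RegulatoryNetwork) -> StateSpace:
    """Discretized phase space of ``net`` (one state range per node)."""
    return StateSpace(net)
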