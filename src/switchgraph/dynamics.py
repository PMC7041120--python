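"""Combinatorial dynamics: state transition graphs and Morse graphs.

Given one inequality region per gene, every face of the phase-space grid is
crossed in exactly one direction determined purely by the sign pattern: on a
face of the ``x_i`` axis at threshold rank ``k``, the flow points upward from
the lower cell iff the production value of gene ``i`` at that cell's input
combination lies above the decay-scaled threshold.  Cells whose face edges
are all incoming are attracting and carry a self-edge.  The Morse graph is
the condensation of the state transition graph onto its recurrent components
(mutually reachable sets containing an edge), annotated FP (a single
attracting cell), XC (a cycle with at least one constant coordinate), or FC
(a full cycle), and a component is stable iff no other recurrent component
is reachable from it.

Construction is allocation-light numpy over the whole grid; strongly
connected components come from scipy's sparse graph machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .factor import FactorRegion
from .network import ACTIVATION, RegulatoryNetwork, StateSpace

__all__ = [
    "DynamicsEngine",
    "StateTransitionGraph",
    "MorseNode",
    "MorseGraph",
    "input_combination",
    "build_stg",
    "morse_graph",
    "stable_fixed_points",
]


class DynamicsEngine:
    """Per-network precomputation for fast repeated STG/Morse evaluation."""

    def __init__(self, net: RegulatoryNetwork):
        self.network = net
        self.space = StateSpace(net)
        self.cells = self.space.cells()  # (N, n)
        self.n = net.n_nodes()
        self.p = np.array([net.out_degree(g) for g in net.nodes], dtype=np.int64)
        self.strides = self.space._strides
        # per gene: list of (regulator index, activating?, regulator out-edge index)
        self.input_info: list[list[tuple[int, bool, int]]] = []
        for g in net.nodes:
            info = []
            for e in net.inputs(g):
                j = net.index(e.source)
                out_idx = net.outputs(e.source).index(e)
                info.append((j, e.sign == ACTIVATION, out_idx))
            self.input_info.append(info)
        self._idx = np.arange(self.space.size, dtype=np.int64)

    # -- per-address machinery --------------------------------------------
    def combos(self, regions: dict[str, FactorRegion] | tuple[FactorRegion, ...]) -> np.ndarray:
        """Input-combination index of every gene in every cell, shape (N, n)."""
        regions = self._as_tuple(regions)
        ranks = [r.rank_of_edge() for r in regions]
        out = np.zeros((self.space.size, self.n), dtype=np.int64)
        for i in range(self.n):
            acc = np.zeros(self.space.size, dtype=np.int64)
            for bit, (j, activating, out_idx) in enumerate(self.input_info[i]):
                above = self.cells[:, j] > ranks[j][out_idx]
                chooses_U = above if activating else ~above
                acc |= chooses_U.astype(np.int64) << bit
            out[:, i] = acc
        return out

    def _as_tuple(self, regions) -> tuple[FactorRegion, ...]:
        if isinstance(regions, dict):
            return tuple(regions[g] for g in self.network.nodes)
        return tuple(regions)

    def _directions(self, regions: tuple[FactorRegion, ...]):
        """Boolean (N, n) arrays: outgoing up-face and down-face crossings per cell."""
        combos = self.combos(regions)
        N = self.space.size
        up = np.zeros((N, self.n), dtype=bool)
        down = np.zeros((N, self.n), dtype=bool)
        for i in range(self.n):
            if self.p[i] == 0:
                continue
            P = regions[i].above_matrix()  # (p_i, 2^q)
            s_i = self.cells[:, i]
            has_up = s_i < self.p[i]
            k_up = np.where(has_up, s_i, 0)
            up[:, i] = has_up & P[k_up, combos[:, i]]
            has_down = s_i > 0
            k_down = np.where(has_down, s_i - 1, 0)
            down[:, i] = has_down & ~P[k_down, combos[:, i]]
        return up, down

    def stg(self, regions) -> "StateTransitionGraph":
        regions = self._as_tuple(regions)
        up, down = self._directions(regions)
        rows_list, cols_list = [], []
        for i in range(self.n):
            src = self._idx[up[:, i]]
            rows_list.append(src)
            cols_list.append(src + self.strides[i])
            src = self._idx[down[:, i]]
            rows_list.append(src)
            cols_list.append(src - self.strides[i])
        rows = np.concatenate(rows_list)
        cols = np.concatenate(cols_list)
        outdeg = up.sum(axis=1) + down.sum(axis=1)
        self_loops = self._idx[outdeg == 0]
        if not self.network.edges or all(
            e.source != e.target for e in self.network.edges
        ):
            # without self-regulation the production term is constant across
            # every face, so each face must carry exactly one directed edge
            n_faces = sum(
                self.space.size // self.space.shape[i] * (self.space.shape[i] - 1) * 1
                for i in range(self.n)
            )
            assert len(rows) == n_faces, "face direction rule violated"
        return StateTransitionGraph(self.space, rows, cols, self_loops)

    def morse(self, regions) -> "MorseGraph":
        return morse_graph(self.stg(regions))


@dataclass
class StateTransitionGraph:
    """Directed graph on the phase-space cells (edges as index arrays)."""

    space: StateSpace
    rows: np.ndarray
    cols: np.ndarray
    self_loops: np.ndarray  # cells whose face edges are all incoming

    def n_edges(self) -> int:
        return len(self.rows) + len(self.self_loops)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(range(self.space.size))
        g.add_edges_from(zip(self.rows.tolist(), self.cols.tolist()))
        g.add_edges_from((int(i), int(i)) for i in self.self_loops)
        return g

    def edges_as_labels(self) -> set[tuple[tuple[int, ...], tuple[int, ...]]]:
        lab = self.space.label
        out = {(lab(int(r)), lab(int(c))) for r, c in zip(self.rows, self.cols)}
        out |= {(lab(int(i)), lab(int(i))) for i in self.self_loops}
        return out


@dataclass(frozen=True)
class MorseNode:
    cells: tuple[tuple[int, ...], ...]
    annotation: str  # 'FP', 'XC' or 'FC'
    stable: bool

    @property
    def label(self) -> str:
        if self.annotation == "FP":
            return "FP(" + ",".join(str(v) for v in self.cells[0]) + ")"
        return self.annotation

    def is_fixed_point(self) -> bool:
        return self.annotation == "FP"


class MorseGraph:
    """Acyclic condensation of an STG onto its recurrent components.

    ``edges`` holds the full reachability relation between recurrent
    components; a transitive reduction for display is available via
    :meth:`to_networkx`.
    """

    def __init__(self, nodes: list[MorseNode], edges: set[tuple[int, int]]):
        self.nodes = nodes
        self.edges = edges

    @property
    def stable_nodes(self) -> list[MorseNode]:
        return [m for m in self.nodes if m.stable]

    def stable_fixed_points(self) -> list[tuple[int, ...]]:
        """Cell labels of the stable FP nodes, in network gene order."""
        return sorted(m.cells[0] for m in self.stable_nodes if m.is_fixed_point())

    def n_stable(self) -> int:
        return sum(1 for m in self.nodes if m.stable)

    def annotations(self) -> list[str]:
        return [m.label for m in self.nodes]

    def to_networkx(self, reduce: bool = True):
        import networkx as nx

        g = nx.DiGraph()
        for i, m in enumerate(self.nodes):
            g.add_node(i, label=m.label, stable=m.stable)
        g.add_edges_from(self.edges)
        if reduce and g.number_of_edges():
            red = nx.transitive_reduction(g)
            for i in red.nodes:
                red.nodes[i].update(g.nodes[i])
            return red
        return g

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "nodes": [
                    {"label": m.label, "stable": m.stable, "annotation": m.annotation}
                    for m in self.nodes
                ],
                "edges": sorted(self.edges),
            },
            indent=2,
        )


def morse_graph(stg: StateTransitionGraph) -> MorseGraph:
    """Condense an STG onto its recurrent components with FP/XC/FC annotations."""
    N = stg.space.size
    adj = csr_matrix(
        (np.ones(len(stg.rows), dtype=np.int8), (stg.rows, stg.cols)), shape=(N, N)
    )
    n_comp, labels = connected_components(adj, directed=True, connection="strong")
    sizes = np.bincount(labels, minlength=n_comp)
    has_self = np.zeros(n_comp, dtype=bool)
    has_self[labels[stg.self_loops]] = True
    recurrent = (sizes > 1) | has_self

    lab_r = labels[stg.rows]
    lab_c = labels[stg.cols]
    cross = lab_r != lab_c
    pair_codes = np.unique(lab_r[cross].astype(np.int64) * n_comp + lab_c[cross])
    cond_adj: dict[int, list[int]] = {}
    has_out = np.zeros(n_comp, dtype=bool)
    for code in pair_codes:
        a, b = divmod(int(code), n_comp)
        cond_adj.setdefault(a, []).append(b)
        has_out[a] = True

    rec_ids = np.flatnonzero(recurrent)
    rec_pos = {int(c): i for i, c in enumerate(rec_ids)}
    cells_by_comp: dict[int, list[int]] = {int(c): [] for c in rec_ids}
    for idx in np.flatnonzero(np.isin(labels, rec_ids)):
        cells_by_comp[int(labels[idx])].append(int(idx))

    cell_arr = stg.space.cells()
    nodes: list[MorseNode] = []
    for c in rec_ids:
        members = cells_by_comp[int(c)]
        labels_cells = tuple(tuple(int(v) for v in cell_arr[m]) for m in sorted(members))
        if len(members) == 1:
            ann = "FP"
        else:
            coords = cell_arr[members]
            constant = np.any(coords.min(axis=0) == coords.max(axis=0))
            ann = "XC" if constant else "FC"
        stable = not has_out[c]
        nodes.append(MorseNode(labels_cells, ann, bool(stable)))

    # reachability between recurrent components via BFS on the condensation
    edges: set[tuple[int, int]] = set()
    for c in rec_ids:
        seen = {int(c)}
        stack = list(cond_adj.get(int(c), ()))
        while stack:
            b = stack.pop()
            if b in seen:
                continue
            seen.add(b)
            if recurrent[b]:
                edges.add((rec_pos[int(c)], rec_pos[b]))
            stack.extend(cond_adj.get(b, ()))
    return MorseGraph(nodes, edges)


# ---------------------------------------------------------------------------
# one-off convenience wrappers
# ---------------------------------------------------------------------------

def input_combination(
    net: RegulatoryNetwork,
    regions: dict[str, FactorRegion],
    gene: str,
    cell: tuple[int, ...],
) -> int:
    """The active low/high tuple of ``gene``'s inputs in ``cell``, as a bitmask.

    Bit ``e`` (input declaration order) is set iff the high level ``U`` is
    active: an activating input above its threshold or a repressing input
    below it.  Whether regulator ``j`` exceeds a threshold is read from the
    rank of that threshold in ``j``'s ordering versus the cell coordinate.
    """
    i = net.index(gene)
    combo = 0
    for bit, e in enumerate(net.inputs(gene)):
        j = net.index(e.source)
        out_idx = net.outputs(e.source).index(e)
        rank = regions[e.source].rank_of_edge()[out_idx]
        above = cell[j] > rank
        chooses_U = above if e.sign == ACTIVATION else not above
        if chooses_U:
            combo |= 1 << bit
    return combo


def build_stg(net: RegulatoryNetwork, regions: dict[str, FactorRegion]) -> StateTransitionGraph:
    """State transition graph at a single parameter-node address."""
    return DynamicsEngine(net).stg(regions)


def stable_fixed_points(mg: MorseGraph) -> list[tuple[int, ...]]:
    return mg.stable_fixed_points()
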