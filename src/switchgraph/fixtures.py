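"""Synthetic inputs and numeric oracles.

Provides the two study networks (the 6-gene EMT circuit and the two-gene
toggle switch) as programmatic builders, a generator of random small
product-logic networks for cross-validation, an exact instantiation of real
parameters inside any enumerated inequality region, and a steep-Hill ODE
integrator used as an independent check that combinatorially predicted
stable fixed points are genuine attractors of the smooth system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .factor import FactorRegion, _slack_lp, MARGIN_TOL
from .network import (
    ACTIVATION,
    REPRESSION,
    Edge,
    RegulatoryNetwork,
    StateSpace,
    parse_network,
)

__all__ = [
    "EMT_SPEC",
    "TOGGLE_SPEC",
    "ConcreteParameters",
    "make_emt_network",
    "make_toggle_switch",
    "random_network",
    "instantiate_parameters",
    "derive_regions",
    "numeric_stg_edges",
    "ode_attractor_check",
]

# Gene order (Zeb1, Snail1, miR200, miR34a, TGFb, Ovol2) fixes all reported
# state labels.  Factor order per line fixes the input-combination bit order.
EMT_SPEC = """\
# EMT core circuit: 6 genes, 12 edges, pure product logic
Zeb1   : (Snail1)(~miR200)(~Ovol2)
Snail1 : (TGFb)(~miR34a)
miR200 : (~Zeb1)(~Snail1)
miR34a : (~Zeb1)(~Snail1)
TGFb   : (~Ovol2)(~miR200)
Ovol2  : (~Zeb1)
"""

TOGGLE_SPEC = """\
# mutual-repression toggle switch
X : (~Y)
Y : (~X)
"""


def make_emt_network() -> RegulatoryNetwork:
    """The modified EMT network: 6 genes, 12 edges, no self-regulation."""
    return parse_network(EMT_SPEC)


def make_toggle_switch() -> RegulatoryNetwork:
    """Two genes repressing each other; the canonical bistable circuit."""
    return parse_network(TOGGLE_SPEC)


def random_network(seed: int, n_nodes: int | None = None) -> RegulatoryNetwork:
    """A random small product-logic network obeying the model assumptions.

    Every node has at least one input and one output edge, at most one edge
    joins an ordered pair, self-edges are positive only.  Reproducible under
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    if n_nodes is None:
        n_nodes = int(rng.integers(2, 4))
    if n_nodes > 3:
        raise ValueError("random oracle networks are limited to 3 nodes")
    names = [f"N{i}" for i in range(n_nodes)]
    while True:
        inputs: dict[str, list[Edge]] = {g: [] for g in names}
        for tgt_i, tgt in enumerate(names):
            candidates = list(range(n_nodes))
            n_in = int(rng.integers(1, n_nodes + 1))
            srcs = rng.choice(candidates, size=n_in, replace=False)
            for src_i in srcs:
                src = names[int(src_i)]
                if src == tgt:
                    sign = ACTIVATION  # no negative self-regulation
                else:
                    sign = ACTIVATION if rng.random() < 0.5 else REPRESSION
                inputs[tgt].append(Edge(src, tgt, sign))
        net = RegulatoryNetwork(names, {g: tuple(v) for g, v in inputs.items()})
        if all(net.out_degree(g) >= 1 for g in names):
            return net


@dataclass
class ConcreteParameters:
    """Positive real parameters realizing one inequality region.

    ``gamma`` maps gene -> decay rate; ``edge`` maps (source, target) ->
    (L, U, theta) with L < U; threshold orderings and all region inequalities
    hold strictly with the margin certified by the slack LP.
    """

    gamma: dict[str, float] = field(default_factory=dict)
    edge: dict[tuple[str, str], tuple[float, float, float]] = field(default_factory=dict)

    def thresholds_of(self, net: RegulatoryNetwork, gene: str) -> np.ndarray:
        """Thresholds on ``gene``'s axis, indexed by out-edge (canonical order)."""
        return np.array([self.edge[(gene, e.target)][2] for e in net.outputs(gene)])


def instantiate_parameters(
    net: RegulatoryNetwork,
    regions: dict[str, FactorRegion],
    margin: float = 1e-3,
    rng: np.random.Generator | None = None,
) -> ConcreteParameters:
    """An interior parameter point of the product region given per-gene.

    Exponentiates the slack-LP optimum of each factor; decay rates are set to
    one, so each decay-scaled threshold variable is the threshold itself.
    With ``rng``, the log-space point is jittered uniformly within an eighth
    of the certified margin, yielding distinct interior points of the same
    region.  All strict inequalities are re-verified numerically.
    """
    params = ConcreteParameters()
    for g in net.nodes:
        params.gamma[g] = 1.0
    for g, region in regions.items():
        q, p = region.n_inputs, region.n_outputs
        res = _slack_lp(q, p, tuple(region.above))
        if res.status != 0 or res.x[-1] <= MARGIN_TOL:
            raise ValueError(f"region of {g!r} is not realizable")
        if res.x[-1] < margin:
            raise ValueError(f"slack margin {res.x[-1]:.2e} below requested {margin:.2e}")
        x = res.x.copy()
        if rng is not None:
            # each constraint touches few unit-coefficient variables, so a
            # per-variable shift below margin/8 cannot exhaust the slack
            x[:-1] += rng.uniform(-res.x[-1] / 8.0, res.x[-1] / 8.0, size=len(x) - 1)
        ins = net.inputs(g)
        for e_idx, e in enumerate(ins):
            L = float(np.exp(x[e_idx]))
            U = float(np.exp(x[q + e_idx]))
            prev = params.edge.get((e.source, e.target))
            theta = prev[2] if prev is not None else np.nan
            params.edge[(e.source, e.target)] = (L, U, theta)
        outs = net.outputs(g)
        for k, e_idx in enumerate(region.order):
            e = outs[e_idx]
            theta = float(np.exp(x[2 * q + k]))
            prev = params.edge.get((e.source, e.target))
            if prev is not None:
                params.edge[(e.source, e.target)] = (prev[0], prev[1], theta)
            else:
                params.edge[(e.source, e.target)] = (np.nan, np.nan, theta)
    _verify(net, regions, params, margin=0.0)
    return params


def _verify(net, regions, params, margin=0.0):
    derived = derive_regions(net, params)
    for g, region in regions.items():
        if derived[g] != region:
            raise AssertionError(f"instantiated parameters leave the region of {g!r}")


def derive_regions(net: RegulatoryNetwork, params: ConcreteParameters) -> dict[str, FactorRegion]:
    """Read back each gene's (threshold order, sign pattern) from real numbers.

    Independent of the LP path: compares products of the chosen L/U values
    against the decay-scaled thresholds directly.
    """
    out: dict[str, FactorRegion] = {}
    for g in net.nodes:
        q = net.in_degree(g)
        p = net.out_degree(g)
        if q == 0 or p == 0:
            continue
        needed = [(g, e.target) for e in net.outputs(g)] + [
            (e.source, e.target) for e in net.inputs(g)
        ]
        known = True
        for src, tgt in needed:
            vals = params.edge.get((src, tgt))
            if vals is None:
                known = False
                break
            if tgt == g and not (np.isfinite(vals[0]) and np.isfinite(vals[1])):
                known = False
            if src == g and not np.isfinite(vals[2]):
                known = False
        if not known:
            continue
        thetas = params.thresholds_of(net, g)
        order = tuple(int(i) for i in np.argsort(thetas, kind="stable"))
        gam = params.gamma[g]
        ins = net.inputs(g)
        masks = []
        for k in range(p):
            scaled = gam * thetas[order[k]]
            mask = 0
            for c in range(1 << q):
                lam = 1.0
                for e_idx, e in enumerate(ins):
                    L, U, _ = params.edge[(e.source, e.target)]
                    lam *= U if c >> e_idx & 1 else L
                if lam > scaled:
                    mask |= 1 << c
            masks.append(mask)
        out[g] = FactorRegion(g, q, order, tuple(masks))
    return out


# ---------------------------------------------------------------------------
# numeric state-transition-graph oracle
# ---------------------------------------------------------------------------

def _cell_centers_1d(thetas_sorted: np.ndarray) -> np.ndarray:
    """Representative coordinates, one per 1-d cell between consecutive thresholds.

    Geometric midpoints inside bounded cells, half the lowest threshold below,
    and twice the highest threshold in the unbounded top cell.
    """
    p = len(thetas_sorted)
    if p == 0:
        return np.array([1.0])
    centers = [thetas_sorted[0] / 2.0]
    for k in range(p - 1):
        centers.append(float(np.sqrt(thetas_sorted[k] * thetas_sorted[k + 1])))
    centers.append(2.0 * thetas_sorted[-1])
    return np.array(centers)


def numeric_stg_edges(net: RegulatoryNetwork, params: ConcreteParameters) -> set[tuple[int, int]]:
    """State-transition edges derived from real arithmetic on every face.

    For each cell, evaluates every step function at a representative point
    and compares the resulting production value with the decay-scaled face
    threshold; entirely bypasses the combinatorial sign-pattern machinery.
    """
    space = StateSpace(net)
    n = net.n_nodes()
    sorted_thetas = {}
    centers = {}
    for g in net.nodes:
        th = np.sort(params.thresholds_of(net, g))
        sorted_thetas[g] = th
        centers[g] = _cell_centers_1d(th)
    edges: set[tuple[int, int]] = set()
    for idx in range(space.size):
        s = space.label(idx)
        x = np.array([centers[g][s[i]] for i, g in enumerate(net.nodes)])
        for i, g in enumerate(net.nodes):
            lam = 1.0
            for e in net.inputs(g):
                L, U, theta = params.edge[(e.source, e.target)]
                xj = x[net.index(e.source)]
                above = xj > theta
                if e.sign == ACTIVATION:
                    lam *= U if above else L
                else:
                    lam *= L if above else U
            th = sorted_thetas[g]
            gam = params.gamma[g]
            if s[i] < len(th) and lam > gam * th[s[i]]:
                up = list(s)
                up[i] += 1
                edges.add((idx, space.index(up)))
            if s[i] > 0 and lam < gam * th[s[i] - 1]:
                down = list(s)
                down[i] -= 1
                edges.add((idx, space.index(down)))
    return edges


# ---------------------------------------------------------------------------
# steep-Hill ODE oracle
# ---------------------------------------------------------------------------

def _hill(x: float, L: float, U: float, theta: float, h: float, repress: bool) -> float:
    # computed through the bounded ratio exp(h*log(theta/x)) to stay overflow-safe
    x = max(x, 1e-300)
    t = np.clip(h * (np.log(theta) - np.log(x)), -700.0, 700.0)
    r = np.exp(t)  # (theta/x)^h
    up = L + (U - L) / (1.0 + r)
    return U + L - up if repress else up


def _rhs(net: RegulatoryNetwork, params: ConcreteParameters, h: float):
    genes = net.nodes

    def f(_t, x):
        dx = np.empty(len(genes))
        for i, g in enumerate(genes):
            lam = 1.0
            for e in net.inputs(g):
                L, U, theta = params.edge[(e.source, e.target)]
                lam *= _hill(x[net.index(e.source)], L, U, theta, h, e.sign == REPRESSION)
            dx[i] = -params.gamma[g] * x[i] + lam
        return dx

    return f


def ode_attractor_check(
    net: RegulatoryNetwork,
    params: ConcreteParameters,
    hill_n: float = 50.0,
    initial_cells: list[tuple[int, ...]] | None = None,
    t_window: float = 50.0,
    max_windows: int = 10,
) -> dict[tuple[int, ...], tuple[int, ...]]:
    """Integrate the smooth Hill system from cell centers to steady state.

    Returns a map from each initial cell to the cell containing the endpoint.
    Steady state is declared when the derivative norm drops below
    ``1e-6 * (1 + state norm)``; non-convergence within the step budget
    raises rather than silently dropping the case.
    """
    if hill_n < 50:
        raise ValueError("the switching limit needs hill_n >= 50")
    space = StateSpace(net)
    centers = {g: _cell_centers_1d(np.sort(params.thresholds_of(net, g))) for g in net.nodes}
    if initial_cells is None:
        initial_cells = [space.label(i) for i in range(space.size)]
    f = _rhs(net, params, hill_n)
    results: dict[tuple[int, ...], tuple[int, ...]] = {}
    for cell in initial_cells:
        x = np.array([centers[g][cell[i]] for i, g in enumerate(net.nodes)])
        converged = False
        for _ in range(max_windows):
            sol = solve_ivp(f, (0.0, t_window), x, method="LSODA", rtol=1e-8, atol=1e-10)
            x = sol.y[:, -1]
            if np.linalg.norm(f(0.0, x)) < 1e-6 * (1.0 + np.linalg.norm(x)):
                converged = True
                break
        if not converged:
            raise RuntimeError(f"ODE did not reach steady state from cell {cell}")
        final = []
        for i, g in enumerate(net.nodes):
            th = np.sort(params.thresholds_of(net, g))
            final.append(int(np.sum(x[i] > th)))
        results[tuple(cell)] = tuple(final)
    return results
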