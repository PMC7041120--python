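"""EMT multistability survey: E/M classification, layered statistics, occupancy.

Stable fixed points of the EMT network are phenotyped by their (Zeb1, Snail1,
Ovol2) projection: the epithelial corner is FP(0,0,*,*,*,2), the mesenchymal
corner FP(3,3,*,*,*,0), and every label sits on one of nine diagonals of the
4 x 4 x 3 projection cube at a fixed taxicab distance from each corner (the
two distances always sum to 8).

A layer survey fixes one gene's factor graph to be general (essential and
inessential regions) while all other genes stay essential, then tallies, per
layer of that gene's factor graph, the proportions of parameter nodes that
are monostable-E, monostable-M, E-present, M-present, the per-diagonal FP
occupancy, and the spectrum of k-multistability.  Layers are scanned
exhaustively when the product is small and by seeded uniform sampling
otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import DynamicsEngine
from .factor import FactorParameterGraph
from .fixtures import make_emt_network
from .network import RegulatoryNetwork
from .product import ParameterGraph

__all__ = [
    "FPClassification",
    "LayerStats",
    "LayerSurvey",
    "DomainOccupancy",
    "classify_fp",
    "diagonal_index",
    "survey_layers",
    "multistability_spectrum",
    "domain_occupancy",
    "write_report",
]

EMT_GENES = ("Zeb1", "Snail1", "miR200", "miR34a", "TGFb", "Ovol2")
EMT_SHAPE = (4, 4, 3, 2, 2, 3)
N_DIAGONALS = 9
SURVEY_GENES = ("Ovol2", "Snail1", "TGFb", "Zeb1")


@dataclass(frozen=True)
class FPClassification:
    label: tuple[int, ...]
    klass: str  # 'E', 'M' or 'intermediate'
    distance_from_E: int
    distance_from_M: int


def _check_label(label) -> tuple[int, ...]:
    label = tuple(int(v) for v in label)
    if len(label) != 6 or any(not 0 <= v < d for v, d in zip(label, EMT_SHAPE)):
        raise ValueError(f"{label} is not an EMT state label")
    return label


def diagonal_index(label) -> int:
    """Taxicab distance of the (Zeb1, Snail1, Ovol2) projection from the E corner.

    Ovol2 enters reversed (high Ovol2 is epithelial), giving nine diagonal
    classes 0..8 on the projection cube; 8 minus this value is the distance
    from the M corner.
    """
    z, s, o = label[0], label[1], label[5]
    return int(z) + int(s) + (2 - int(o))


def classify_fp(label) -> FPClassification:
    """Phenotype a fixed-point label as E, M or intermediate with diagonal distances."""
    label = _check_label(label)
    d_e = diagonal_index(label)
    d_m = 8 - d_e
    if d_e == 0:
        klass = "E"
    elif d_m == 0:
        klass = "M"
    else:
        klass = "intermediate"
    return FPClassification(label, klass, d_e, d_m)


@dataclass
class LayerStats:
    """Tallies for one factor-graph layer of a general ensemble."""

    layer: int
    n: int
    mono_E: float
    mono_M: float
    E_present: float
    M_present: float
    mono_diag: tuple[float, ...]  # 9 bins: monostable FP on each diagonal
    any_diag: tuple[float, ...]  # 9 bins: some stable FP on each diagonal
    k_hist: dict[int, float]  # k stable nodes -> proportion of nodes
    n_stable_non_fp: int  # addresses with a stable non-FP recurrent component


@dataclass
class LayerSurvey:
    gene: str
    mode: str
    seed: int | None
    n_per_layer: int
    exhaustive: bool
    layers: list[LayerStats] = field(default_factory=list)
    observed_labels: set[tuple[int, ...]] = field(default_factory=set)

    def layer(self, lay: int) -> LayerStats:
        for ls in self.layers:
            if ls.layer == lay:
                return ls
        raise KeyError(lay)

    @property
    def max_k(self) -> int:
        return max((k for ls in self.layers for k in ls.k_hist), default=0)


@dataclass(frozen=True)
class DomainOccupancy:
    mode: str
    labels: frozenset[tuple[int, ...]]
    count: int
    fraction: float


def _tally(engine: DynamicsEngine, pg: ParameterGraph, addresses):
    n = 0
    mono_E = mono_M = e_present = m_present = 0
    mono_diag = np.zeros(N_DIAGONALS, dtype=np.int64)
    any_diag = np.zeros(N_DIAGONALS, dtype=np.int64)
    k_counts: dict[int, int] = {}
    non_fp = 0
    labels_seen: set[tuple[int, ...]] = set()
    for addr in addresses:
        mg = engine.morse(pg.regions(addr))
        stable = mg.stable_nodes
        fps = [m.cells[0] for m in stable if m.is_fixed_point()]
        if len(fps) != len(stable):
            non_fp += 1
        labels_seen.update(fps)
        k = len(stable)
        k_counts[k] = k_counts.get(k, 0) + 1
        diags = [diagonal_index(lbl) for lbl in fps]
        has_e = any(d == 0 for d in diags)
        has_m = any(d == 8 for d in diags)
        e_present += has_e
        m_present += has_m
        if k == 1 and len(fps) == 1:
            mono_E += has_e
            mono_M += has_m
            mono_diag[diags[0]] += 1
        for d in set(diags):
            any_diag[d] += 1
        n += 1
    if n == 0:
        raise ValueError("empty address set")
    stats = LayerStats(
        layer=-1,
        n=n,
        mono_E=mono_E / n,
        mono_M=mono_M / n,
        E_present=e_present / n,
        M_present=m_present / n,
        mono_diag=tuple(mono_diag / n),
        any_diag=tuple(any_diag / n),
        k_hist={k: c / n for k, c in sorted(k_counts.items())},
        n_stable_non_fp=non_fp,
    )
    return stats, labels_seen


def survey_layers(
    gene: str,
    n_per_layer: int = 2000,
    seed: int | None = 0,
    exhaustive: bool = False,
    net: RegulatoryNetwork | None = None,
    factors: dict[str, FactorParameterGraph] | None = None,
    engine: DynamicsEngine | None = None,
    work_bound: int = 10**6,
    layers: list[int] | None = None,
) -> LayerSurvey:
    """Per-layer dynamics statistics of the ``gene``-general EMT parameter graph.

    For each layer of the gene's (full) factor graph, Morse graphs are
    computed on all addresses whose component for ``gene`` lies in that layer
    (exhaustive mode, refused above ``work_bound``) or on ``n_per_layer``
    uniform samples.  Monostable-E means the Morse graph's unique stable node
    is an E-class fixed point.
    """
    if net is None:
        net = make_emt_network()
    if gene not in net.nodes:
        raise ValueError(f"unknown gene {gene!r}")
    pg = ParameterGraph(net, modes={gene: "full"}, default_mode="essential", factors=factors)
    if engine is None:
        engine = DynamicsEngine(net)
    fg = pg.factors[gene]
    rng = np.random.default_rng(seed)
    survey = LayerSurvey(
        gene=gene,
        mode=f"{gene}-general",
        seed=seed,
        n_per_layer=n_per_layer,
        exhaustive=exhaustive,
    )
    for lay in layers if layers is not None else range(1, fg.n_layers + 1):
        positions = pg.layer_positions(gene, lay)
        if not positions:
            raise ValueError(f"layer {lay} of {gene!r} is empty")
        if exhaustive:
            sub_size = pg.size // pg.radices[net.index(gene)] * len(positions)
            if sub_size > work_bound:
                raise RuntimeError(
                    f"exhaustive layer scan of {sub_size} nodes exceeds work bound {work_bound}"
                )
            addresses = (
                a for a in pg.iter_addresses(force=True, work_bound=work_bound)
                if a[net.index(gene)] in set(positions)
            )
        else:
            addresses = pg.sample(n_per_layer, rng=rng, restrict=(gene, lay))
        stats, labels_seen = _tally(engine, pg, addresses)
        stats.layer = lay
        survey.layers.append(stats)
        survey.observed_labels.update(labels_seen)
    return survey


def multistability_spectrum(survey: LayerSurvey) -> pd.DataFrame:
    """Per-layer k-stability proportions, one row per layer, columns ``k_1..k_max``."""
    kmax = survey.max_k
    rows = []
    for ls in survey.layers:
        row = {"layer": ls.layer, "n": ls.n}
        for k in range(1, kmax + 1):
            row[f"k_{k}"] = ls.k_hist.get(k, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def domain_occupancy(mode: str, label_sets) -> DomainOccupancy:
    """Distinct stable-FP labels observed, as a count and fraction of the 576 domains.

    ``label_sets`` is any iterable of FP label collections (e.g. per-address
    stable FP lists, or a survey's ``observed_labels``); sampled runs give a
    lower bound that never decreases as addresses are added.
    """
    labels: set[tuple[int, ...]] = set()
    for group in label_sets:
        if isinstance(group, tuple) and group and isinstance(group[0], int):
            labels.add(_check_label(group))
        else:
            for lbl in group:
                labels.add(_check_label(lbl))
    total = int(np.prod(EMT_SHAPE))
    return DomainOccupancy(mode, frozenset(labels), len(labels), len(labels) / total)


def _survey_frame(survey: LayerSurvey) -> pd.DataFrame:
    kmax = survey.max_k
    rows = []
    for ls in survey.layers:
        row = {
            "layer": ls.layer,
            "n": ls.n,
            "mono_E": ls.mono_E,
            "mono_M": ls.mono_M,
            "E_present": ls.E_present,
            "M_present": ls.M_present,
        }
        for d in range(N_DIAGONALS):
            row[f"diag_{d}"] = ls.any_diag[d]
        for k in range(1, kmax + 1):
            row[f"k_{k}"] = ls.k_hist.get(k, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def write_report(result: LayerSurvey | DomainOccupancy, path: str | Path) -> list[Path]:
    """Write a survey (CSV + JSON) or occupancy (JSON) report; deterministic layout."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if isinstance(result, DomainOccupancy):
        out = path / "occupancy.json"
        out.write_text(
            json.dumps(
                {
                    "mode": result.mode,
                    "count": result.count,
                    "fraction": result.fraction,
                    "labels": sorted(list(l) for l in result.labels),
                },
                indent=2,
            )
        )
        written.append(out)
        return written
    if not result.layers:
        raise ValueError("empty survey")
    frame = _survey_frame(result)
    csv_path = path / f"survey_{result.gene}.csv"
    frame.to_csv(csv_path, index=False)
    written.append(csv_path)
    json_path = path / f"survey_{result.gene}.json"
    payload = {
        "gene": result.gene,
        "mode": result.mode,
        "seed": result.seed,
        "n_per_layer": result.n_per_layer,
        "exhaustive": result.exhaustive,
        "layers": [
            {
                "layer": ls.layer,
                "n": ls.n,
                "mono_E": ls.mono_E,
                "mono_M": ls.mono_M,
                "E_present": ls.E_present,
                "M_present": ls.M_present,
                "mono_diag": list(ls.mono_diag),
                "any_diag": list(ls.any_diag),
                "k_hist": {str(k): v for k, v in ls.k_hist.items()},
                "n_stable_non_fp": ls.n_stable_non_fp,
            }
            for ls in result.layers
        ],
    }
    json_path.write_text(json.dumps(payload, indent=2))
    written.append(json_path)
    return written
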