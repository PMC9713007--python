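"""Weighted graph topology, reference nulls, and AUC summaries.

All metrics operate on undirected, positively weighted graphs. Weights are
interpreted as connection strengths, so shortest-path computations use the
edge length ``1/weight``; clustering uses Onnela's geometric-mean form on
weights normalized by the graph maximum, which keeps clustering, both
small-world indices, and the efficiencies invariant to a global rescaling
of the weights. Characteristic path length averages finite distances only
and efficiencies score unreachable pairs as zero, so every point of a
sparsity grid remains computable even when the graph disconnects.

Small-worldness is quantified two ways:

* ``sigma = (Cp / <Cp_rand>) / (Lp / <Lp_rand>)`` against degree-preserving
  randomized references (Maslov-Sneppen double-edge swaps with the weight
  multiset reshuffled), small-world when sigma > 1;
* ``omega = <Lp_rand> / Lp - Cp / <Cp_latt>`` which additionally compares
  clustering against latticized references (swaps accepted only when they
  shorten the total ring distance of the edge set); omega near 0 is
  small-world, positive values are random-like, negative lattice-like.

Metric curves across the sparsity grid are reduced to a single scalar per
attribute by trapezoidal area under the curve (AUC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path

from .connectome import WeightedGraph

logger = logging.getLogger(__name__)

__all__ = [
    "GlobalMetricSet",
    "NodalMetricSet",
    "MetricCurve",
    "ReferenceConfig",
    "GLOBAL_ATTRIBUTES",
    "NODAL_ATTRIBUTES",
    "global_metrics",
    "nodal_metrics",
    "random_reference",
    "lattice_reference",
    "auc_over_thresholds",
    "assemble_auc_features",
    "compute_metric_curves",
]

GLOBAL_ATTRIBUTES = ("Cp", "Lp", "Sp", "E_loc", "E_glob", "Q", "sigma", "omega")
NODAL_ATTRIBUTES = ("E_nodal", "btwn_cent")


@dataclass(frozen=True)
class ReferenceConfig:
    """How many reference nulls to draw and how hard to rewire them."""

    n_refs: int = 20
    n_swaps_per_edge: int = 10
    lattice_passes: int = 5
    louvain_restarts: int = 10


@dataclass(frozen=True)
class GlobalMetricSet:
    Cp: float
    Lp: float
    Sp: float
    E_loc: float
    E_glob: float
    Q: float
    sigma: float
    omega: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in GLOBAL_ATTRIBUTES}


@dataclass(frozen=True)
class NodalMetricSet:
    E_nodal: np.ndarray
    btwn_cent: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"E_nodal": self.E_nodal, "btwn_cent": self.btwn_cent}


@dataclass(frozen=True)
class MetricCurve:
    """One metric traced over the sparsity grid for one subject."""

    sparsities: np.ndarray
    values: np.ndarray
    name: str
    subject_id: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.sparsities, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "sparsities", s)
        object.__setattr__(self, "values", v)
        if len(s) != len(v):
            raise ValueError("grid and values must have equal length")
        if len(s) >= 2 and np.any(np.diff(s) <= 0):
            raise ValueError("sparsity grid must be strictly increasing")


def _normalized_dense(g: WeightedGraph) -> np.ndarray:
    W = g.to_dense()
    wmax = g.weights.max()
    return W / wmax


def _distances(W: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances with edge length 1/weight."""
    lengths = np.zeros_like(W)
    nz = W > 0
    lengths[nz] = 1.0 / W[nz]
    return shortest_path(csr_array(lengths), method="D", directed=False)


def _onnela_clustering(W: np.ndarray) -> np.ndarray:
    """Per-node Onnela clustering on a max-normalized weight matrix."""
    A = (W > 0).astype(float)
    k = A.sum(axis=1)
    cube = np.cbrt(W)
    tri = np.diag(cube @ cube @ cube)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri / denom, 0.0)
    return c


def _efficiency_terms(D: np.ndarray) -> np.ndarray:
    inv = np.zeros_like(D)
    finite = np.isfinite(D) & (D > 0)
    inv[finite] = 1.0 / D[finite]
    return inv


def _global_efficiency(W: np.ndarray) -> float:
    n = W.shape[0]
    if n < 2:
        return 0.0
    inv = _efficiency_terms(_distances(W))
    return float(inv.sum() / (n * (n - 1)))


def _char_path_length(D: np.ndarray) -> float:
    n = D.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    if not finite.any():
        return float("inf")
    return float(D[finite].mean())


def _cp_lp(g: WeightedGraph) -> tuple[float, float]:
    W = _normalized_dense(g)
    cp = float(_onnela_clustering(W).mean())
    lp = _char_path_length(_distances(W))
    return cp, lp


def _modularity(g: WeightedGraph, restarts: int, seed: int) -> float:
    G = nx.Graph()
    G.add_nodes_from(range(g.n_nodes))
    G.add_weighted_edges_from(zip(g.edge_i.tolist(), g.edge_j.tolist(), g.weights.tolist()))
    best = -np.inf
    for r in range(restarts):
        parts = nx.community.louvain_communities(G, weight="weight", seed=seed + r)
        q = nx.community.modularity(G, parts, weight="weight")
        best = max(best, q)
    return float(best)


def global_metrics(
    g: WeightedGraph,
    ref: ReferenceConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> GlobalMetricSet:
    """All global attributes of one weighted graph, including sigma/omega.

    ``sigma`` and ``omega`` average clustering and path length over
    ``ref.n_refs`` randomized and latticized degree-preserving references.
    """
    if g.n_edges < 1:
        raise ValueError("graph has no edges")
    ref = ref or ReferenceConfig()
    if ref.n_refs < 1:
        raise ValueError("sigma/omega require at least one reference network")

    W = _normalized_dense(g)
    D = _distances(W)
    cp = float(_onnela_clustering(W).mean())
    lp = _char_path_length(D)
    n = g.n_nodes
    inv = _efficiency_terms(D)
    e_glob = float(inv.sum() / (n * (n - 1)))
    sp = float(g.to_dense().sum(axis=1).mean())

    A = W > 0
    e_loc_terms = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(A[i])
        if len(nb) >= 2:
            e_loc_terms[i] = _global_efficiency(W[np.ix_(nb, nb)])
    e_loc = float(e_loc_terms.mean())

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_q, ss_rand, ss_latt = ss.spawn(3)
    q = _modularity(g, ref.louvain_restarts, int(ss_q.generate_state(1)[0] % 2**31))

    cps_r, lps_r, cps_l = [], [], []
    for child in ss_rand.spawn(ref.n_refs):
        gr = random_reference(g, ref.n_swaps_per_edge, child)
        c, l = _cp_lp(gr)
        cps_r.append(c)
        lps_r.append(l)
    for child in ss_latt.spawn(ref.n_refs):
        gl = lattice_reference(g, ref.lattice_passes, child)
        cps_l.append(_cp_lp(gl)[0])

    cp_rand = float(np.mean(cps_r))
    lp_rand = float(np.mean(lps_r))
    cp_latt = float(np.mean(cps_l))
    sigma = (cp / cp_rand) / (lp / lp_rand) if cp_rand > 0 and np.isfinite(lp) else float("nan")
    omega = lp_rand / lp - cp / cp_latt if cp_latt > 0 and np.isfinite(lp) else float("nan")

    return GlobalMetricSet(Cp=cp, Lp=lp, Sp=sp, E_loc=e_loc, E_glob=e_glob,
                           Q=q, sigma=float(sigma), omega=float(omega))


def nodal_metrics(g: WeightedGraph) -> NodalMetricSet:
    """Nodal efficiency and (unnormalized) betweenness centrality per node."""
    if g.n_edges < 1:
        raise ValueError("graph has no edges")
    W = _normalized_dense(g)
    D = _distances(W)
    inv = _efficiency_terms(D)
    e_nodal = inv.sum(axis=1) / (g.n_nodes - 1)

    G = nx.Graph()
    G.add_nodes_from(range(g.n_nodes))
    for i, j, w in zip(g.edge_i.tolist(), g.edge_j.tolist(), g.weights.tolist()):
        G.add_edge(i, j, length=1.0 / (w / g.weights.max()))
    bc = nx.betweenness_centrality(G, weight="length", normalized=False)
    btwn = np.array([bc[i] for i in range(g.n_nodes)])
    return NodalMetricSet(E_nodal=e_nodal, btwn_cent=btwn)


def _edge_set(ei: np.ndarray, ej: np.ndarray) -> set[tuple[int, int]]:
    return set(zip(ei.tolist(), ej.tolist()))


def _as_graph(g: WeightedGraph, edges: list[tuple[int, int]], weights: np.ndarray) -> WeightedGraph:
    arr = np.array([(min(i, j), max(i, j)) for i, j in edges], dtype=np.intp)
    order = np.lexsort((arr[:, 1], arr[:, 0]))
    return WeightedGraph(
        n_nodes=g.n_nodes,
        edge_i=arr[order, 0],
        edge_j=arr[order, 1],
        weights=np.asarray(weights)[order],
        sparsity=g.sparsity,
        node_labels=g.node_labels,
    )


def random_reference(
    g: WeightedGraph,
    n_swaps_per_edge: int = 10,
    seed: int | np.random.SeedSequence = 0,
) -> WeightedGraph:
    """Degree-preserving randomized null via Maslov-Sneppen edge swaps.

    ``n_swaps_per_edge * n_edges`` swaps are attempted; the weight multiset
    is then reassigned to the rewired edge list by a random permutation.
    """
    if g.n_edges < 2:
        raise ValueError("need at least 2 edges to rewire")
    rng = np.random.default_rng(seed)
    edges = [(int(i), int(j)) for i, j in zip(g.edge_i, g.edge_j)]
    present = _edge_set(g.edge_i, g.edge_j)
    m = len(edges)
    attempts = n_swaps_per_edge * m
    failed = 0
    idx = rng.integers(0, m, size=(attempts, 2))
    flips = rng.random(attempts) < 0.5
    for t in range(attempts):
        e1, e2 = idx[t]
        if e1 == e2:
            failed += 1
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if flips[t]:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            failed += 1
            continue
        n1 = (min(a, d), max(a, d))
        n2 = (min(c, b), max(c, b))
        if n1 in present or n2 in present or n1 == n2:
            failed += 1
            continue
        present.discard((min(a, b), max(a, b)))
        present.discard((min(c, d), max(c, d)))
        present.add(n1)
        present.add(n2)
        edges[e1] = n1
        edges[e2] = n2
    if failed == attempts:
        logger.warning("random_reference: all %d swap attempts failed", attempts)
    weights = g.weights[rng.permutation(m)]
    return _as_graph(g, edges, weights)


def _ring_dist(i: int, j: int, n: int) -> int:
    d = abs(i - j)
    return min(d, n - d)


def lattice_reference(
    g: WeightedGraph,
    n_passes: int = 5,
    seed: int | np.random.SeedSequence = 0,
) -> WeightedGraph:
    """Degree-preserving latticized null (ring-distance-minimizing swaps).

    Runs ``n_passes`` sweeps of ``n_edges`` proposed swaps each, accepting
    only swaps that strictly reduce the total ring distance of the edge
    set; weights travel with the swapped endpoints, preserving the weight
    multiset.
    """
    if g.n_edges < 2:
        raise ValueError("need at least 2 edges to rewire")
    rng = np.random.default_rng(seed)
    n = g.n_nodes
    edges = [(int(i), int(j)) for i, j in zip(g.edge_i, g.edge_j)]
    weights = list(g.weights)
    present = _edge_set(g.edge_i, g.edge_j)
    m = len(edges)
    for _ in range(n_passes):
        idx = rng.integers(0, m, size=(m, 2))
        flips = rng.random(m) < 0.5
        for t in range(m):
            e1, e2 = idx[t]
            if e1 == e2:
                continue
            a, b = edges[e1]
            c, d = edges[e2]
            if flips[t]:
                c, d = d, c
            if a == d or c == b:
                continue
            n1 = (min(a, d), max(a, d))
            n2 = (min(c, b), max(c, b))
            if n1 in present or n2 in present or n1 == n2:
                continue
            old = _ring_dist(a, b, n) + _ring_dist(c, d, n)
            new = _ring_dist(*n1, n) + _ring_dist(*n2, n)
            if new >= old:
                continue
            present.discard((min(a, b), max(a, b)))
            present.discard((min(c, d), max(c, d)))
            present.add(n1)
            present.add(n2)
            edges[e1] = n1
            edges[e2] = n2
    return _as_graph(g, edges, np.array(weights))


def auc_over_thresholds(curve: MetricCurve) -> float:
    """Trapezoidal area of the metric over the sparsity grid."""
    if len(curve.sparsities) < 2:
        raise ValueError("AUC requires at least 2 grid points")
    return float(np.trapezoid(curve.values, curve.sparsities))


def compute_metric_curves(
    graphs: list[WeightedGraph],
    grid: np.ndarray,
    subject_id: str = "",
    ref: ReferenceConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> dict[str, MetricCurve]:
    """Global and nodal metric curves for one subject's thresholded graphs.

    ``graphs`` must align with ``grid``. Returns a mapping from attribute
    name (nodal attributes suffixed ``:<label>``) to its curve.
    """
    if len(graphs) != len(grid):
        raise ValueError("one graph per grid point required")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(graphs))
    glob_rows = []
    nodal_rows = []
    for graph, child in zip(graphs, children):
        glob_rows.append(global_metrics(graph, ref, child).as_dict())
        nodal_rows.append(nodal_metrics(graph))
    curves: dict[str, MetricCurve] = {}
    for name in GLOBAL_ATTRIBUTES:
        vals = np.array([row[name] for row in glob_rows])
        curves[name] = MetricCurve(grid, vals, name, subject_id)
    labels = graphs[0].node_labels or tuple(f"node{k}" for k in range(graphs[0].n_nodes))
    for attr in NODAL_ATTRIBUTES:
        mat = np.stack([getattr(row, attr) for row in nodal_rows])
        for k, lab in enumerate(labels):
            key = f"{attr}:{lab}"
            curves[key] = MetricCurve(grid, mat[:, k], key, subject_id)
    return curves


def assemble_auc_features(
    subject_curves: dict[str, dict[str, MetricCurve]],
    include_e_loc: bool = False,
) -> pd.DataFrame:
    """Subjects x AUC-feature table from per-subject metric curves.

    Column order: global attributes first (``E_loc`` optional), then nodal
    attribute x ROI columns. With ``include_e_loc=False`` a network of N
    nodes yields ``7 + 2 N`` features.
    """
    globals_used = [a for a in GLOBAL_ATTRIBUTES if include_e_loc or a != "E_loc"]
    rows = {}
    expected: list[str] | None = None
    for sid, curves in subject_curves.items():
        nodal_keys = sorted(
            k for k in curves if any(k.startswith(a + ":") for a in NODAL_ATTRIBUTES)
        )
        cols = globals_used + nodal_keys
        if expected is None:
            expected = cols
        missing = [c for c in expected if c not in curves]
        if missing or cols != expected:
            raise ValueError(f"subject {sid!r} is missing curves: {missing or expected}")
        values = [auc_over_thresholds(curves[c]) for c in expected]
        for name, v in zip(expected, values):
            if not np.isfinite(v):
                raise ValueError(
                    f"non-finite AUC for subject {sid!r}, attribute {name!r}; "
                    "sigma/omega are undefined when every reference network is "
                    "triangle-free — use denser graphs or more references"
                )
        rows[sid] = values
    table = pd.DataFrame.from_dict(rows, orient="index", columns=expected)
    table.index.name = "subject_id"
    return table
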