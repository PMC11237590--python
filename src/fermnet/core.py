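"""Core-network construction and its rewiring null model.

Per-study networks are aligned on the union of their ASVs into a multiplex
(one adjacency layer per study, weighted by metric-support counts).  The
core network with minimum share k keeps the associations found in at least
k layers; its nodes sit at the mean of their per-study scaled WMA, giving a
common fermentation time axis across studies.

Whether the networks share more structure than chance is judged against a
null model: each layer is rewired (degree-preserving double-edge swaps by
default, or uniform endpoint redraws), the distribution of intersection
sizes over all m-subsets of layers is recomputed, and observed vs null
distributions are compared with a two-sample Kolmogorov-Smirnov test, once
per null replicate.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from fermnet.association import AssociationNetwork
from fermnet.io import canonical_edge


@dataclass
class Layer:
    """One study's slice of the multiplex."""

    study_id: str
    adjacency: np.ndarray  # symmetric int, support counts, 0 = no edge
    presence: np.ndarray   # bool, node present in this study's network

    def edge_index_set(self) -> set[tuple[int, int]]:
        rows, cols = np.nonzero(np.triu(self.adjacency, k=1))
        return set(zip(rows.tolist(), cols.tolist()))

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, k=1)))


@dataclass
class MultiplexNetwork:
    """Aligned union node set with one weighted adjacency layer per study."""

    node_ids: list[str]
    layers: list[Layer] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def presence_matrix(self) -> np.ndarray:
        """layers x nodes membership flags."""
        return np.array([lay.presence for lay in self.layers])

    def validate(self) -> None:
        n = self.n_nodes
        for lay in self.layers:
            if lay.adjacency.shape != (n, n):
                raise ValueError(f"layer {lay.study_id}: bad adjacency shape")
            if not np.array_equal(lay.adjacency, lay.adjacency.T):
                raise ValueError(f"layer {lay.study_id}: adjacency not symmetric")
            if np.any(np.diag(lay.adjacency) != 0):
                raise ValueError(f"layer {lay.study_id}: nonzero diagonal")
            absent = ~lay.presence
            if np.any(lay.adjacency[absent, :]) or np.any(lay.adjacency[:, absent]):
                raise ValueError(f"layer {lay.study_id}: edges on absent nodes")


@dataclass
class CoreNetwork:
    """Edges shared by >= min_share layers; nodes are their endpoints."""

    min_share: int
    graph: nx.Graph = field(default_factory=nx.Graph)

    def edge_set(self) -> set[tuple[str, str]]:
        return {canonical_edge(u, v) for u, v in self.graph.edges}


@dataclass
class IntersectionDistribution:
    """Intersection sizes over every m-subset of layers."""

    m: int
    mode: str  # "vertices" | "edges"
    sizes: np.ndarray
    subsets: list[tuple[str, ...]]


@dataclass
class KsTestResult:
    """Observed intersection distribution vs rewired null replicates."""

    m: int
    mode: str
    observed: np.ndarray
    statistics: np.ndarray
    p_values: np.ndarray
    alpha: float

    @property
    def n_reject(self) -> int:
        return int(np.sum(self.p_values < self.alpha))

    @property
    def n_replicates(self) -> int:
        return len(self.p_values)


def align_networks(nets: list[AssociationNetwork]) -> MultiplexNetwork:
    """Align per-study networks on the union of their ASV ids.

    ASV identity is exact id (sequence) equality.  Each layer's adjacency
    holds the metric-support count of the study's edges, zero elsewhere.
    """
    if len(nets) < 2:
        raise ValueError("need at least 2 networks to align")
    study_ids = [net.study_id for net in nets]
    if len(set(study_ids)) != len(study_ids):
        raise ValueError(f"duplicate study ids among networks: {study_ids}")
    node_ids = sorted(set().union(*(net.node_ids for net in nets)))
    index = {a: i for i, a in enumerate(node_ids)}
    n = len(node_ids)
    layers = []
    for net in nets:
        adj = np.zeros((n, n), dtype=np.int64)
        presence = np.zeros(n, dtype=bool)
        for node in net.graph.nodes:
            presence[index[node]] = True
        for u, v, attrs in net.graph.edges(data=True):
            i, j = index[u], index[v]
            support = int(attrs.get("support", 1))
            adj[i, j] = support
            adj[j, i] = support
        layers.append(Layer(net.study_id, adj, presence))
    mplex = MultiplexNetwork(node_ids=node_ids, layers=layers)
    mplex.validate()
    return mplex


def intersection_distribution(
    mplex: MultiplexNetwork, m: int, mode: str = "edges"
) -> IntersectionDistribution:
    """Size of the vertex or edge intersection for every m-subset of layers."""
    L = mplex.n_layers
    if not 2 <= m <= L:
        raise ValueError(f"m must lie in [2, {L}], got {m}")
    if mode not in ("vertices", "edges"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "edges":
        items = [lay.edge_index_set() for lay in mplex.layers]
    else:
        items = [set(np.nonzero(lay.presence)[0].tolist()) for lay in mplex.layers]
    sizes, subsets = [], []
    for combo in itertools.combinations(range(L), m):
        shared = set.intersection(*(items[i] for i in combo))
        sizes.append(len(shared))
        subsets.append(tuple(mplex.layers[i].study_id for i in combo))
    return IntersectionDistribution(
        m=m, mode=mode, sizes=np.asarray(sizes, dtype=np.int64), subsets=subsets
    )


def edge_share_counts(mplex: MultiplexNetwork) -> dict[tuple[int, int], int]:
    """For every edge present anywhere: in how many layers does it occur."""
    counts: dict[tuple[int, int], int] = {}
    for lay in mplex.layers:
        for pair in lay.edge_index_set():
            counts[pair] = counts.get(pair, 0) + 1
    return counts


def build_core_network(
    mplex: MultiplexNetwork,
    scaled_wmas: dict[str, dict[str, float]] | None = None,
    k: int = 3,
    taxonomy=None,
) -> CoreNetwork:
    """Keep edges found in at least k layers; nodes are their endpoints.

    ``scaled_wmas`` maps study_id -> {asv_id -> scaled WMA}; each retained
    node is positioned at the mean of its scaled WMA over the layers whose
    network contains it, and annotated with its prevalence (number of
    layers containing the ASV).
    """
    if k < 2:
        raise ValueError("min share k must be >= 2")
    shares = edge_share_counts(mplex)
    core = CoreNetwork(min_share=k)
    presence = mplex.presence_matrix()
    prevalence = presence.sum(axis=0)
    for (i, j), count in sorted(shares.items()):
        if count >= k:
            u, v = mplex.node_ids[i], mplex.node_ids[j]
            a, b = canonical_edge(u, v)
            core.graph.add_edge(a, b, share_count=int(count))
    if core.graph.number_of_edges() == 0:
        warnings.warn(f"core network at k={k} is empty", stacklevel=2)
    index = {a: i for i, a in enumerate(mplex.node_ids)}
    for node in core.graph.nodes:
        i = index[node]
        attrs = {"prevalence": int(prevalence[i])}
        if scaled_wmas is not None:
            zs = [
                per_study[node]
                for per_study in scaled_wmas.values()
                if node in per_study
            ]
            attrs["mean_scaled_wma"] = float(np.mean(zs)) if zs else float("nan")
        if taxonomy is not None:
            attrs["order"] = taxonomy.rank_of(node, "order")
        core.graph.nodes[node].update(attrs)
    return core


# ---------------------------------------------------------------------------
# null model
# ---------------------------------------------------------------------------

def _double_edge_swaps(pairs, n_swaps: int, rng) -> list[tuple[int, int]]:
    """Attempt ``n_swaps`` degree-preserving double-edge swaps.

    Each attempt picks two edges (a,b), (c,d) and proposes (a,c), (b,d);
    attempts that would touch fewer than four distinct nodes or create a
    duplicate edge are skipped, so the graph stays simple and every node
    keeps its degree.
    """
    edges = [tuple(p) for p in pairs]
    edge_set = set(edges)
    n_edges = len(edges)
    picks = rng.integers(0, n_edges, size=(n_swaps, 2))
    flips = rng.integers(0, 2, size=n_swaps)
    for (e1, e2), flip in zip(picks, flips):
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if flip:
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        p1 = (a, c) if a < c else (c, a)
        p2 = (b, d) if b < d else (d, b)
        if p1 in edge_set or p2 in edge_set:
            continue
        edge_set.remove(edges[e1])
        edge_set.remove(edges[e2])
        edge_set.add(p1)
        edge_set.add(p2)
        edges[e1] = p1
        edges[e2] = p2
    return sorted(edge_set)


def rewire_network(
    layer: Layer,
    method: str = "degree_preserving_swaps",
    n_swaps: int | None = None,
    seed=None,
) -> Layer:
    """Randomize one layer while keeping its node set and edge count.

    ``degree_preserving_swaps`` performs double-edge swaps (default
    10x|E| attempted swaps), preserving every node's degree.
    ``uniform_endpoints`` redraws each edge's endpoints uniformly among the
    layer's present nodes (the classic rewire-with-probability-1 null).
    Support weights of the original edges are carried onto the rewired
    edges in a seeded random order.
    """
    rng = np.random.default_rng(seed)
    present = np.nonzero(layer.presence)[0]
    pairs = sorted(layer.edge_index_set())
    n_edges = len(pairs)
    if n_edges < 2:
        warnings.warn(
            f"layer {layer.study_id}: fewer than 2 edges, returned unchanged",
            stacklevel=2,
        )
        return Layer(layer.study_id, layer.adjacency.copy(), layer.presence.copy())

    if method == "degree_preserving_swaps":
        nswap = n_swaps if n_swaps is not None else 10 * n_edges
        new_pairs = _double_edge_swaps(pairs, nswap, rng)
    elif method == "uniform_endpoints":
        chosen: set[tuple[int, int]] = set()
        while len(chosen) < n_edges:
            i, j = rng.choice(present, size=2, replace=False)
            chosen.add((min(i, j), max(i, j)))
        new_pairs = sorted(chosen)
    else:
        raise ValueError(f"unknown rewiring method {method!r}")

    weights = np.array([layer.adjacency[i, j] for i, j in pairs])
    rng.shuffle(weights)
    adj = np.zeros_like(layer.adjacency)
    for (i, j), w in zip(new_pairs, weights):
        adj[i, j] = w
        adj[j, i] = w
    return Layer(layer.study_id, adj, layer.presence.copy())


def rewire_multiplex(
    mplex: MultiplexNetwork, method: str = "degree_preserving_swaps", seed=None
) -> MultiplexNetwork:
    """Rewire every layer independently (seeded per layer)."""
    rng = np.random.default_rng(seed)
    layers = [
        rewire_network(lay, method=method, seed=int(rng.integers(2**31)))
        for lay in mplex.layers
    ]
    return MultiplexNetwork(node_ids=list(mplex.node_ids), layers=layers)


def null_model_test(
    mplex: MultiplexNetwork,
    m: int,
    mode: str = "edges",
    n_sets: int = 100,
    alpha: float = 0.05,
    method: str = "degree_preserving_swaps",
    seed=None,
) -> KsTestResult:
    """KS comparison of observed intersection sizes against rewired nulls.

    The observed distribution (over all m-subsets of layers) is compared
    against each of ``n_sets`` independently rewired multiplexes with a
    two-sided two-sample Kolmogorov-Smirnov test; the per-replicate
    p-values and the rejection count at ``alpha`` are reported.  Degenerate
    comparisons (both distributions identically zero) get p = 1.
    """
    observed = intersection_distribution(mplex, m, mode).sizes
    rng = np.random.default_rng(seed)
    statistics = np.empty(n_sets)
    p_values = np.empty(n_sets)
    for r in range(n_sets):
        null_mplex = rewire_multiplex(
            mplex, method=method, seed=int(rng.integers(2**31))
        )
        null_sizes = intersection_distribution(null_mplex, m, mode).sizes
        if not observed.any() and not null_sizes.any():
            statistics[r], p_values[r] = 0.0, 1.0
            continue
        res = stats.ks_2samp(observed, null_sizes, alternative="two-sided")
        statistics[r], p_values[r] = res.statistic, res.pvalue
    return KsTestResult(
        m=m, mode=mode, observed=observed,
        statistics=statistics, p_values=p_values, alpha=alpha,
    )
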