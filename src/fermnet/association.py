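"""Per-study ASV association networks.

For every pair of ASVs in a filtered count table, four association measures
are computed over the study's samples:

* Jaccard distance between presence/absence profiles (co-presence),
* Pearson and Spearman correlation of relative abundances (co-abundance),
* the proportionality statistic phi(a, b) = var(clr a - clr b) /
  var(clr a + clr b) on clr-transformed counts (phi = 0 means the two clr
  profiles differ only by a constant, i.e. the abundances are perfectly
  proportional).

An edge is drawn when at least one measure reaches its (deliberately
non-stringent) threshold — distance <= 0.4 for Jaccard, r >= 0.5 for the
correlations, phi <= 0.5 — and the edge's ``support`` records how many of
the four agreed.  Each node carries its weighted mean age (WMA): the mean
sampling time of the samples containing the ASV, weighted by relative
abundance.  WMA orders nodes along the fermentation time axis; its
per-network z-score ("scaled WMA") puts studies with different time scales
on a common axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from fermnet.io import CountTable, SampleMetadata, TaxonomyTable, canonical_edge
from fermnet.preprocessing import clr_transform, to_relative


@dataclass
class MetricThresholds:
    """Edge thresholds for the four association measures.

    ``jaccard_as_distance`` switches the Jaccard rule between
    distance <= jaccard_dist_max (default) and similarity >= jaccard_dist_max.
    ``signed_corr=True`` means only positive correlations can support an
    edge; set False to accept |r| >= corr_min.
    """

    jaccard_dist_max: float = 0.4
    corr_min: float = 0.5
    phi_max: float = 0.5
    signed_corr: bool = True
    jaccard_as_distance: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.jaccard_dist_max < 1:
            raise ValueError("jaccard_dist_max must lie in (0, 1)")
        if not 0 < self.corr_min <= 1:
            raise ValueError("corr_min must lie in (0, 1]")
        if self.phi_max <= 0:
            raise ValueError("phi_max must be positive")


METRIC_NAMES = ("jaccard", "pearson", "spearman", "phi")


@dataclass
class AssociationNetwork:
    """One study's ASV association graph.

    Nodes are ASV ids with ``wma`` (days), ``scaled_wma`` (z-units, set by
    :func:`scale_wma`), ``order`` (taxonomic order) and ``max_relabund``.
    Edges carry ``support`` (1-4) and one boolean flag per metric.
    """

    study_id: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def node_ids(self) -> set[str]:
        return set(self.graph.nodes)

    def edge_set(self) -> set[tuple[str, str]]:
        return {canonical_edge(u, v) for u, v in self.graph.edges}


# ---------------------------------------------------------------------------
# the four measures
# ---------------------------------------------------------------------------

def jaccard_distance(x, y) -> float:
    """1 - |x AND y| / |x OR y| on presence vectors.

    Two ASVs absent everywhere share no co-presence evidence: distance 1.
    """
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError("presence vectors must have equal length")
    union = np.count_nonzero(x | y)
    if union == 0:
        return 1.0
    return 1.0 - np.count_nonzero(x & y) / union


def abundance_correlation(x, y, method: str = "pearson") -> float:
    """Pearson or Spearman correlation; NaN when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("abundance vectors must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 samples for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def phi_proportionality(cx, cy) -> float:
    """var(cx - cy) / var(cx + cy) on clr vectors (sample variance, n-1).

    Returns NaN when var(cx + cy) = 0 (anti-proportional profiles have no
    defined phi; they never form an edge).
    """
    cx = np.asarray(cx, dtype=float)
    cy = np.asarray(cy, dtype=float)
    if cx.shape != cy.shape:
        raise ValueError("clr vectors must have equal length")
    if len(cx) < 3:
        raise ValueError("need at least 3 samples for phi")
    denom = np.var(cx + cy, ddof=1)
    if denom == 0:
        return float("nan")
    return float(np.var(cx - cy, ddof=1) / denom)


def decide_edge(metrics: dict, th: MetricThresholds | None = None) -> dict:
    """Combine the four measures into an edge decision.

    ``metrics`` maps metric name -> value; missing or NaN values count as
    failing (zero-variance profiles never create edges).  Returns
    ``{"is_edge": bool, "support": int, "flags": {name: bool}}``.
    """
    th = th or MetricThresholds()
    flags = {}
    jd = metrics.get("jaccard")
    if jd is None or np.isnan(jd):
        flags["jaccard"] = False
    elif th.jaccard_as_distance:
        flags["jaccard"] = jd <= th.jaccard_dist_max
    else:
        flags["jaccard"] = (1.0 - jd) >= th.jaccard_dist_max
    for name in ("pearson", "spearman"):
        r = metrics.get(name)
        if r is None or np.isnan(r):
            flags[name] = False
        else:
            flags[name] = (r if th.signed_corr else abs(r)) >= th.corr_min
    phi = metrics.get("phi")
    flags["phi"] = phi is not None and not np.isnan(phi) and phi <= th.phi_max
    support = sum(flags.values())
    return {"is_edge": support > 0, "support": support, "flags": flags}


def weighted_mean_age(relabund, ages_days) -> float:
    """Mean age of the samples containing the ASV, weighted by abundance."""
    p = np.asarray(relabund, dtype=float)
    t = np.asarray(ages_days, dtype=float)
    if p.shape != t.shape:
        raise ValueError("abundances and ages must have equal length")
    mask = p > 0
    if not mask.any():
        raise ValueError("ASV absent from every sample: WMA undefined")
    return float(np.sum(t[mask] * p[mask]) / np.sum(p[mask]))


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def _pairwise_metrics(counts: CountTable, clr_values: np.ndarray):
    """All-pairs metric matrices (vectorized over the ASV axis)."""
    presence = counts.counts > 0
    rel = to_relative(counts).values
    n_asv = presence.shape[1]

    inter = presence.T.astype(np.int64) @ presence.astype(np.int64)
    sizes = presence.sum(axis=0)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        jaccard = np.where(union > 0, 1.0 - inter / np.maximum(union, 1), 1.0)

    pearson = _safe_corr(rel)
    ranks = stats.rankdata(rel, axis=0)
    spearman = _safe_corr(ranks)

    cov = np.cov(clr_values.T)  # ddof=1
    cov = np.atleast_2d(cov)
    var = np.diag(cov)
    num = var[:, None] + var[None, :] - 2 * cov
    den = var[:, None] + var[None, :] + 2 * cov
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(np.abs(den) > 1e-300, num / den, np.nan)
    assert phi.shape == (n_asv, n_asv)
    return jaccard, pearson, spearman, phi


def _safe_corr(matrix: np.ndarray) -> np.ndarray:
    """Column-wise correlation matrix with NaN for constant columns."""
    sd = matrix.std(axis=0)
    constant = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(matrix.T)
    corr = np.atleast_2d(corr)
    corr[constant, :] = np.nan
    corr[:, constant] = np.nan
    return corr


def build_association_network(
    counts: CountTable,
    taxonomy: TaxonomyTable,
    metadata: SampleMetadata,
    th: MetricThresholds | None = None,
    study_id: str | None = None,
    clr_mode: str = "pseudocount",
    clr_pseudocount: float = 0.5,
    clr_n_instances: int = 128,
    seed: int | None = None,
) -> AssociationNetwork:
    """Build one study's association network from a filtered count table.

    ``counts`` is expected to have passed :func:`fermnet.preprocessing.
    filter_for_network`.  Deterministic given inputs and seed (the seed only
    matters in ``dirichlet_mc`` clr mode).
    """
    th = th or MetricThresholds()
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 ASVs to build a network")
    if study_id is None:
        studies = metadata.data.loc[counts.sample_ids, "study_id"].unique()
        study_id = str(studies[0]) if len(studies) == 1 else "+".join(map(str, studies))

    ages = metadata.time_of(counts.sample_ids)
    rel = to_relative(counts).values
    clr = clr_transform(
        counts, mode=clr_mode, pseudocount=clr_pseudocount,
        n_instances=clr_n_instances, seed=seed,
    ).values
    jac, pea, spe, phi = _pairwise_metrics(counts, clr)

    net = AssociationNetwork(study_id=study_id)
    net.graph.graph["study_id"] = study_id
    asv_ids = counts.asv_ids
    for j, asv in enumerate(asv_ids):
        net.graph.add_node(
            asv,
            wma=weighted_mean_age(rel[:, j], ages),
            order=taxonomy.rank_of(asv, "order"),
            max_relabund=float(rel[:, j].max()),
        )
    n = len(asv_ids)
    for i in range(n):
        for j in range(i + 1, n):
            decision = decide_edge(
                {"jaccard": jac[i, j], "pearson": pea[i, j],
                 "spearman": spe[i, j], "phi": phi[i, j]},
                th,
            )
            if decision["is_edge"]:
                a, b = canonical_edge(asv_ids[i], asv_ids[j])
                net.graph.add_edge(
                    a, b,
                    support=decision["support"],
                    **{f"flag_{k}": bool(v) for k, v in decision["flags"].items()},
                )
    return net


def scale_wma(net: AssociationNetwork) -> AssociationNetwork:
    """Attach per-network z-scored WMA (mean 0, sd 1 with n-1) to each node.

    All-equal WMAs get scaled_wma 0 with a warning.  Idempotent: the
    z-score is always recomputed from the raw ``wma`` attribute.
    """
    nodes = list(net.graph.nodes)
    if not nodes:
        return net
    wmas = np.array([net.graph.nodes[n]["wma"] for n in nodes], dtype=float)
    sd = wmas.std(ddof=1) if len(wmas) > 1 else 0.0
    if sd == 0:
        warnings.warn(
            f"network {net.study_id}: all WMA equal, scaled_wma set to 0",
            stacklevel=2,
        )
        scaled = np.zeros_like(wmas)
    else:
        scaled = (wmas - wmas.mean()) / sd
    for node, z in zip(nodes, scaled):
        net.graph.nodes[node]["scaled_wma"] = float(z)
    return net


def compute_layout(net: AssociationNetwork, seed: int | None = None) -> dict:
    """Fruchterman-Reingold layout, then x replaced by each node's WMA.

    Returns node -> (x, y); the y coordinate keeps the force-directed
    arrangement while x becomes fermentation time.
    """
    pos = nx.spring_layout(net.graph, seed=seed)
    return {
        node: (float(net.graph.nodes[node]["wma"]), float(xy[1]))
        for node, xy in pos.items()
    }
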