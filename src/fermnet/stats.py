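"""Group comparisons of WMA / prevalence, and LAB fermentation types.

The temporal claims of the pipeline — e.g. that *Pseudomonadales* ASVs
precede *Enterobacterales*, which precede *Lactobacillales* — are tested
with the non-parametric Wilcoxon-Mann-Whitney rank-sum test on per-ASV
scaled WMA (or prevalence), pairwise between groups, with
Benjamini-Hochberg adjusted p-values reported alongside the raw ones.

A bundled genus -> fermentation-type table (hetero- vs homofermentative
lactic acid bacteria, following the 2020 Lactobacillaceae reclassification
of Zheng et al.) supports the hetero/homo comparisons; it is an editable
TSV covering common fermented-vegetable genera, with no claim of
completeness.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from fermnet.io import TaxonomyTable

#: exact-U enumeration is used up to this product of group sizes
EXACT_LIMIT = 400


@dataclass
class GroupComparison:
    """One pairwise Wilcoxon-Mann-Whitney comparison."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    method: str  # "exact" | "asymptotic"
    p_adjusted: float | None = None


def rank_sum_test(a, b, group_a: str = "a", group_b: str = "b") -> GroupComparison:
    """Two-sided Wilcoxon-Mann-Whitney test.

    Exact U distribution when n1*n2 <= 400 and there are no ties across
    the pooled sample; otherwise the normal approximation with tie and
    continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (len(a) * len(b) <= EXACT_LIMIT) and not has_ties
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return GroupComparison(
        group_a=group_a, group_b=group_b, n_a=len(a), n_b=len(b),
        u_statistic=float(res.statistic), p_value=float(res.pvalue),
        method="exact" if exact else "asymptotic",
    )


def asv_prevalence(mplex) -> dict[str, int]:
    """Number of per-study networks whose node set contains each ASV."""
    presence = mplex.presence_matrix()
    counts = presence.sum(axis=0)
    return {asv: int(c) for asv, c in zip(mplex.node_ids, counts)}


def mean_scaled_wma(networks) -> pd.DataFrame:
    """Per-ASV mean scaled WMA and prevalence over a list of networks.

    Each ASV's scaled WMA is averaged over the study networks whose node
    set contains it; prevalence is the number of such networks.
    """
    per_asv: dict[str, list[float]] = {}
    for net in networks:
        for node, attrs in net.graph.nodes(data=True):
            per_asv.setdefault(node, []).append(float(attrs["scaled_wma"]))
    frame = pd.DataFrame({
        "scaled_wma": {a: float(np.mean(v)) for a, v in per_asv.items()},
        "prevalence": {a: len(v) for a, v in per_asv.items()},
    })
    frame.index.name = "asv_id"
    return frame


def _node_table(core_or_mplex, taxonomy=None, clusters=None,
                fermentation_map=None) -> pd.DataFrame:
    """Per-ASV value/grouping table.

    Accepts a CoreNetwork / AssociationNetwork (graph node attributes), a
    MultiplexNetwork (prevalence only) or a prepared DataFrame such as the
    output of :func:`mean_scaled_wma`.
    """
    if isinstance(core_or_mplex, pd.DataFrame):
        frame = core_or_mplex.copy()
        for col in ("scaled_wma", "prevalence", "order"):
            if col not in frame.columns:
                frame[col] = np.nan if col != "order" else None
    elif hasattr(core_or_mplex, "graph"):  # CoreNetwork / AssociationNetwork
        graph = core_or_mplex.graph
        records = []
        for node, attrs in graph.nodes(data=True):
            records.append({
                "asv_id": node,
                "scaled_wma": attrs.get("mean_scaled_wma", attrs.get("scaled_wma")),
                "prevalence": attrs.get("prevalence"),
                "order": attrs.get("order"),
            })
        frame = pd.DataFrame(records).set_index("asv_id")
    else:  # MultiplexNetwork
        prev = asv_prevalence(core_or_mplex)
        frame = pd.DataFrame({"prevalence": pd.Series(prev)})
        frame["scaled_wma"] = np.nan
        frame["order"] = None
        frame.index.name = "asv_id"
    if taxonomy is not None:
        frame["order"] = [taxonomy.rank_of(a, "order") for a in frame.index]
        frame["genus"] = [taxonomy.rank_of(a, "genus") for a in frame.index]
    if clusters is not None:
        frame["cluster"] = [clusters.get(a) for a in frame.index]
    if fermentation_map is not None and taxonomy is not None:
        ftypes = annotate_fermentation_type(taxonomy, fermentation_map)
        frame["fermentation_type"] = [ftypes.get(a, "unknown") for a in frame.index]
    return frame


def compare_groups(
    core_or_mplex,
    grouping: str,
    value: str = "scaled_wma",
    taxonomy: TaxonomyTable | None = None,
    clusters: dict[str, int] | None = None,
    fermentation_map: dict[str, str] | None = None,
    min_group_size: int = 2,
) -> list[GroupComparison]:
    """All pairwise rank-sum tests of ``value`` between groups of ASVs.

    ``grouping`` is one of order / cluster / genus / fermentation_type;
    ``value`` is scaled_wma or prevalence.  Groups smaller than
    ``min_group_size`` (or unlabeled ASVs) are dropped.  Benjamini-Hochberg
    adjusted p-values are filled in across the returned comparisons.
    """
    if grouping not in ("order", "cluster", "genus", "fermentation_type"):
        raise ValueError(f"unknown grouping {grouping!r}")
    if value not in ("scaled_wma", "prevalence"):
        raise ValueError(f"unknown value {value!r}")
    frame = _node_table(core_or_mplex, taxonomy, clusters, fermentation_map)
    if grouping not in frame.columns:
        raise ValueError(f"grouping {grouping!r} unresolvable for this input")
    frame = frame.dropna(subset=[grouping, value])
    if grouping == "fermentation_type":
        frame = frame[frame[grouping] != "unknown"]
    groups = {
        name: sub[value].to_numpy(dtype=float)
        for name, sub in frame.groupby(grouping)
        if len(sub) >= min_group_size
    }
    if len(groups) < 2:
        raise ValueError(
            f"grouping {grouping!r} yields fewer than 2 usable groups"
        )
    comparisons = [
        rank_sum_test(groups[ga], groups[gb], group_a=str(ga), group_b=str(gb))
        for ga, gb in itertools.combinations(sorted(groups, key=str), 2)
    ]
    adjusted = multipletests([c.p_value for c in comparisons], method="fdr_bh")[1]
    for comp, adj in zip(comparisons, adjusted):
        comp.p_adjusted = float(adj)
    return comparisons


def comparisons_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Tabulate comparisons for TSV export."""
    return pd.DataFrame([
        {
            "group_a": c.group_a, "group_b": c.group_b,
            "n_a": c.n_a, "n_b": c.n_b,
            "U": c.u_statistic, "p_value": c.p_value,
            "p_adjusted": c.p_adjusted, "method": c.method,
        }
        for c in comparisons
    ])


def load_fermentation_type_map(path=None) -> dict[str, str]:
    """Load the genus -> {heterofermentative, homofermentative} table.

    Defaults to the bundled TSV; genus matching downstream is
    case-insensitive.
    """
    if path is None:
        source = resources.files("fermnet.data").joinpath("fermentation_types.tsv")
        with resources.as_file(source) as p:
            frame = pd.read_csv(p, sep="\t")
    else:
        frame = pd.read_csv(path, sep="\t")
    return {
        str(row.genus).lower(): str(row.fermentation_type)
        for row in frame.itertuples()
    }


def annotate_fermentation_type(
    taxonomy: TaxonomyTable, type_map: dict[str, str] | None = None
) -> dict[str, str]:
    """Per-ASV fermentation type from its genus; 'unknown' when unmapped."""
    if type_map is None:
        type_map = load_fermentation_type_map()
    type_map = {k.lower(): v for k, v in type_map.items()}
    out = {}
    for asv in taxonomy.data.index:
        genus = taxonomy.rank_of(asv, "genus")
        if genus is None:
            out[asv] = "unknown"
        else:
            out[asv] = type_map.get(str(genus).lower(), "unknown")
    return out
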