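"""End-to-end orchestration: per-study networks, then meta-integration.

``run_study_pipeline`` turns one study's tables into a scaled association
network (filter -> network -> scaled WMA) with an attrition report.
``run_meta_pipeline`` aligns the study networks, computes intersection
distributions and their rewiring-null KS tests, builds the core network,
fits/selects the multiplex SBM and runs the group comparisons.

All randomness flows from one global seed through named substreams
(:func:`substream_seed`), so any stage can be re-run in isolation with
identical results.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict

from fermnet import association, core, preprocessing, sbm as sbm_mod, stats

logger = logging.getLogger("fermnet")


def substream_seed(global_seed: int, name: str) -> int:
    """Stable per-stage seed derived from the global seed and a stage name."""
    digest = hashlib.blake2b(
        f"{global_seed}:{name}".encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, with the published defaults."""

    seed: int = 0
    min_depth: int = preprocessing.DEFAULT_MIN_DEPTH
    min_samples: int = preprocessing.DEFAULT_MIN_SAMPLES
    min_mean_relabund: float = preprocessing.DEFAULT_MIN_MEAN_RELABUND
    clr_mode: str = "pseudocount"
    clr_pseudocount: float = 0.5
    clr_n_instances: int = 128
    jaccard_dist_max: float = 0.4
    corr_min: float = 0.5
    phi_max: float = 0.5
    signed_corr: bool = True
    min_share: int = 3
    null_sets: int = 100
    null_alpha: float = 0.05
    rewire_method: str = "degree_preserving_swaps"
    sbm_q_min: int = 1
    sbm_q_max: int = 8
    sbm_restarts: int = 5
    sbm_structural_zeros: bool = True

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = set(cls().__dict__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def thresholds(self) -> association.MetricThresholds:
        return association.MetricThresholds(
            jaccard_dist_max=self.jaccard_dist_max,
            corr_min=self.corr_min,
            phi_max=self.phi_max,
            signed_corr=self.signed_corr,
        )


@dataclass
class StudyResult:
    network: association.AssociationNetwork
    attrition: dict


def run_study_pipeline(counts, taxonomy, metadata,
                       config: PipelineConfig | None = None) -> StudyResult:
    """Filter one study's table and build its scaled association network."""
    config = config or PipelineConfig()
    n0_samples, n0_asvs = counts.shape
    cleaned = preprocessing.remove_nontarget(counts, taxonomy, metadata)
    n1_samples, n1_asvs = cleaned.shape
    filtered = preprocessing.filter_for_network(
        cleaned, config.min_depth, config.min_samples, config.min_mean_relabund
    )
    n2_samples, n2_asvs = filtered.shape
    net = association.build_association_network(
        filtered, taxonomy, metadata,
        th=config.thresholds(),
        clr_mode=config.clr_mode,
        clr_pseudocount=config.clr_pseudocount,
        clr_n_instances=config.clr_n_instances,
        seed=substream_seed(config.seed, f"clr:{net_id(metadata, counts)}"),
    )
    association.scale_wma(net)
    attrition = {
        "input_samples": n0_samples, "input_asvs": n0_asvs,
        "after_nontarget_samples": n1_samples, "after_nontarget_asvs": n1_asvs,
        "after_filter_samples": n2_samples, "after_filter_asvs": n2_asvs,
        "network_nodes": net.graph.number_of_nodes(),
        "network_edges": net.graph.number_of_edges(),
    }
    logger.info("study %s: %s", net.study_id, attrition)
    return StudyResult(network=net, attrition=attrition)


def net_id(metadata, counts) -> str:
    studies = metadata.data.loc[counts.sample_ids, "study_id"].unique()
    return str(studies[0]) if len(studies) == 1 else "+".join(map(str, studies))


@dataclass
class MetaResult:
    mplex: core.MultiplexNetwork
    core_network: core.CoreNetwork
    ks_results: dict[int, core.KsTestResult]
    sbm_results: sbm_mod.SBMResults
    comparisons: list


def run_meta_pipeline(networks, taxonomy=None,
                      config: PipelineConfig | None = None,
                      ks_mode: str = "edges") -> MetaResult:
    """Integrate per-study networks into core network, null tests and SBM."""
    config = config or PipelineConfig()
    mplex = core.align_networks(networks)
    L = mplex.n_layers

    ks_results = {}
    for m in range(2, L + 1):
        ks_results[m] = core.null_model_test(
            mplex, m, mode=ks_mode,
            n_sets=config.null_sets, alpha=config.null_alpha,
            method=config.rewire_method,
            seed=substream_seed(config.seed, f"null:{ks_mode}:{m}"),
        )

    scaled = {
        net.study_id: {
            n: attrs["scaled_wma"] for n, attrs in net.graph.nodes(data=True)
        }
        for net in networks
    }
    k = min(config.min_share, L)
    core_net = core.build_core_network(mplex, scaled, k=k, taxonomy=taxonomy)

    q_max = min(config.sbm_q_max, mplex.n_nodes)
    model = sbm_mod.MultiplexSBM.from_multiplex(
        mplex, structural_zeros=config.sbm_structural_zeros
    )
    fit = model.select(
        range(config.sbm_q_min, q_max + 1),
        n_restarts=config.sbm_restarts,
        seed=substream_seed(config.seed, "sbm"),
    )

    comparisons = []
    if taxonomy is not None and core_net.graph.number_of_nodes() > 0:
        try:
            comparisons = stats.compare_groups(
                core_net, grouping="order", value="scaled_wma",
                taxonomy=taxonomy,
            )
        except ValueError as exc:
            logger.warning("group comparison skipped: %s", exc)
    return MetaResult(
        mplex=mplex, core_network=core_net, ks_results=ks_results,
        sbm_results=fit, comparisons=comparisons,
    )
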