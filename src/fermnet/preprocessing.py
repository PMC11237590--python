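"""Sample/ASV filters and compositional transforms.

Before a per-study association network is built, the count table is reduced
to non-control samples with more than 15,000 reads, and to ASVs seen in at
least three of the kept samples with a mean relative abundance above 1e-5.
Read counts are compositional, so co-abundance analysis uses either plain
relative abundances (for rank/linear correlation) or the centered log-ratio
transform (for the proportionality statistic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from fermnet.io import CountTable, SampleMetadata, TaxonomyTable

#: default filters: strict read of "more than 15,000 reads", "at least three
#: samples", "average relative abundance greater than 1e-5"
DEFAULT_MIN_DEPTH = 15_000
DEFAULT_MIN_SAMPLES = 3
DEFAULT_MIN_MEAN_RELABUND = 1e-5


@dataclass
class RelativeAbundanceTable:
    """Row-normalized counts; each sample row sums to 1."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        sums = self.data.sum(axis=1).to_numpy()
        if self.data.shape[1] and not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("relative-abundance rows must sum to 1")

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


@dataclass
class ClrTable:
    """Per-sample centered log-ratios; each row sums to 0."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        sums = self.data.sum(axis=1).to_numpy()
        if self.data.shape[1] and not np.allclose(sums, 0.0, atol=1e-6):
            raise ValueError("clr rows must sum to 0")

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


def remove_nontarget(
    counts: CountTable,
    taxonomy: TaxonomyTable,
    metadata: SampleMetadata,
) -> CountTable:
    """Drop organelle ASVs and negative-control samples.

    ASVs whose family is Mitochondria, or whose order or class is
    Chloroplast, are 16S hits on plant organelles rather than bacteria.
    Samples flagged ``is_control`` are negative fermentation controls.
    """
    metadata.require_samples(counts.sample_ids)
    tax = taxonomy.data.reindex(counts.asv_ids)

    def _is(series: pd.Series, value: str) -> pd.Series:
        return series.fillna("").str.lower() == value

    organelle = (
        _is(tax["family"], "mitochondria")
        | _is(tax["order"], "chloroplast")
        | _is(tax["class"], "chloroplast")
    )
    keep_asvs = [a for a, bad in zip(counts.asv_ids, organelle) if not bad]
    controls = metadata.data.loc[counts.sample_ids, "is_control"]
    keep_samples = [s for s in counts.sample_ids if not controls[s]]
    if not keep_samples or not keep_asvs:
        warnings.warn("remove_nontarget produced an empty table", stacklevel=2)
    return CountTable(counts.data.loc[keep_samples, keep_asvs])


def filter_for_network(
    counts: CountTable,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    min_mean_relabund: float = DEFAULT_MIN_MEAN_RELABUND,
) -> CountTable:
    """Apply the network-construction filters, in order.

    1. keep samples with total reads strictly greater than ``min_depth``;
    2. over the kept samples, keep ASVs present (count > 0) in at least
       ``min_samples`` samples AND with mean relative abundance (zeros
       included) strictly greater than ``min_mean_relabund``.

    Raises ``ValueError`` if fewer than two samples survive — no network
    can be built from fewer.
    """
    depths = counts.sample_depths()
    kept_samples = depths.index[depths > min_depth]
    if len(kept_samples) < 2:
        raise ValueError(
            f"only {len(kept_samples)} samples exceed {min_depth} reads; "
            "at least 2 are required to build a network"
        )
    sub = counts.data.loc[kept_samples]
    rel = sub.div(sub.sum(axis=1), axis=0)
    n_present = (sub > 0).sum(axis=0)
    mean_rel = rel.mean(axis=0)
    keep = (n_present >= min_samples) & (mean_rel > min_mean_relabund)
    return CountTable(sub.loc[:, keep[keep].index])


def to_relative(counts: CountTable) -> RelativeAbundanceTable:
    """Counts -> per-sample relative abundances."""
    totals = counts.sample_depths()
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"zero-total samples cannot be normalized: {bad[:5]}")
    return RelativeAbundanceTable(counts.data.div(totals, axis=0))


def clr_transform(
    counts: CountTable,
    mode: str = "pseudocount",
    pseudocount: float = 0.5,
    n_instances: int = 128,
    seed: int | None = None,
) -> ClrTable:
    """Centered log-ratio transform of a count table.

    ``pseudocount`` mode is deterministic: clr(count + pseudocount).
    ``dirichlet_mc`` mirrors ALDEx2-style Monte-Carlo instances: the clr is
    averaged over ``n_instances`` draws of Dirichlet(count + 0.5) per
    sample (seeded).  clr rows sum to zero in both modes because the clr of
    any positive composition does.
    """
    x = counts.counts.astype(float)
    if mode == "pseudocount":
        if pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        logs = np.log(x + pseudocount)
        clr = logs - logs.mean(axis=1, keepdims=True)
    elif mode == "dirichlet_mc":
        rng = np.random.default_rng(seed)
        alpha = x + 0.5
        clr = np.zeros_like(x)
        for _ in range(n_instances):
            draws = rng.gamma(alpha)  # Dirichlet via normalized Gammas
            logs = np.log(draws)
            clr += logs - logs.mean(axis=1, keepdims=True)
        clr /= n_instances
    else:
        raise ValueError(f"unknown clr mode {mode!r}")
    frame = pd.DataFrame(clr, index=counts.sample_ids, columns=counts.asv_ids)
    return ClrTable(frame)
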