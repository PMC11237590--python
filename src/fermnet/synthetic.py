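"""Synthetic multi-study fermentation time series and planted multiplexes.

The generator emulates the shape of public fermented-vegetable 16S data
sets: several studies, each a handful of time points between 0 and 60
days, tens to hundreds of samples, sequencing depths around a 30,000-read
median, and a three-guild bacterial succession —

* an early, taxonomically diverse flora (including *Pseudomonadales*)
  peaking around day 1,
* a transient *Enterobacterales* bloom peaking around day 7,
* a *Lactobacillales* (LAB) community dominating from ~day 30.

Every ASV follows a Gaussian-in-time intensity curve; per-sample expected
compositions are the normalized intensities and observed counts are drawn
Dirichlet-multinomial at lognormal depth, so the data are overdispersed
and compositional like real amplicon counts.  Studies share a global pool
of ASVs (exact sequence identity) with guild-specific sharing rates:
mid-guild (*Enterobacterales*) ASVs are shared widely, late-guild LAB
ASVs rarely — the planted analogue of LAB being fermentation-specific.

``generate_planted_multiplex`` draws Poisson multiplex SBM graphs with
known labels for testing the clustering stage; weights are truncated to
the 0..4 support-count range the association stage produces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from fermnet.core import Layer, MultiplexNetwork
from fermnet.io import CountTable, SampleMetadata, TaxonomyTable, RANKS

_BASES = np.array(list("ACGT"))

#: guild -> (taxonomic order, peak day, peak sd in days)
GUILDS = {
    "early": ("Pseudomonadales", 1.0, 3.0),
    "mid": ("Enterobacterales", 7.0, 6.0),
    "late": ("Lactobacillales", 30.0, 12.0),
}

#: extra orders mixed into the early, diverse flora
DIVERSE_ORDERS = (
    "Flavobacteriales", "Bacillales", "Rhizobiales",
    "Xanthomonadales", "Sphingomonadales", "Burkholderiales",
)

_GENERA = {
    "Pseudomonadales": ["Pseudomonas", "Acinetobacter", "Moraxella"],
    "Enterobacterales": ["Klebsiella", "Citrobacter", "Serratia", "Erwinia",
                         "Pectobacterium", "Providencia", "Yersinia",
                         "Pseudocitrobacter", "Enterobacter"],
    "Lactobacillales": ["Leuconostoc", "Weissella", "Lactiplantibacillus",
                        "Latilactobacillus", "Levilactobacillus", "Pediococcus",
                        "Lactococcus", "Enterococcus", "Companilactobacillus",
                        "Vagococcus"],
}

_FAMILIES = {
    "Pseudomonadales": "Pseudomonadaceae",
    "Enterobacterales": "Enterobacteriaceae",
    "Lactobacillales": "Lactobacillaceae",
}


@dataclass
class AsvSpec:
    """One planted ASV: sequence identity, taxonomy and temporal niche."""

    sequence: str
    guild: str
    order: str
    genus: str
    peak_day: float
    width_days: float
    base_intensity: float
    shared: bool


@dataclass
class StudyConfig:
    """Conditions for one synthetic study.

    Defaults mirror the desk-scale collection used throughout the test
    suite: 40 samples over 6 time points within 0-60 days, ~30,000-read
    median lognormal depths and moderate Dirichlet overdispersion.
    """

    study_id: str
    n_samples: int = 40
    time_points: tuple = (0.0, 2.0, 5.0, 10.0, 20.0, 40.0)
    depth_log_mu: float = math.log(30_000.0)
    depth_log_sigma: float = 0.35
    n_specific: dict = field(
        default_factory=lambda: {"early": 55, "mid": 20, "late": 30}
    )
    dirichlet_concentration: float = 50.0
    n_control_samples: int = 0
    n_organelle_asvs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 10:
            raise ValueError("studies need more than 10 samples")
        if len(self.time_points) < 2:
            raise ValueError("studies need at least two time points")
        if any(t < 0 for t in self.time_points):
            raise ValueError("time points must be non-negative days")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be positive")


@dataclass
class SharedPoolConfig:
    """Global shared-ASV pool and per-guild sharing rates.

    Mid-guild ASVs are included in each study with high probability and
    late-guild ASVs with low probability, planting the pattern that
    *Enterobacterales* are shared between studies more often than
    *Lactobacillales*.
    """

    n_shared: dict = field(
        default_factory=lambda: {"early": 12, "mid": 20, "late": 16}
    )
    share_rate: dict = field(
        default_factory=lambda: {"early": 0.85, "mid": 0.95, "late": 0.7}
    )
    seed: int = 0


def _random_sequence(rng: np.random.Generator, length: int = 100) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _make_asv(rng, guild: str, shared: bool, diverse_early: bool) -> AsvSpec:
    order, peak, width = GUILDS[guild]
    if guild == "early" and diverse_early and rng.random() < 0.5:
        order = str(rng.choice(DIVERSE_ORDERS))
        genus = order.replace("ales", "") + "_genus"
    else:
        genus = str(rng.choice(_GENERA[GUILDS[guild][0]]))
    # heavy-tailed base intensities: few dominant ASVs, a long rare tail,
    # as in real amplicon tables; shared ASVs sit higher so they survive
    # the abundance filters in every study that contains them
    base = float(rng.lognormal(mean=2.0 if shared else 0.0, sigma=1.8))
    return AsvSpec(
        sequence=_random_sequence(rng),
        guild=guild,
        order=order,
        genus=genus,
        peak_day=float(peak + rng.normal(0.0, 0.15 * width)),
        width_days=float(width * rng.uniform(0.8, 1.25)),
        base_intensity=base,
        shared=shared,
    )


def make_shared_pool(cfg: SharedPoolConfig | None = None) -> list[AsvSpec]:
    """Draw the global pool of shared ASVs (reused across studies)."""
    cfg = cfg or SharedPoolConfig()
    rng = np.random.default_rng(cfg.seed)
    pool = []
    for guild, n in cfg.n_shared.items():
        for _ in range(n):
            pool.append(_make_asv(rng, guild, shared=True, diverse_early=True))
    return pool


def _intensity(spec: AsvSpec, times: np.ndarray) -> np.ndarray:
    z = (times - spec.peak_day) / spec.width_days
    return spec.base_intensity * np.exp(-0.5 * z * z)


def expected_composition(specs: list[AsvSpec], times) -> np.ndarray:
    """Noise-free expected relative abundances (samples x ASVs)."""
    times = np.asarray(times, dtype=float)
    w = np.stack([_intensity(s, times) for s in specs], axis=1)
    w = np.maximum(w, 1e-12)
    return w / w.sum(axis=1, keepdims=True)


def true_wma(specs: list[AsvSpec], times) -> np.ndarray:
    """Closed-form WMA of each planted ASV on its expected abundances."""
    comp = expected_composition(specs, times)
    times = np.asarray(times, dtype=float)
    return (comp * times[:, None]).sum(axis=0) / comp.sum(axis=0)


def generate_study(
    cfg: StudyConfig,
    shared_pool: list[AsvSpec] | None = None,
    pool_cfg: SharedPoolConfig | None = None,
) -> tuple[CountTable, TaxonomyTable, SampleMetadata]:
    """Generate one study's count table, taxonomy and metadata.

    If ``shared_pool`` is given, shared ASVs are drawn from it at the
    per-guild rates of ``pool_cfg`` (defaults), so that repeated calls for
    different studies overlap on exact sequences.  Fully deterministic
    given the config seeds.
    """
    rng = np.random.default_rng(cfg.seed)
    pool_cfg = pool_cfg or SharedPoolConfig()
    if shared_pool is None:
        shared_pool = make_shared_pool(pool_cfg)

    specs: list[AsvSpec] = []
    for spec in shared_pool:
        if rng.random() < pool_cfg.share_rate[spec.guild]:
            specs.append(spec)
    for guild, n in cfg.n_specific.items():
        for _ in range(n):
            specs.append(_make_asv(rng, guild, shared=False, diverse_early=True))

    n_rep, extra = divmod(cfg.n_samples, len(cfg.time_points))
    times = []
    for i, t in enumerate(cfg.time_points):
        times.extend([float(t)] * (n_rep + (1 if i < extra else 0)))
    times = np.asarray(times)

    comp = expected_composition(specs, times)
    alpha = cfg.dirichlet_concentration * comp
    depths = rng.lognormal(cfg.depth_log_mu, cfg.depth_log_sigma, size=len(times))
    counts = np.zeros((len(times), len(specs)), dtype=np.int64)
    for s in range(len(times)):
        gam = rng.gamma(np.maximum(alpha[s], 1e-8))
        p = gam / gam.sum()
        counts[s] = rng.multinomial(int(depths[s]), p)

    sample_ids = [
        f"{cfg.study_id}_s{i:03d}_d{times[i]:g}" for i in range(len(times))
    ]
    asv_ids = [s.sequence for s in specs]
    is_control = [False] * len(times)

    # optional organelle contamination + negative controls for filter tests
    tax_rows = {
        s.sequence: ("Bacteria", "planted", "planted", s.order,
                     _FAMILIES.get(s.order, s.order + "aceae"), s.genus)
        for s in specs
    }
    if cfg.n_organelle_asvs:
        for k in range(cfg.n_organelle_asvs):
            seq = _random_sequence(rng)
            asv_ids.append(seq)
            tax_rows[seq] = ("Eukaryota", "planted", "planted", "Rickettsiales",
                            "Mitochondria", None)
            org = rng.multinomial(200, np.full(len(times), 1 / len(times)))
            counts = np.column_stack([counts, org])
    if cfg.n_control_samples:
        blank = np.zeros((cfg.n_control_samples, counts.shape[1]), dtype=np.int64)
        blank[:, : min(3, counts.shape[1])] = 40
        counts = np.vstack([counts, blank])
        for k in range(cfg.n_control_samples):
            sample_ids.append(f"{cfg.study_id}_control{k}")
            times = np.append(times, 0.0)
            is_control.append(True)

    table = CountTable(pd.DataFrame(counts, index=sample_ids, columns=asv_ids))
    taxonomy = TaxonomyTable(pd.DataFrame(
        [tax_rows[a] for a in asv_ids], index=asv_ids, columns=list(RANKS)
    ))
    metadata = SampleMetadata(pd.DataFrame({
        "study_id": cfg.study_id,
        "time_days": times,
        "is_control": is_control,
        "is_inoculated": False,
    }, index=sample_ids))
    return table, taxonomy, metadata


def default_collection_configs(
    n_studies: int = 4, base_seed: int = 0
) -> list[StudyConfig]:
    """The default desk-scale collection: 4 studies x 40 samples x 6 times."""
    return [
        StudyConfig(study_id=f"study{i + 1}", seed=base_seed * 1000 + i)
        for i in range(n_studies)
    ]


def generate_meta_collection(
    cfgs: list[StudyConfig] | None = None,
    shared_pool_seed: int = 0,
    pool_cfg: SharedPoolConfig | None = None,
):
    """Generate a multi-study collection over one shared ASV pool.

    Returns ``(studies, shared_pool)`` where studies is a list of
    (CountTable, TaxonomyTable, SampleMetadata) triples.
    """
    cfgs = cfgs if cfgs is not None else default_collection_configs()
    pool_cfg = pool_cfg or SharedPoolConfig(seed=shared_pool_seed)
    pool = make_shared_pool(pool_cfg)
    studies = [generate_study(cfg, shared_pool=pool, pool_cfg=pool_cfg)
               for cfg in cfgs]
    return studies, pool


@dataclass
class PlantedMultiplexConfig:
    """Planted Poisson multiplex SBM: N nodes, L layers, Q blocks."""

    N: int = 60
    L: int = 4
    Q: int = 2
    pi: np.ndarray | None = None
    lam: np.ndarray | None = None  # L x Q x Q rates
    lam_in: float = 4.0
    lam_out: float = 0.2
    truncate_at: int = 4
    seed: int = 0

    def resolved(self) -> tuple[np.ndarray, np.ndarray]:
        pi = (np.full(self.Q, 1.0 / self.Q) if self.pi is None
              else np.asarray(self.pi, dtype=float))
        if not math.isclose(pi.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("pi must sum to 1")
        if self.lam is None:
            base = np.full((self.Q, self.Q), self.lam_out)
            np.fill_diagonal(base, self.lam_in)
            lam = np.tile(base, (self.L, 1, 1))
        else:
            lam = np.asarray(self.lam, dtype=float)
        if lam.shape != (self.L, self.Q, self.Q) or np.any(lam < 0):
            raise ValueError("lam must be a non-negative L x Q x Q array")
        return pi, lam


def generate_planted_multiplex(
    cfg: PlantedMultiplexConfig,
) -> tuple[MultiplexNetwork, np.ndarray]:
    """Draw a multiplex with known block labels.

    Labels z ~ Categorical(pi); for every unordered pair, layer l draws
    A^l_ij ~ Poisson(lam^l_{z_i z_j}), truncated at ``truncate_at`` to stay
    in the support-count range of real layers.  All nodes are present in
    all layers.
    """
    pi, lam = cfg.resolved()
    rng = np.random.default_rng(cfg.seed)
    labels = rng.choice(cfg.Q, size=cfg.N, p=pi)
    node_ids = [f"node{i:04d}" for i in range(cfg.N)]
    iu = np.triu_indices(cfg.N, k=1)
    layers = []
    for l in range(cfg.L):
        rates = lam[l][labels[:, None], labels[None, :]]
        draws = rng.poisson(rates[iu])
        if cfg.truncate_at is not None:
            draws = np.minimum(draws, cfg.truncate_at)
        adj = np.zeros((cfg.N, cfg.N), dtype=np.int64)
        adj[iu] = draws
        adj += adj.T
        layers.append(Layer(f"layer{l}", adj, np.ones(cfg.N, dtype=bool)))
    mplex = MultiplexNetwork(node_ids=node_ids, layers=layers)
    mplex.validate()
    return mplex, labels
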