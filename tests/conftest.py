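import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from fermnet.io import CountTable, SampleMetadata, TaxonomyTable, RANKS

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_counts(values, sample_ids=None, asv_ids=None) -> CountTable:
    values = np.asarray(values)
    sample_ids = sample_ids or [f"s{i}" for i in range(values.shape[0])]
    asv_ids = asv_ids or [f"asv{j}" for j in range(values.shape[1])]
    return CountTable(pd.DataFrame(values, index=sample_ids, columns=asv_ids))


def make_taxonomy(rows: dict) -> TaxonomyTable:
    """rows: asv_id -> dict of rank overrides (missing ranks None)."""
    frame = pd.DataFrame(
        {asv: {r: over.get(r) for r in RANKS} for asv, over in rows.items()}
    ).T
    frame.index.name = "asv_id"
    return TaxonomyTable(frame[list(RANKS)])


def make_metadata(sample_ids, times=None, study="study1", controls=None):
    n = len(sample_ids)
    frame = pd.DataFrame(
        {
            "study_id": study,
            "time_days": times if times is not None else np.zeros(n),
            "is_control": controls if controls is not None else [False] * n,
            "is_inoculated": False,
        },
        index=list(sample_ids),
    )
    return SampleMetadata(frame)


@pytest.fixture(scope="session")
def synthetic_study():
    from fermnet.synthetic import StudyConfig, generate_study

    return generate_study(StudyConfig(study_id="fixture_study", seed=7))


@pytest.fixture(scope="session")
def synthetic_collection():
    """Default 4-study collection plus its shared ASV pool."""
    from fermnet.synthetic import generate_meta_collection

    return generate_meta_collection(shared_pool_seed=11)


@pytest.fixture(scope="session")
def collection_networks(synthetic_collection):
    """Scaled association networks for the default collection."""
    from fermnet.pipeline import run_study_pipeline

    studies, pool = synthetic_collection
    nets = [run_study_pipeline(c, t, m).network for c, t, m in studies]
    return nets, studies, pool
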