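import numpy as np
import pandas as pd
import pytest

from exometab.config import RunConfig
from exometab.simulate import (
    FeatureGroundTruth,
    PlantedFeature,
    generate_feature_tables,
    random_truth,
)


@pytest.fixture
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture
def clean_truth() -> FeatureGroundTruth:
    """Zero-jitter, high-separation truth: presence must equal membership."""
    rng = np.random.default_rng(123)
    truth = random_truth(
        60,
        rng,
        jitter_mz_sd=0.0,
        jitter_rt_sd=0.0,
        height_meanlog=np.log(1e5),
        height_sdlog=0.2,
        blank_contaminant_fraction=0.0,
    )
    return truth


@pytest.fixture
def clean_tables(clean_truth):
    return generate_feature_tables(clean_truth, seed=7)


def toy_feature_table(rows, samples):
    """Small feature table: rows = (feature_id, mz, rt, heights...)."""
    recs = []
    for fid, mz, rt, *heights in rows:
        recs.append({"feature_id": fid, "mz": mz, "rt": rt, **dict(zip(samples, heights))})
    return pd.DataFrame(recs).set_index("feature_id")


def toy_metadata(entries):
    """entries = (sample_id, batch, species, sample_type, replicate)."""
    return pd.DataFrame(
        entries, columns=["sample_id", "batch", "species", "sample_type", "replicate"]
    )
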