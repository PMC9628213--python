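import numpy as np
import pandas as pd
import pytest

from gutmarkers import CountTable, SampleMetadata, SyntheticConfig, simulate_dataset
from gutmarkers.io import TaxonomyTable


@pytest.fixture
def tiny_counts() -> CountTable:
    df = pd.DataFrame(
        {"S1": [3, 1, 0, 2], "S2": [0, 2, 4, 1], "S3": [5, 0, 1, 0]},
        index=["ASV1", "ASV2", "ASV3", "ASV4"],
    )
    return CountTable(df)


@pytest.fixture
def tiny_taxonomy() -> TaxonomyTable:
    lineages = {
        "ASV1": "k__Bacteria;p__Firmicutes;c__Bacilli;o__Lactobacillales;"
                "f__Streptococcaceae;g__Streptococcus;s__unclassified",
        "ASV2": "k__Bacteria;p__Firmicutes;c__Bacilli;o__Lactobacillales;"
                "f__Streptococcaceae;g__Streptococcus",
        "ASV3": "k__Bacteria;p__Bacteroidota;c__Bacteroidia;o__Bacteroidales;"
                "f__Bacteroidaceae;g__Bacteroides",
        "ASV4": "k__Bacteria;p__Firmicutes;c__Clostridia;o__Oscillospirales;"
                "f__Ruminococcaceae",
    }
    return TaxonomyTable.from_lineage_strings(lineages)


@pytest.fixture
def tiny_metadata() -> SampleMetadata:
    df = pd.DataFrame(
        {"group": ["case", "case", "control"], "age": [60.0, 55.0, 50.0]},
        index=["S1", "S2", "S3"],
    )
    return SampleMetadata(df)


@pytest.fixture(scope="session")
def small_dataset():
    """A modest two-group dataset with planted effects, shared across tests."""
    cfg = SyntheticConfig(
        n_per_group=12,
        n_features=100,
        depth_range=(4000, 8000),
        n_differential=4,
        fold_changes=5.0,
        seed=11,
    )
    return simulate_dataset(cfg)
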