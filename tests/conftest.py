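import numpy as np
import pandas as pd
import pytest

from emonet import (
    EmotionTaxonomy,
    ReportDataset,
    SyntheticConfig,
    dataset_from_arrays,
    default_taxonomy,
    generate_dataset,
)


@pytest.fixture(scope="session")
def taxonomy():
    return default_taxonomy()


@pytest.fixture(scope="session")
def toy_taxonomy():
    """4-emotion taxonomy (A, B positive; C, D negative) for rule tests."""
    return EmotionTaxonomy(
        emotions=("A", "B", "C", "D"),
        valence={"A": "positive", "B": "positive", "C": "negative", "D": "negative"},
    )


@pytest.fixture(scope="session")
def small_config():
    """Small but nested synthetic setup: 60 participants, ~5 prompts each."""
    return SyntheticConfig(n_participants=60, prompts_per_participant=5, seed=202)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture
def wide_csv(tmp_path, taxonomy):
    """Two-row wide CSV covering all 18 indicator columns."""
    rows = []
    for i, ind in enumerate([[1] + [0] * 17, [0] * 17 + [1]]):
        row = {"participant_id": f"p{i}", "timestamp": f"2013-03-0{i+1}T09:0{i}:00"}
        row.update(dict(zip(taxonomy, ind)))
        rows.append(row)
    path = tmp_path / "wide.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def make_dataset(indicators, participant_ids=None, taxonomy=None, **kw):
    """Shortcut wrapper used across test modules."""
    return dataset_from_arrays(
        np.asarray(indicators), participant_ids=participant_ids, taxonomy=taxonomy, **kw
    )
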