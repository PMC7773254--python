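import numpy as np
import pandas as pd
import pytest

import phenoscreen as ps


@pytest.fixture
def continuous_frame() -> pd.DataFrame:
    """Small screening dataset with a real genotype and bodyweight effect."""
    df, _ = ps.gen_continuous_dataset(ps.SimConfig(
        n_control=200, n_batches=10,
        beta={"intercept": 10.0, "genotype": 1.0, "sex": 0.5,
              "interaction": 0.0, "bodyweight": 0.1},
        seed=11))
    return df


@pytest.fixture
def continuous_ds(continuous_frame) -> ps.PhenDataset:
    return ps.prepare(ps.RawTable(continuous_frame),
                      ps.default_spec("LMM", seed=1))


@pytest.fixture
def categorical_ds() -> ps.PhenDataset:
    df, _ = ps.gen_categorical_dataset(ps.SimConfig(
        n_control=150, n_batches=8,
        categorical_rates={"control": [0.9, 0.1], "mutant": [0.5, 0.5]},
        seed=21))
    return ps.prepare(ps.RawTable(df), ps.default_spec("FisherExact", seed=2))


def raw(df: pd.DataFrame) -> ps.RawTable:
    return ps.RawTable(df)
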