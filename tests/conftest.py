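import numpy as np
import pandas as pd
import pytest

from ddpmix.synthetic import FinishTimeSpec, SplitSpec, gen_finish_times, gen_split_profiles


@pytest.fixture(scope="session")
def two_lump_data():
    """Two well-separated finishing-time clusters, one gender, five ages."""
    spec = FinishTimeSpec(
        true_means=(180.0, 240.0),
        true_weights=(0.5, 0.5),
        ages=range(30, 35),
        genders=(0,),
        noise_sd=6.0,
        n_per_group=40,
        seed=1,
    )
    return gen_finish_times(spec)


@pytest.fixture(scope="session")
def split_cohort():
    """Three pacing patterns, two groups with different mixing."""
    P = np.array(
        [
            [0.22, 0.20, 0.20, 0.19, 0.19],
            [0.17, 0.19, 0.20, 0.21, 0.23],
            [0.15, 0.17, 0.20, 0.23, 0.25],
        ]
    )
    P = P / P.sum(axis=1, keepdims=True)
    spec = SplitSpec(
        true_patterns=P,
        tau=5000.0,
        group_mixing=[[0.5, 0.3, 0.2], [0.2, 0.3, 0.5]],
        interval_lengths=(5, 5, 5, 5, 2.195),
        n_per_group=200,
        seed=3,
    )
    return gen_split_profiles(spec)


def profiles_from(df: pd.DataFrame):
    cum = df[[c for c in df.columns if c.startswith("split_")]].to_numpy()
    return np.diff(cum, prepend=0.0, axis=1) / cum[:, -1:], cum, df["group"].to_numpy()
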