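import numpy as np
import pandas as pd
import pytest

from mirnomics import synthdata
from mirnomics.iokit import ExpressionMatrix


@pytest.fixture(scope="session")
def small_cohort():
    cfg = synthdata.SimConfig(
        seed=5, n_mirna=80, n_mrna=120, n_protein=60,
        n_modules=2, module_size=20, cluster_size=22,
    )
    return synthdata.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def module_cohorts():
    """Twenty seeds of the planted-module configuration (3 modules x 40
    miRNAs, 30 samples) shared by the network recovery tests."""
    bundles = []
    for seed in range(20):
        cfg = synthdata.SimConfig(
            seed=seed, n_mirna=120, n_mrna=30, n_protein=10,
            n_modules=3, module_size=40, cluster_size=0, de_fraction=0.0,
        )
        bundles.append(synthdata.simulate_cohort(cfg))
    return bundles


def make_matrix(values, feature_class="mature", groups=None, is_counts=True):
    """Small ExpressionMatrix helper for unit tests."""
    df = pd.DataFrame(values)
    df.index = [str(i) for i in df.index]
    df.columns = [str(c) for c in df.columns]
    if groups is None:
        half = df.shape[1] // 2
        groups = ["DP"] * half + ["DR"] * (df.shape[1] - half)
    meta = pd.DataFrame({"group": groups, "sex": "F"}, index=df.columns)
    cls = pd.Series(feature_class, index=df.index)
    return ExpressionMatrix(values=df, feature_class=cls, sample_meta=meta,
                            is_counts=is_counts)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
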