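import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import bayescart as bc

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study_table():
    """Synthetic stand-in at the study conditions: 6 classes x 100,
    72 features, first 10 informative at effect size 1.5."""
    return bc.generate_table(bc.TableSpec(seed=11))


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny separable dataset for fast sampler runs."""
    table = bc.generate_table(
        bc.TableSpec(n_classes=3, n_per_class=30, n_features=8,
                     informative_idx=(1, 2), effect_size=2.5, seed=5)
    )
    X, y = bc.split_xy(table)
    return bc.Dataset(X, y)


@pytest.fixture(scope="session")
def small_ensemble(small_dataset):
    """Quick posterior ensemble shared across read-only tests."""
    cfg = bc.ChainConfig(burn_in=1_000, post_burn_in=700, thin=7, seed=3)
    ens, diag = bc.run_chain(small_dataset, cfg)
    return ens, diag


@pytest.fixture(scope="session")
def wide_ensemble(study_table):
    """Posterior ensemble over the 72-feature study table (one chain,
    desk-scale settings), with its train/test split."""
    from sklearn.model_selection import train_test_split

    X, y = bc.split_xy(study_table)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=1 / 3, stratify=y, random_state=0
    )
    clf = bc.BayesianTreeClassifier(
        burn_in=5_000, post_burn_in=2_000, thin=7, random_state=1
    ).fit(X_tr, y_tr)
    return clf, X_te, y_te
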