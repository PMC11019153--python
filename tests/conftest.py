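"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pytest

from senotex.datasets import make_condition_dataset, make_qc_dataset


@pytest.fixture(scope="session")
def qc_small():
    """50 good + 50 bad labeled detail images with extracted features."""
    df, labels, truths = make_qc_dataset(50, 50, seed=11)
    return df, np.asarray(labels), truths


@pytest.fixture(scope="session")
def two_cond_train():
    """Balanced proliferating/senescent training feature table."""
    df, labels = make_condition_dataset(25, ("proliferating", "senescent"), seed=21)
    return df, np.asarray(labels)


@pytest.fixture(scope="session")
def two_cond_test():
    """Held-out proliferating/senescent feature table (independent seed)."""
    df, labels = make_condition_dataset(15, ("proliferating", "senescent"), seed=22)
    return df, np.asarray(labels)
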