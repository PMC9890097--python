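import numpy as np
import pytest

import quollacc as q


@pytest.fixture(scope="session")
def regimes():
    return q.default_regimes()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def labelled_features():
    """A balanced labelled feature table (12 classes x 60 epochs)."""
    return q.make_training_set(n_per_class=60, seed=5)


@pytest.fixture(scope="session")
def trained_model(labelled_features):
    """A trained, labelled 7x10 SOM plus its held-out test split."""
    X = labelled_features.drop(columns=["epoch_s", "hour", "behavior"])
    y = labelled_features["behavior"].to_numpy(object)
    (tr_X, tr_y), (te_X, te_y) = q.split_data(X, y, q.TrainTestSplit(seed=1))
    model = q.train_som(tr_X, seed=2)
    model = q.label_nodes(model, tr_X, tr_y)
    return model, (tr_X, tr_y), (te_X, te_y)
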