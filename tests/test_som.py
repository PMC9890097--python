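"""SOM training, BMU search, node labelling and prediction."""

import numpy as np
import pandas as pd
import pytest

import quollacc as q
from quollacc.som import SOMModel, quantization_error


def two_cluster_data(n, seed, sep=8.0):
    """Two well-separated Gaussian blobs in 25-d."""
    rng = np.random.default_rng(seed)
    d = 25
    a = rng.normal(0.0, 1.0, (n // 2, d))
    b = rng.normal(sep / np.sqrt(d), 1.0, (n - n // 2, d))
    X = np.vstack([a, b])
    y = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2), dtype=object)
    perm = rng.permutation(n)
    return X[perm], y[perm]


class TestSplit:
    def test_80_20_partition(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 5)))
        y = np.repeat(["A", "B"], 50)
        (trX, trY), (teX, teY) = q.split_data(X, y, q.TrainTestSplit(seed=0))
        assert len(trX) == 80 and len(teX) == 20
        assert sorted(np.r_[trX.index, teX.index].tolist()) == list(range(100))

    def test_minimal_class_split_half(self, rng):
        X = pd.DataFrame(rng.normal(size=(2, 3)))
        y = np.array(["A", "A"], dtype=object)
        (trX, _), (teX, _) = q.split_data(
            X, y, q.TrainTestSplit(train_fraction=0.5, seed=0))
        assert len(trX) == 1 and len(teX) == 1

    def test_same_seed_same_partition(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 4)))
        y = np.repeat(["A", "B", "C"], 20)
        s = q.TrainTestSplit(seed=11)
        (a, _), _ = q.split_data(X, y, s)
        (b, _), _ = q.split_data(X, y, s)
        pd.testing.assert_frame_equal(a, b)

    def test_singleton_class_rejected_by_name(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 3)))
        y = np.array(["A", "A", "A", "A", "Jumping"], dtype=object)
        with pytest.raises(ValueError, match="Jumping"):
            q.split_data(X, y, q.TrainTestSplit())

    def test_stratification_balances_classes(self, rng):
        X = pd.DataFrame(rng.normal(size=(200, 4)))
        y = np.repeat(["A", "B", "C", "D"], 50)
        (_, trY), (_, teY) = q.split_data(X, y, q.TrainTestSplit(seed=2))
        for cls in "ABCD":
            assert np.sum(trY == cls) == 40
            assert np.sum(teY == cls) == 10


class TestTraining:
    def test_identical_seed_identical_codebook(self, rng):
        X = rng.normal(size=(200, 6))
        a = q.train_som(X, grid_shape=(4, 4), seed=3, n_iter=1500)
        b = q.train_som(X, grid_shape=(4, 4), seed=3, n_iter=1500)
        assert np.array_equal(a.codebook, b.codebook)

    def test_training_reduces_quantization_error(self, rng):
        X = rng.normal(size=(300, 8))
        m = q.train_som(X, grid_shape=(5, 5), seed=1)
        assert m.quantization_error <= m.initial_quantization_error

    def test_zero_learning_rate_leaves_codebook_fixed(self, rng):
        X = rng.normal(size=(100, 4))
        m = q.train_som(X, grid_shape=(3, 3), seed=5, lr=(0.0, 0.0),
                        n_iter=500)
        assert np.array_equal(m.codebook, m.initial_codebook)

    def test_non_finite_rows_rejected_with_index(self, rng):
        X = rng.normal(size=(50, 4))
        X[17, 2] = np.nan
        with pytest.raises(ValueError, match="17"):
            q.train_som(X, grid_shape=(3, 3), seed=0)

    def test_zero_variance_feature_dropped_with_warning(self, rng):
        X = rng.normal(size=(100, 5))
        X[:, 3] = 2.5
        with pytest.warns(UserWarning, match="zero-variance"):
            m = q.train_som(X, grid_shape=(3, 3), seed=0, n_iter=500)
        assert m.codebook.shape[1] == 4
        assert (m.feature_sds > 0).all()

    def test_small_training_set_warns(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.warns(UserWarning, match="under-determined"):
            q.train_som(X, grid_shape=(7, 10), seed=0, n_iter=200)

    def test_separated_clusters_win_disjoint_nodes(self):
        X, y = two_cluster_data(400, seed=7)
        m = q.train_som(X, grid_shape=(7, 10), seed=8)
        winners = q.bmu_batch(m, X)
        assert set(winners[y == "A"]).isdisjoint(winners[y == "B"])


class TestBMU:
    def test_codebook_vector_maps_to_its_node(self, trained_model):
        model, _, _ = trained_model
        # undo z-scoring so the input equals codebook row 13 exactly
        vec = model.codebook[13] * model.feature_sds + model.feature_means
        assert q.bmu(model, vec) == 13

    def test_matches_brute_force_argmin(self, trained_model, rng):
        model, _, _ = trained_model
        X = rng.normal(0, 2, (1000, len(model.kept)))
        got = q.bmu_batch(model, X)
        Z = model.zscore(X)
        want = np.array([
            int(np.argmin([np.sum((z - w) ** 2) for w in model.codebook]))
            for z in Z])
        assert np.array_equal(got, want)

    def test_tie_breaks_to_lower_index(self):
        cb = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 5.0]])
        m = SOMModel(grid_shape=(1, 3), codebook=cb,
                     feature_names=["a", "b"], kept=np.array([0, 1]),
                     feature_means=np.zeros(2), feature_sds=np.ones(2), seed=0)
        # origin is exactly equidistant from nodes 0 and 1
        assert q.bmu(m, np.zeros(2)) == 0

    def test_dimension_mismatch_rejected(self, trained_model):
        model, _, _ = trained_model
        with pytest.raises(ValueError, match="dimension"):
            q.bmu(model, np.zeros(7))


class TestLabelling:
    def test_majority_vote_matches_recount(self, trained_model):
        model, (tr_X, tr_y), _ = trained_model
        winners = q.bmu_batch(model, tr_X)
        from collections import Counter
        overall = Counter(tr_y)
        for node in range(model.n_nodes):
            votes = Counter(tr_y[winners == node])
            if votes:
                best = max(votes.values())
                cands = sorted((c for c, v in votes.items() if v == best),
                               key=lambda c: (-overall[c], c))
                assert model.node_labels[node] == cands[0]

    def test_every_node_labelled(self, trained_model):
        model, _, _ = trained_model
        assert all(lab in q.BEHAVIORS for lab in model.node_labels)

    def test_empty_node_inherits_nearest_label(self):
        cb = np.array([[0.0, 0.0], [10.0, 0.0], [0.2, 0.0]])
        m = SOMModel(grid_shape=(1, 3), codebook=cb,
                     feature_names=["a", "b"], kept=np.array([0, 1]),
                     feature_means=np.zeros(2), feature_sds=np.ones(2), seed=0)
        X = np.array([[0.0, 0.0], [10.0, 0.0]])
        y = np.array(["Sitting", "Walking"], dtype=object)
        m = q.label_nodes(m, X, y)
        # node 2 wins nothing; its nearest labelled codebook is node 0
        assert m.node_labels[2] == "Sitting"

    def test_no_training_data_rejected(self, trained_model):
        model, _, _ = trained_model
        with pytest.raises(ValueError):
            q.label_nodes(model, np.empty((0, len(model.kept))),
                          np.array([], dtype=object))


class TestPredict:
    def test_unlabelled_model_rejected(self, rng):
        X = rng.normal(size=(100, 4))
        m = q.train_som(X, grid_shape=(3, 3), seed=0, n_iter=500)
        with pytest.raises(ValueError, match="label"):
            q.predict(m, X)

    def test_output_length_and_statelessness(self, trained_model, rng):
        model, _, (te_X, _) = trained_model
        pred = q.predict(model, te_X)
        assert len(pred) == len(te_X)
        # pointwise: prediction of a row unchanged by appended rows
        both = q.predict(model, pd.concat([te_X, te_X]))
        assert np.array_equal(both[: len(te_X)], pred)

    def test_training_epochs_self_consistent(self, trained_model):
        model, (tr_X, tr_y), _ = trained_model
        agree = (q.predict(model, tr_X) == tr_y).mean()
        assert agree >= 0.95

    def test_two_cluster_holdout_accuracy(self):
        X, y = two_cluster_data(2000, seed=21)
        (trX, trY), (teX, teY) = q.split_data(
            pd.DataFrame(X), y, q.TrainTestSplit(seed=22))
        m = q.label_nodes(q.train_som(trX, seed=23), trX, trY)
        acc = (q.predict(m, teX) == teY).mean()
        assert acc >= 0.99


class TestSerialization:
    def test_round_trip(self, trained_model, tmp_path):
        model, _, (te_X, _) = trained_model
        path = tmp_path / "som.json"
        model.save(path)
        loaded = SOMModel.load(path)
        assert loaded.node_labels == model.node_labels
        assert np.allclose(loaded.codebook, model.codebook)
        assert np.array_equal(q.predict(loaded, te_X), q.predict(model, te_X))

    def test_foreign_file_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"format": "something-else"}')
        with pytest.raises(ValueError, match="not a quollacc"):
            SOMModel.load(path)


def test_quantization_error_helper_consistent(trained_model):
    model, (tr_X, _), _ = trained_model
    assert quantization_error(model, tr_X) == pytest.approx(
        model.quantization_error, rel=1e-9)
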