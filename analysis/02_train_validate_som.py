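#!/usr/bin/env python
"""Train the 7x10 SOM on the labelled training set and validate it.

Splits the balanced training set 80/20, trains the map, labels nodes by
majority vote and reports the held-out confusion matrix with per-behaviour
sensitivity, precision, specificity and accuracy.
"""

from pathlib import Path

import quollacc as q

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 2


def main():
    RESULTS.mkdir(exist_ok=True)
    feats = q.make_training_set(n_per_class=167, seed=SEED)
    X = feats.drop(columns=["epoch_s", "hour", "behavior"])
    y = feats["behavior"].to_numpy(object)
    (trX, trY), (teX, teY) = q.split_data(X, y, q.TrainTestSplit(seed=SEED))
    model = q.train_som(trX, grid_shape=(7, 10), seed=SEED)
    print(f"quantization error: {model.initial_quantization_error:.3f} "
          f"(random init) -> {model.quantization_error:.3f} (trained)")
    model = q.label_nodes(model, trX, trY)

    cm = q.confusion(teY, q.predict(model, teX))
    metrics = q.metrics_table(cm)
    cm.reset_index(names="true").to_csv(RESULTS / "som_confusion.csv",
                                        index=False)
    metrics.reset_index(names="behavior").to_csv(
        RESULTS / "som_accuracy_metrics.csv", index=False)
    model.save(RESULTS / "som_model.json")

    print(f"held-out epochs: {len(teY)}; overall accuracy "
          f"{q.overall_accuracy(cm):.4f}")
    print("per-class sensitivity range: "
          f"{metrics['sensitivity'].min():.3f}-{metrics['sensitivity'].max():.3f}")
    print(f"tables -> {RESULTS}")


if __name__ == "__main__":
    main()
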