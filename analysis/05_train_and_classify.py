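#!/usr/bin/env python
"""Score the qPCR validation panel, train the discriminant, classify.

Converts the triplicate Ct wells of the 7 + 5 validation panel to
x = log10(CCND1/CDKN2A) at efficiency 2, trains the one-dimensional
Fisher discriminant (midpoint-of-means threshold), classifies the panel
with both the trained model and the published reference model
(threshold 0.404), and reports both accuracies. Writes
results/model.json and results/calls.tsv.
"""

from pathlib import Path

import pandas as pd

from rbratio import classifier as clf
from rbratio import io as rio

DATA = Path("results/data")


def accuracy(preds, labels) -> float:
    return sum((p.call == "positive") == (labels[p.sample_id] == 1) for p in preds) / len(preds)


def main() -> None:
    ct = rio.read_ct_table(DATA / "validation.ct.csv")
    labels = rio.read_labels(DATA / "validation.labels.tsv")
    scores = clf.scores_from_ct_table(ct, efficiency=2.0)

    trained = clf.train_discriminant(scores, labels)
    clf.save_model(trained, "results/model.json")
    preds = clf.classify(scores, trained)
    pd.DataFrame(
        {
            "sample_id": [p.sample_id for p in preds],
            "x": [p.x for p in preds],
            "threshold": trained.threshold,
            "call": [p.call for p in preds],
            "margin": [p.margin for p in preds],
        }
    ).to_csv("results/calls.tsv", sep="\t", index=False)

    published = clf.published_model()
    preds_pub = clf.classify(scores, published)

    n = len(preds)
    print(f"trained threshold: {trained.threshold:.4f} "
          f"(published reference: {published.threshold})")
    print(f"trained-model accuracy:   {accuracy(preds, labels):.0%} "
          f"({int(accuracy(preds, labels) * n)}/{n})")
    print(f"published-model accuracy: {accuracy(preds_pub, labels):.0%} "
          f"({int(accuracy(preds_pub, labels) * n)}/{n})")


if __name__ == "__main__":
    main()
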