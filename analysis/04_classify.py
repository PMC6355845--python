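"""Train LR / RF / DNN on the object features and evaluate on held-out objects.

Stratified split of all labelled objects first, then the training side is
resampled to a balanced 150 objects per class (the "balanced" protocol in
docs/methods.md).  Writes per-model metrics, confusion matrices and
whole-scene predictions.

Usage: python analysis/04_classify.py [--features results/features.csv]
       [--outdir results/classification] [--seed 0]
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from mobia.classes import DEFAULT_SCHEME
from mobia.classification import (
    LabelledSet,
    MODEL_KINDS,
    evaluate,
    predict,
    split_train_test,
    train,
)
from mobia.features import FEATURE_COLUMNS
from mobia.pipeline import stage_seed


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--features", default="results/features.csv")
    ap.add_argument("--outdir", default="results/classification")
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--per-class", type=int, default=150)
    ap.add_argument("--train-fraction", type=float, default=0.15)
    args = ap.parse_args()

    out = Path(args.outdir)
    out.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(args.features, index_col=0)

    keep = table["label"] != DEFAULT_SCHEME.excluded
    full = LabelledSet(
        np.asarray(table.index[keep]),
        table.loc[keep, FEATURE_COLUMNS].reset_index(drop=True),
        np.asarray(table.loc[keep, "label"]),
        DEFAULT_SCHEME,
    )
    train_set, test_set = split_train_test(
        full, args.train_fraction, stage_seed(args.seed, "split")
    )
    rng = np.random.default_rng(stage_seed(args.seed, "sample"))
    picks = [
        np.sort(rng.choice(
            idx, size=args.per_class, replace=idx.size < args.per_class))
        for idx in (np.flatnonzero(train_set.labels == c)
                    for c in DEFAULT_SCHEME.codes)
    ]
    train_set = train_set.subset(np.concatenate(picks))

    predictions = pd.DataFrame(index=table.index)
    predictions["label"] = table["label"]
    for kind in MODEL_KINDS:
        clf = train(kind, train_set,
                    seed=stage_seed(args.seed, "train", MODEL_KINDS.index(kind)))
        cm, metrics = evaluate(
            np.asarray(predict(clf, test_set.features).labels), test_set.labels
        )
        (out / f"metrics_{kind}.json").write_text(
            json.dumps(metrics.as_dict(), indent=2))
        cm.to_csv(out / f"confusion_{kind}.csv")
        predictions[f"class_{kind}"] = np.asarray(
            predict(clf, table[FEATURE_COLUMNS]).labels)
        print(f"{kind}: overall accuracy "
              f"{metrics.overall_accuracy:.3f} on {len(test_set.labels)} objects")
    predictions.to_csv(out / "predictions.csv")
    print(f"written to {out}")


if __name__ == "__main__":
    main()
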