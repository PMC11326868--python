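"""Train the E/I random forest on a labeled synthetic feature table (the
midline-stimulation analogue), evaluate it, and apply it to an unlabeled
auditory-nerve-like table, splitting any mixed clusters.

Writes results/classifier_report.json and results/an_predictions.tsv.
"""

import json
import pathlib

import numpy as np
import pandas as pd

from mocsyn import io
from mocsyn.classify import (
    evaluate_classifier,
    predict_ei,
    split_mixed_clusters,
    train_ei_classifier,
)
from mocsyn.synth import CLASS_FEATURE_PARAMS, generate_feature_table

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main():
    train = generate_feature_table(476, seed=21)          # ~952 rows total
    holdout = generate_feature_table(172, seed=22)        # ~344 rows, AN-like
    model = train_ei_classifier(train, n_trees=500, seed=3)
    acc, roc, auc = evaluate_classifier(model, holdout)
    stable_at = int(np.argmax(np.abs(np.diff(model.oob_error_by_ntrees)) < 0.005))

    # apply to an unlabeled AN-like table grouped into pseudo-clusters
    an = generate_feature_table(172, seed=23)
    truth = an.pop("label")
    pred = predict_ei(model, an)
    an_out = pd.concat([an, pred], axis=1)
    an_out["cluster"] = np.arange(len(an_out)) // 12
    an_out["true_label"] = truth
    split = split_mixed_clusters(an_out, label_col="label")
    io.save_table(OUT / "an_predictions.tsv", split)

    report = dict(
        oob_error=model.oob_error,
        resubstitution_accuracy=model.resubstitution_accuracy,
        holdout_accuracy=acc,
        auc=auc,
        oob_stable_after_trees=stable_at,
        importances=model.importances.to_dict(),
        n_mixed_clusters=int(
            (split.groupby("cluster")["label"].nunique() > 1).sum()
        ),
        mean_p_excitatory_for_E=float(
            pred.loc[truth == "excitatory", "p_excitatory"].mean()),
        mean_p_inhibitory_for_I=float(
            pred.loc[truth == "inhibitory", "p_inhibitory"].mean()),
    )
    with open(OUT / "classifier_report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    print(f"holdout accuracy {acc:.4f}, AUC {auc:.4f}, OOB error "
          f"{model.oob_error:.4f} (stable after ~{stable_at} trees)")
    print("feature importances:",
          {k: round(v, 3) for k, v in model.importances.items()})


if __name__ == "__main__":
    main()
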