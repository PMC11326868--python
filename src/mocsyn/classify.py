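"""Tree-ensemble classification of PSCs as excitatory or inhibitory.

A bootstrap-aggregated random forest is trained on labeled events (the
holding-potential-labeled midline dataset in the original workflow) and then
applied to events lacking holding-potential labels.  Seven features enter:
rise time, decay time constant, amplitude, within-cluster occurrence
probability, onset jitter, peak jitter, and animal age (categorical).

Class probabilities are reported as the fraction of trees voting excitatory;
a tie at exactly 0.5 classifies as inhibitory and is flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve

__all__ = [
    "FEATURE_COLUMNS",
    "EnsembleModel",
    "train_ei_classifier",
    "predict_ei",
    "evaluate_classifier",
    "split_mixed_clusters",
]

FEATURE_COLUMNS = (
    "rise_time", "decay_tau", "amplitude", "probability",
    "onset_jitter", "peak_jitter", "age",
)
CLASSES = ("excitatory", "inhibitory")


@dataclass
class EnsembleModel:
    """A fitted forest plus its OOB error curve and importances."""

    forest: RandomForestClassifier
    feature_columns: tuple
    age_categories: tuple
    oob_error_by_ntrees: np.ndarray    # cumulative majority-vote OOB error
    importances: pd.Series
    oob_error: float
    resubstitution_accuracy: float

    @property
    def n_trees(self) -> int:
        return len(self.forest.estimators_)


def _encode(df: pd.DataFrame, age_categories, warn_unseen: bool = True) -> np.ndarray:
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise KeyError(f"feature table lacks columns {missing}")
    x = df[list(FEATURE_COLUMNS)].copy()
    cats = np.asarray(age_categories, dtype=float)
    ages = pd.to_numeric(x["age"]).to_numpy(dtype=float)
    unseen = ~np.isin(ages, cats)
    if unseen.any():
        if warn_unseen:
            warnings.warn(
                f"{int(unseen.sum())} rows carry unseen age categories; "
                "mapped to the nearest trained category",
                stacklevel=2,
            )
        ages[unseen] = cats[np.argmin(np.abs(ages[unseen, None] - cats[None, :]), axis=1)]
    x["age"] = ages
    vals = x.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals[:, :-1])):
        raise ValueError("continuous features must be finite")
    return vals


def _unsampled_masks(forest: RandomForestClassifier, n: int) -> list[np.ndarray]:
    """Per-tree boolean masks of out-of-bag samples."""
    try:
        from sklearn.ensemble._forest import _generate_unsampled_indices

        ms = forest.max_samples
        if ms is None:
            nb = n
        elif isinstance(ms, float):
            nb = max(round(n * ms), 1)
        else:
            nb = int(ms)
        masks = []
        for tree in forest.estimators_:
            try:
                idx = _generate_unsampled_indices(tree.random_state, n, nb, None)
            except TypeError:
                idx = _generate_unsampled_indices(tree.random_state, n, nb)
            m = np.zeros(n, dtype=bool)
            m[idx] = True
            masks.append(m)
        return masks
    except ImportError:  # pragma: no cover - sklearn internals moved
        masks = []
        for tree in forest.estimators_:
            rs = np.random.RandomState(tree.random_state)
            sampled = rs.randint(0, n, n)
            m = np.ones(n, dtype=bool)
            m[sampled] = False
            masks.append(m)
        return masks


def train_ei_classifier(
    rows: pd.DataFrame,
    n_trees: int = 500,
    seed: int = 0,
    max_features: str | int = "sqrt",
) -> EnsembleModel:
    """Train the E/I random forest; deterministic under ``seed``.

    Returns the model with its cumulative out-of-bag error curve (one value
    per tree count), variable importances, and both the OOB error and the
    resubstitution accuracy (the two accuracy notions a forest can report on
    its own training set).
    """
    if "label" not in rows.columns:
        raise KeyError("training table needs a 'label' column")
    labels = rows["label"].to_numpy()
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2:
        raise ValueError("training data contains a single class")
    if counts.min() < 2:
        raise ValueError("need at least 2 rows per class")
    age_categories = tuple(sorted(pd.to_numeric(rows["age"]).unique()))
    x = _encode(rows, age_categories)
    y = (labels == "excitatory").astype(int)

    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        bootstrap=True,
        oob_score=True,
        random_state=seed,
    ).fit(x, y)

    # cumulative majority-vote OOB error per tree count
    n = len(y)
    masks = _unsampled_masks(forest, n)
    votes_e = np.zeros(n)
    votes_total = np.zeros(n)
    curve = np.empty(n_trees)
    for t, (tree, m) in enumerate(zip(forest.estimators_, masks)):
        if m.any():
            pred = tree.predict(x[m])
            votes_e[m] += (pred > 0.5).astype(float)
            votes_total[m] += 1.0
        seen = votes_total > 0
        if seen.any():
            maj = (votes_e[seen] / votes_total[seen]) > 0.5
            curve[t] = float(np.mean(maj != (y[seen] > 0)))
        else:
            curve[t] = np.nan

    importances = pd.Series(forest.feature_importances_, index=FEATURE_COLUMNS)
    resub = float(np.mean(forest.predict(x) == y))
    return EnsembleModel(
        forest=forest,
        feature_columns=FEATURE_COLUMNS,
        age_categories=age_categories,
        oob_error_by_ntrees=curve,
        importances=importances,
        oob_error=float(1.0 - forest.oob_score_),
        resubstitution_accuracy=resub,
    )


def predict_ei(model: EnsembleModel, rows: pd.DataFrame) -> pd.DataFrame:
    """Per-row excitatory probability and label.

    ``p_excitatory`` is the fraction of trees voting excitatory; the label
    is the class with probability > 0.5, with exact ties going to inhibitory
    and flagged in the ``tie`` column.
    """
    x = _encode(rows, model.age_categories)
    votes = np.zeros(len(x))
    for tree in model.forest.estimators_:
        votes += (tree.predict(x) > 0.5).astype(float)
    p_exc = votes / model.n_trees
    label = np.where(p_exc > 0.5, "excitatory", "inhibitory")
    return pd.DataFrame(
        {
            "p_excitatory": p_exc,
            "p_inhibitory": 1.0 - p_exc,
            "label": label,
            "tie": p_exc == 0.5,
        },
        index=rows.index,
    )


def evaluate_classifier(
    model: EnsembleModel, rows: pd.DataFrame
) -> tuple[float, pd.DataFrame, float]:
    """Accuracy (0.5 threshold), ROC curve, and trapezoid AUC on labeled rows."""
    if "label" not in rows.columns:
        raise KeyError("evaluation table needs a 'label' column")
    y = (rows["label"].to_numpy() == "excitatory").astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined on a single-class evaluation set")
    pred = predict_ei(model, rows)
    accuracy = float(np.mean(pred["label"].to_numpy() == rows["label"].to_numpy()))
    fpr, tpr, thresh = roc_curve(y, pred["p_excitatory"].to_numpy())
    auc = float(np.trapezoid(tpr, fpr))
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresh})
    return accuracy, roc, auc


def split_mixed_clusters(
    events: pd.DataFrame,
    cluster_col: str = "cluster",
    label_col: str = "label",
) -> pd.DataFrame:
    """Split clusters whose events carry both labels into one E and one I
    cluster each; returns a copy with a ``split_cluster`` column.

    Pure clusters keep their id as a string; mixed ones get "<id>E"/"<id>I".
    The cluster-level label elsewhere is the majority vote of member events.
    """
    out = events.copy()
    ids = out[cluster_col].astype(str)
    new = ids.copy()
    for cid in ids.unique():
        m = ids == cid
        labs = out.loc[m, label_col].unique()
        if len(labs) > 1:
            new[m] = ids[m] + np.where(
                out.loc[m, label_col] == "excitatory", "E", "I"
            )
    out["split_cluster"] = new
    return out
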