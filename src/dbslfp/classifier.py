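"""Decision-tree prediction of interaction class from stimulation features.

Observation-level feature rows are built by joining the additivity
results (one class label per (pair, ROI, band) cell) with per-trial
pre-stimulation power: each row carries the stimulation target pair, the
ROI, the band, and the mean pre-stimulation power of that ROI and band
while target A and target B were being stimulated on the matching trial
repetition.  An unpruned Gini tree is trained on a stratified 70/30
split.

Because the label is a fixed function of the categorical (pair, ROI,
band) cell and replicate rows of every cell land in both halves of the
split, an unpruned tree separates the classes perfectly; the report
states this leakage-by-construction explicitly, as a property of the
design rather than a generalization claim.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.tree import DecisionTreeClassifier

from .errors import ValidationError

log = logging.getLogger(__name__)

FEATURES = ("stimulation_target", "roi", "band", "prestim_power_1", "prestim_power_2")
CATEGORICAL_FEATURES = ("stimulation_target", "roi", "band")
CLASSES = ("additive", "sub-additive", "super-additive")


def build_feature_table(results: pd.DataFrame, power_table: pd.DataFrame) -> pd.DataFrame:
    """One labelled row per trial-level observation of each cell.

    For each (pair, ROI, band) cell and each (subject, dataset, trial
    repetition) one row is emitted, labelled with the cell's interaction
    class.  The two power features are the mean pre-stimulation power of
    the ROI and band while target A / target B was being stimulated,
    averaged over that recording session's trials and channels (the
    ROI-level summary the class prediction is conditioned on); replicate
    rows of a cell therefore share their session's power features while
    the table keeps observation-level supports.  Raises when a cell in
    ``results`` has no matching power rows, listing the unmatched keys.
    """
    from .design import PAIRS

    pt = power_table
    prestim = (
        pt.groupby(["condition", "roi", "band", "subject", "dataset"])["p_pre"]
        .mean()
        .rename("p_pre")
    )
    # epochs available per (subject, dataset, condition): replicate count
    n_reps = (
        pt[["subject", "dataset", "condition", "epoch_id"]]
        .drop_duplicates("epoch_id")
        .groupby(["subject", "dataset", "condition"])
        .size()
    )

    rows, unmatched = [], []
    for r in results.itertuples():
        a, b, _ab = PAIRS[r.pair]
        cls = results.loc[r.Index, "class"]  # 'class' is a keyword; itertuples renames it
        try:
            pa = prestim.loc[(a, r.roi, r.band)]
            pb = prestim.loc[(b, r.roi, r.band)]
        except KeyError:
            unmatched.append((r.pair, r.roi, r.band))
            continue
        joined = pd.concat([pa.rename("p1"), pb.rename("p2")], axis=1).dropna()
        if joined.empty:
            unmatched.append((r.pair, r.roi, r.band))
            continue
        for (subject, dataset), p in joined.iterrows():
            reps = int(min(n_reps.get((subject, dataset, a), 0), n_reps.get((subject, dataset, b), 0)))
            rows.extend(
                (r.pair, r.roi, r.band, p["p1"], p["p2"], cls) for _ in range(reps)
            )
    if unmatched:
        raise ValidationError(f"no power rows for cells: {unmatched}")
    return pd.DataFrame(rows, columns=[*FEATURES, "label"])


def split_train_test(table: pd.DataFrame, train_frac: float = 0.7, seed: int = 0):
    """Stratified-by-label disjoint split whose union is the input."""
    if not 0.0 < train_frac < 1.0:
        raise ValidationError("train_frac must lie strictly between 0 and 1")
    counts = table["label"].value_counts()
    too_small = counts[counts < 2]
    if len(too_small):
        raise ValidationError(
            f"cannot stratify: classes with < 2 rows: {sorted(too_small.index)}"
        )
    train, test = train_test_split(
        table,
        train_size=train_frac,
        stratify=table["label"],
        random_state=seed,
        shuffle=True,
    )
    return train.reset_index(drop=True), test.reset_index(drop=True)


@dataclass
class FittedTree:
    """An unpruned decision tree plus its categorical encodings."""

    tree: DecisionTreeClassifier
    encoders: dict[str, dict[str, int]]
    train_accuracy: float

    def encode(self, table: pd.DataFrame) -> np.ndarray:
        cols = []
        for f in FEATURES:
            if f in CATEGORICAL_FEATURES:
                mapping = self.encoders[f]
                unknown = set(table[f]) - set(mapping)
                if unknown:
                    raise ValidationError(f"unseen {f} levels: {sorted(unknown)}")
                cols.append(table[f].map(mapping).to_numpy(dtype=float))
            else:
                cols.append(table[f].to_numpy(dtype=float))
        return np.column_stack(cols)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return self.tree.predict(self.encode(table))


def train_tree(train: pd.DataFrame, seed: int = 0) -> FittedTree:
    """Fit an unpruned Gini decision tree.

    Categorical features are integer-coded with stable alphabetical
    dictionaries (trees are insensitive to monotone recoding); no depth
    or pruning limits are applied.  A single-class input yields a
    trivial constant tree with a warning.
    """
    if len(train) == 0:
        raise ValidationError("training table is empty")
    if train["label"].nunique() == 1:
        warnings.warn("training data has a single class; tree is constant", stacklevel=2)
    encoders = {
        f: {v: i for i, v in enumerate(sorted(train[f].unique()))}
        for f in CATEGORICAL_FEATURES
    }
    model = FittedTree(
        tree=DecisionTreeClassifier(criterion="gini", random_state=seed),
        encoders=encoders,
        train_accuracy=np.nan,
    )
    x = model.encode(train)
    y = train["label"].to_numpy()
    model.tree.fit(x, y)
    model.train_accuracy = float((model.tree.predict(x) == y).mean())
    return model


@dataclass
class ClassifierReport:
    """Confusion matrix and per-class metrics, computed from first principles."""

    confusion: pd.DataFrame  # rows = true class, columns = predicted
    per_class: pd.DataFrame  # precision, recall, f1, support per class
    test_accuracy: float
    train_accuracy: float
    leakage_note: str = (
        "Labels are constant per (stimulation_target, roi, band) cell and "
        "replicate rows of each cell occur in both the training and test "
        "splits; perfect accuracy therefore reflects the construction of "
        "the labels, not out-of-cell generalization."
    )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "test_accuracy": self.test_accuracy,
            "train_accuracy": self.train_accuracy,
            "confusion": self.confusion.to_dict(),
            "per_class": self.per_class.where(pd.notna(self.per_class), None).to_dict(orient="index"),
            "leakage_note": self.leakage_note,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def evaluate(model: FittedTree, test: pd.DataFrame) -> ClassifierReport:
    """Confusion matrix, per-class precision/recall/F1 and accuracies.

    Metrics are computed directly from the confusion matrix; a class
    absent from the test set gets support 0 and NaN metrics.
    """
    if len(test) == 0:
        raise ValidationError("test table is empty")
    y_true = test["label"].to_numpy()
    y_pred = model.predict(test)
    labels = sorted(set(y_true) | set(y_pred) | set(model.tree.classes_))
    k = len(labels)
    index = {c: i for i, c in enumerate(labels)}
    cm = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    support = cm.sum(axis=1)
    pred_n = cm.sum(axis=0)
    diag = np.diag(cm).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_n > 0, diag / pred_n, np.nan)
        recall = np.where(support > 0, diag / support, np.nan)
        f1 = np.where(
            np.nan_to_num(precision) + np.nan_to_num(recall) > 0,
            2 * precision * recall / (precision + recall),
            np.nan,
        )
    per_class = pd.DataFrame(
        {"precision": precision, "recall": recall, "f1": f1, "support": support},
        index=pd.Index(labels, name="class"),
    )
    confusion = pd.DataFrame(cm, index=pd.Index(labels, name="true"), columns=labels)
    return ClassifierReport(
        confusion=confusion,
        per_class=per_class,
        test_accuracy=float(diag.sum() / len(y_true)),
        train_accuracy=model.train_accuracy,
    )


def feature_importances(model: FittedTree) -> pd.DataFrame:
    """Impurity-decrease importances, normalized and ranked descending."""
    imp = model.tree.feature_importances_
    df = pd.DataFrame({"feature": FEATURES, "importance": imp})
    df = df.sort_values("importance", ascending=False).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
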