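"""Decision-tree BPSD classifiers: training, evaluation, serialization.

Four variants share one training recipe: a CART tree grown on Gini
impurity with the split count capped at 20 (equivalently at most 21
leaves), the published configuration.  Variants differ only in their
feature set: PsyCo (8 caregiver-observable factors), PsyCo+HRV, BePhyEn
(6 sensor-observable manifestations), and BePhyEn without HRV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.tree import DecisionTreeClassifier

from .datagen import Dataset, default_composition, generate_dataset, variant_table
from .regularities import BPSD_LABELS

__all__ = [
    "TreeParams",
    "TreeModel",
    "EvalReport",
    "train_tree",
    "predict",
    "evaluate",
    "sample_size_study",
]


@dataclass(frozen=True)
class TreeParams:
    """Training configuration; the defaults are the published ones."""

    split_criterion: str = "gini"
    max_splits: int = 20


@dataclass
class EvalReport:
    """Accuracy, 4x4 confusion matrix, macro one-vs-rest AUC, per-class P/R."""

    accuracy: float
    confusion: np.ndarray  # rows = true label 0..3, cols = predicted
    macro_auc: float
    precision: dict[int, float]
    recall: dict[int, float]
    n: int


class TreeModel:
    """A fitted BPSD decision tree plus its provenance.

    Thin wrapper over an sklearn ``DecisionTreeClassifier`` that fixes the
    feature order, exposes tree structure for inspection, and serializes to
    a plain-JSON node list (the JSON form is traversed by pure-Python code,
    so a round-trip reproduces predictions exactly).
    """

    def __init__(
        self,
        clf: DecisionTreeClassifier,
        feature_names: Sequence[str],
        params: TreeParams,
        seed: int | None = None,
        n_train: int | None = None,
    ) -> None:
        self.clf = clf
        self.feature_names = tuple(feature_names)
        self.params = params
        self.seed = seed
        self.n_train = n_train

    # -- structure introspection -------------------------------------------------
    @property
    def n_internal_nodes(self) -> int:
        t = self.clf.tree_
        return int(np.sum(t.children_left != -1))

    @property
    def root_feature(self) -> str:
        """Name of the feature tested at the root split."""
        idx = self.clf.tree_.feature[0]
        if idx < 0:
            raise ValueError("degenerate single-leaf tree has no root split")
        return self.feature_names[idx]

    @property
    def root_threshold(self) -> float:
        if self.clf.tree_.feature[0] < 0:
            raise ValueError("degenerate single-leaf tree has no root split")
        return float(self.clf.tree_.threshold[0])

    def _vectorize(self, values: Mapping[str, int]) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in values]
        if missing:
            raise KeyError(f"sample is missing feature(s) {missing}")
        return np.array([[values[f] for f in self.feature_names]], dtype=float)

    def predict_one(self, values: Mapping[str, int]) -> int:
        """Label for a single factor->level mapping; ties at a leaf go to the
        smallest label code."""
        proba = self.clf.predict_proba(self._vectorize(values))[0]
        classes = self.clf.classes_
        return int(classes[int(np.argmax(proba))])

    def predict_dataset(self, dataset: Dataset) -> np.ndarray:
        X = np.array(
            [s.feature_vector(self.feature_names) for s in dataset.samples], dtype=float
        )
        return self.clf.predict(X).astype(int)

    def predict_proba_full(self, X: np.ndarray) -> np.ndarray:
        """Leaf class frequencies expanded to all four labels (absent
        training classes get probability zero)."""
        proba = self.clf.predict_proba(X)
        full = np.zeros((len(X), len(BPSD_LABELS)))
        for j, c in enumerate(self.clf.classes_):
            full[:, int(c)] = proba[:, j]
        return full

    # -- serialization -----------------------------------------------------------
    def to_json_dict(self) -> dict:
        t = self.clf.tree_
        nodes = []
        for i in range(t.node_count):
            nodes.append(
                {
                    "left": int(t.children_left[i]),
                    "right": int(t.children_right[i]),
                    "feature": int(t.feature[i]),
                    "threshold": float(t.threshold[i]),
                    "counts": [float(c) for c in t.value[i][0]],
                }
            )
        return {
            "feature_names": list(self.feature_names),
            "classes": [int(c) for c in self.clf.classes_],
            "params": {"split_criterion": self.params.split_criterion,
                       "max_splits": self.params.max_splits},
            "seed": self.seed,
            "n_train": self.n_train,
            "nodes": nodes,
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)

    def render_text(self) -> str:
        """Indented text rendering of the tree for visual inspection."""
        d = self.to_json_dict()
        lines: list[str] = []

        def walk(i: int, depth: int) -> None:
            node = d["nodes"][i]
            pad = "  " * depth
            if node["left"] == -1:
                counts = node["counts"]
                label = d["classes"][int(np.argmax(counts))]
                lines.append(f"{pad}-> label {label} {counts}")
                return
            name = d["feature_names"][node["feature"]]
            lines.append(f"{pad}{name} <= {node['threshold']:.2f}?")
            walk(node["left"], depth + 1)
            lines.append(f"{pad}else ({name} > {node['threshold']:.2f}):")
            walk(node["right"], depth + 1)

        walk(0, 0)
        return "\n".join(lines)


@dataclass
class JSONTreeModel:
    """Pure-Python reload of a serialized tree; prediction only."""

    feature_names: tuple[str, ...]
    classes: tuple[int, ...]
    nodes: list[dict]
    params: TreeParams = field(default_factory=TreeParams)

    @classmethod
    def load_json(cls, path) -> "JSONTreeModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            feature_names=tuple(d["feature_names"]),
            classes=tuple(d["classes"]),
            nodes=d["nodes"],
            params=TreeParams(**d["params"]),
        )

    def predict_one(self, values: Mapping[str, int]) -> int:
        missing = [f for f in self.feature_names if f not in values]
        if missing:
            raise KeyError(f"sample is missing feature(s) {missing}")
        i = 0
        while self.nodes[i]["left"] != -1:
            node = self.nodes[i]
            x = values[self.feature_names[node["feature"]]]
            i = node["left"] if x <= node["threshold"] else node["right"]
        counts = self.nodes[i]["counts"]
        return int(self.classes[int(np.argmax(counts))])


def train_tree(
    dataset: Dataset,
    params: TreeParams | None = None,
    seed: int = 0,
) -> TreeModel:
    """Fit a Gini CART tree with at most ``params.max_splits`` internal nodes.

    A binary tree with k internal nodes has k+1 leaves, so the split cap is
    enforced through ``max_leaf_nodes = max_splits + 1`` (best-first
    impurity-greedy growth).  A single-class dataset yields a degenerate
    single-leaf model.
    """
    params = params or TreeParams()
    if len(dataset) == 0:
        raise ValueError("cannot train on an empty dataset")
    X, y = dataset.X_y()
    clf = DecisionTreeClassifier(
        criterion=params.split_criterion,
        max_leaf_nodes=params.max_splits + 1,
        random_state=seed,
    )
    clf.fit(X.astype(float), y)
    return TreeModel(clf, dataset.feature_names, params, seed=seed, n_train=len(dataset))


def predict(model: TreeModel, values: Mapping[str, int]) -> int:
    """Label one sample (factor name -> level mapping)."""
    return model.predict_one(values)


def evaluate(model: TreeModel, dataset: Dataset) -> EvalReport:
    """Accuracy, confusion matrix, and macro one-vs-rest AUC on a dataset.

    AUC scores are the leaf class frequencies; classes absent from the
    evaluation set are skipped in the macro average.
    """
    X, y = dataset.X_y()
    y_pred = model.predict_dataset(dataset)
    cm = confusion_matrix(y, y_pred, labels=list(BPSD_LABELS))
    acc = float(np.trace(cm)) / len(y)
    proba = model.predict_proba_full(X.astype(float))
    present = [c for c in BPSD_LABELS if np.any(y == c)]
    aucs = []
    for c in present:
        if len(present) < 2:
            break
        aucs.append(roc_auc_score((y == c).astype(int), proba[:, c]))
    macro_auc = float(np.mean(aucs)) if aucs else float("nan")
    precision, recall = {}, {}
    for c in BPSD_LABELS:
        pred_c = int(cm[:, c].sum())
        true_c = int(cm[c, :].sum())
        precision[c] = cm[c, c] / pred_c if pred_c else float("nan")
        recall[c] = cm[c, c] / true_c if true_c else float("nan")
    return EvalReport(
        accuracy=acc, confusion=cm, macro_auc=macro_auc,
        precision=precision, recall=recall, n=len(y),
    )


def train_eval_variant(
    kind: str, seed: int, params: TreeParams | None = None, n: int = 120
) -> tuple[TreeModel, EvalReport]:
    """Convenience: generate train/test sets of size ``n`` for a variant,
    train, and evaluate on the independent test set.

    Train and test sets share the composition but use distinct streams
    derived from ``seed``.
    """
    table = variant_table(kind)
    comp = default_composition(n)
    train = generate_dataset(table, comp, seed=2 * seed)
    test = generate_dataset(table, comp, seed=2 * seed + 1)
    model = train_tree(train, params, seed=seed)
    return model, evaluate(model, test)


def sample_size_study(
    kind: str = "bephyen",
    sizes: Sequence[int] = (60, 120, 240, 480),
    seeds: Sequence[int] = tuple(range(10)),
    params: TreeParams | None = None,
):
    """Training-set accuracy and macro AUC as the training set grows.

    Both metrics are 5-fold stratified cross-validation estimates on the
    training set — the figure the original modeling application displays as
    a model's training accuracy.  (Plain resubstitution on a 21-leaf tree
    nearly memorizes these small datasets and *decreases* with n, so it
    cannot be the reported quantity; the cross-validated estimate grows
    with n as leaf statistics stabilize.)

    For each size the default composition is scaled proportionally; for
    each seed a fresh training set is generated.  Returns a DataFrame with
    one row per size: (n, cv_accuracy, cv_auc) means over seeds.
    """
    import pandas as pd
    from sklearn.model_selection import StratifiedKFold, cross_val_predict

    params = params or TreeParams()
    table = variant_table(kind)
    rows = []
    for n in sizes:
        comp = default_composition(n)
        accs, aucs = [], []
        for seed in seeds:
            train = generate_dataset(table, comp, seed=100_000 + 7919 * seed + n)
            X, y = train.X_y()
            clf = DecisionTreeClassifier(
                criterion=params.split_criterion,
                max_leaf_nodes=params.max_splits + 1,
                random_state=seed,
            )
            cv = StratifiedKFold(5, shuffle=True, random_state=seed)
            proba = cross_val_predict(
                clf, X.astype(float), y, cv=cv, method="predict_proba"
            )
            pred = proba.argmax(axis=1)
            accs.append(float(np.mean(pred == y)))
            aucs.append(
                float(roc_auc_score(y, proba, multi_class="ovr", average="macro"))
            )
        rows.append(
            {"n": n, "cv_accuracy": float(np.mean(accs)), "cv_auc": float(np.mean(aucs))}
        )
    return pd.DataFrame(rows)
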