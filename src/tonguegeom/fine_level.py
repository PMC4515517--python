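"""Fine-level two-class discrimination within one tongue shape.

Two patient classes that fall into the same coarse shape are separated
using a subset of the 13 geometry features, chosen by sequential forward
selection (SFS).  The criterion J maximized at each step is the average
accuracy of a linear maximum-margin classifier (SVM, dot-product kernel)
on a fixed stratified half split: half of each class trains the
classifier, the other half is held out.

"Average accuracy" is the macro average of per-class recall.  The class
pairs this protocol targets are strongly imbalanced, where plain
accuracy is dominated by the majority class; plain accuracy remains
available through :class:`ClassifierConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.svm import SVC

from .geometry import FEATURE_NAMES


@dataclass
class LabeledFeatureTable:
    """Feature rows with class labels (and optionally source masks).

    ``features`` is an (n_samples, n_features) float array whose columns
    follow FEATURE_NAMES order; ``labels`` holds one class label per row.
    """

    ids: List[str]
    features: np.ndarray
    labels: np.ndarray
    masks: Optional[list] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        n = len(self.ids)
        if self.features.ndim != 2 or self.features.shape[0] != n:
            raise ValueError("features must be a 2-D array with one row per id")
        if self.labels.shape != (n,):
            raise ValueError("labels must have one entry per id")

    @property
    def classes(self) -> Tuple:
        return tuple(sorted(np.unique(self.labels).tolist()))

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


@dataclass(frozen=True)
class ClassifierConfig:
    """Margin-classifier settings: regularization C and accuracy flavor.

    ``average`` is "macro" (per-class recall averaged; the default) or
    "plain" (overall fraction correct).
    """

    C: float = 1.0
    average: str = "macro"

    def __post_init__(self) -> None:
        if self.average not in ("macro", "plain"):
            raise ValueError(f"unknown average mode {self.average!r}")
        if not self.C > 0:
            raise ValueError("C must be positive")


@dataclass(frozen=True)
class SFSResult:
    """Outcome of a sequential-forward-selection run.

    ``order`` lists all candidate features (1-based indices) in addition
    order; ``criterion_path[k]`` is J after the (k+1)-th addition;
    ``best_subset`` is the shortest prefix of ``order`` attaining
    ``best_J = max(criterion_path)``.
    """

    order: Tuple[int, ...]
    criterion_path: Tuple[float, ...]
    best_subset: Tuple[int, ...]
    best_J: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "order": list(self.order),
            "criterion_path": list(self.criterion_path),
            "best_subset": list(self.best_subset),
            "best_J": self.best_J,
            "seed": self.seed,
        }


def stratified_half_split(
    table: LabeledFeatureTable, seed: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Random half split preserving class proportions.

    Per class, floor(n/2) samples go to training and the rest to test,
    drawn uniformly at random under ``seed``.  Returns sorted row-index
    arrays (train, test); they are disjoint and cover the table.
    """
    rng = np.random.default_rng(seed)
    train: List[int] = []
    test: List[int] = []
    for cls in table.classes:
        idx = np.flatnonzero(table.labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        perm = rng.permutation(idx)
        k = idx.size // 2
        train.extend(perm[:k].tolist())
        test.extend(perm[k:].tolist())
    return np.sort(np.array(train)), np.sort(np.array(test))


def average_accuracy(
    truth: Sequence, pred: Sequence, average: str = "macro"
) -> float:
    """Macro-averaged per-class recall (or plain accuracy).

    Macro mode averages, over the classes present in ``truth``, the
    fraction of that class predicted correctly; a balanced measure under
    class imbalance.
    """
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.size == 0:
        raise ValueError("empty input")
    if truth.shape != pred.shape:
        raise ValueError("truth and pred must have equal length")
    if average == "plain":
        return float(np.mean(truth == pred))
    recalls = []
    for cls in np.unique(truth):
        in_cls = truth == cls
        recalls.append(float(np.mean(pred[in_cls] == cls)))
    return float(np.mean(recalls))


def evaluate_subset(
    table: LabeledFeatureTable,
    subset: Sequence[int],
    split: Tuple[np.ndarray, np.ndarray],
    config: ClassifierConfig = ClassifierConfig(),
) -> float:
    """Train/test criterion value J for one feature subset.

    Selected features (1-based indices into FEATURE_NAMES order) are
    standardized by the training fold's mean and standard deviation
    (a zero train-fold deviation falls back to 1, leaving the centered
    feature at zero rather than failing), a linear-kernel SVM is fit on
    the training half, and the average accuracy on the test half is
    returned.
    """
    if len(subset) == 0:
        raise ValueError("feature subset is empty")
    cols = np.array([i - 1 for i in subset])
    if cols.min() < 0 or cols.max() >= table.n_features:
        raise ValueError(f"feature indices out of range: {list(subset)}")
    train_idx, test_idx = split
    x_train = table.features[np.ix_(train_idx, cols)]
    x_test = table.features[np.ix_(test_idx, cols)]
    mu = x_train.mean(axis=0)
    sd = x_train.std(axis=0)
    sd[sd == 0] = 1.0
    clf = SVC(kernel="linear", C=config.C)
    clf.fit((x_train - mu) / sd, table.labels[train_idx])
    pred = clf.predict((x_test - mu) / sd)
    return average_accuracy(table.labels[test_idx], pred, config.average)


def sfs(
    table: LabeledFeatureTable,
    seed: int,
    config: ClassifierConfig = ClassifierConfig(),
) -> SFSResult:
    """Sequential forward selection over all features of the table.

    Starting from the empty set, each step adds the candidate feature
    whose inclusion maximizes J on one fixed stratified half split
    (ties broken toward the lowest feature index) and stops when every
    feature has been added.  The full addition path is reported together
    with the best prefix (earliest on ties).
    """
    if len(table.classes) != 2:
        raise ValueError(
            f"fine-level runs are pairwise; got classes {table.classes}"
        )
    split = stratified_half_split(table, seed)
    remaining = list(range(1, table.n_features + 1))
    order: List[int] = []
    path: List[float] = []
    while remaining:
        best_j = -np.inf
        best_feat = None
        for feat in remaining:  # ascending order => lowest index wins ties
            j = evaluate_subset(table, order + [feat], split, config)
            if j > best_j:
                best_j = j
                best_feat = feat
        order.append(best_feat)
        remaining.remove(best_feat)
        path.append(best_j)
    best_k = int(np.argmax(path))  # first occurrence of the maximum
    return SFSResult(
        order=tuple(order),
        criterion_path=tuple(path),
        best_subset=tuple(order[: best_k + 1]),
        best_J=float(path[best_k]),
        seed=seed,
    )
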