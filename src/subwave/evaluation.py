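"""Cross-validation, detection metrics, learning curves and smoothing.

Evaluation follows the study protocol: grouped fivefold cross-validation
(replicate measurements taken without repositioning the helmet share a group
and are never split between training and held-out folds), confusion matrices
with total/per-class accuracy and binary bleeding-detection sensitivity
(TPR) / specificity (TNR), learning curves over random class-balanced
subsets, and a binary validation protocol where six subspaces fitted on the
training data classify an unseen dataset into bleeding / no-bleeding.  The
Whittaker-Eilers penalized least-squares smoother used for presenting raw
magnitude traces is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .classifier import NearestSubspaceModel

__all__ = [
    "ConfusionMatrix",
    "FoldAssignment",
    "grouped_kfold",
    "cross_validate",
    "confusion_metrics",
    "learning_curve",
    "binary_validation",
    "whittaker_smooth",
]


@dataclass
class ConfusionMatrix:
    """C x C counts; rows = actual class, columns = predicted class."""

    counts: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        c = len(self.class_names)
        if self.counts.shape != (c, c):
            raise ValueError("counts must be C x C matching class_names")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_names, columns=self.class_names)


@dataclass
class FoldAssignment:
    """Fold id (1..k) per observation; groups never split across folds."""

    fold: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.fold = np.asarray(self.fold, dtype=int)
        if len(self.fold) and not (1 <= self.fold.min() and self.fold.max() <= self.k):
            raise ValueError("fold ids must lie in 1..k")

    def test_indices(self, fold_id: int) -> np.ndarray:
        return np.where(self.fold == fold_id)[0]

    def train_indices(self, fold_id: int) -> np.ndarray:
        return np.where(self.fold != fold_id)[0]


def grouped_kfold(labels, group_ids, k: int, seed: int = 0) -> FoldAssignment:
    """Randomized class-stratified fold assignment honoring replicate groups.

    Groups (each single-labeled) are shuffled within each class and dealt
    greedily to the currently smallest fold, so fold sizes are balanced to
    within group granularity and every fold sees every class when there are
    at least k groups per class.
    """
    labels = np.asarray(labels)
    group_ids = np.asarray(group_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(labels) != len(group_ids):
        raise ValueError("labels and group_ids must have equal length")
    uniq_groups = np.unique(group_ids)
    if len(uniq_groups) < k:
        raise ValueError(f"fewer groups ({len(uniq_groups)}) than folds ({k})")

    group_label: dict = {}
    group_size: dict = {}
    for g in uniq_groups:
        mask = group_ids == g
        labs = np.unique(labels[mask])
        if len(labs) != 1:
            raise ValueError(f"group {g!r} spans multiple classes {labs!r}")
        group_label[g] = labs[0]
        group_size[g] = int(mask.sum())

    rng = np.random.default_rng(seed)
    fold_of_group: dict = {}
    fold_sizes = np.zeros(k, dtype=int)
    for lab in np.unique(labels):
        groups_c = [g for g in uniq_groups if group_label[g] == lab]
        order = rng.permutation(len(groups_c))
        for g in (groups_c[i] for i in order):
            # smallest fold first; random tie-break
            candidates = np.where(fold_sizes == fold_sizes.min())[0]
            f = int(rng.choice(candidates))
            fold_of_group[g] = f + 1
            fold_sizes[f] += group_size[g]

    fold = np.array([fold_of_group[g] for g in group_ids], dtype=int)
    return FoldAssignment(fold=fold, k=k)


def cross_validate(
    dataset,
    k: int = 5,
    seed: int = 0,
    return_distances: bool = False,
    **fit_kwargs,
):
    """Grouped k-fold cross-validation of the nearest-subspace classifier.

    Returns a :class:`ConfusionMatrix`; with ``return_distances=True`` also a
    (N, C) array of held-out subspace distances (each observation's distances
    computed by the model that did not train on it).
    """
    folds = grouped_kfold(dataset.y, dataset.groups, k, seed=seed)
    C = dataset.n_classes
    counts = np.zeros((C, C), dtype=int)
    dists = np.full((len(dataset), C), np.nan)
    for f in range(1, k + 1):
        tr, te = folds.train_indices(f), folds.test_indices(f)
        y_tr = dataset.y[tr]
        if len(np.unique(y_tr)) != len(np.unique(dataset.y)):
            raise ValueError(f"fold {f}: a class is absent from the training split")
        res = NearestSubspaceModel(
            dataset.X[tr], y_tr, class_names=dataset.class_names
        ).fit(**fit_kwargs)
        d = res.distances(dataset.X[te])
        pred = np.asarray(res.classes_)[np.argmin(d, axis=1)]
        dists[te] = d
        for a, p in zip(dataset.y[te], pred):
            counts[a, p] += 1
    cm = ConfusionMatrix(counts, list(dataset.class_names))
    if return_distances:
        return cm, dists
    return cm


def confusion_metrics(cm: ConfusionMatrix, positive_class_set=None) -> dict:
    """Total/per-class accuracy plus binary detection TPR/TNR.

    ``positive_class_set``: indices of the "bleeding" classes (default: all
    classes except index 0).  Metrics are returned both as counts and as
    percentages (no rounding; round only for presentation).
    """
    counts = cm.counts
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    row = counts.sum(axis=1)
    if np.any(row == 0):
        raise ValueError("zero row sum: per-class accuracy undefined")
    C = len(counts)
    if positive_class_set is None:
        positive_class_set = list(range(1, C))
    pos = np.zeros(C, dtype=bool)
    pos[list(positive_class_set)] = True
    neg = ~pos

    diag = np.diag(counts)
    per_class = diag / row
    tp = counts[np.ix_(pos, pos)].sum()
    fn = counts[np.ix_(pos, neg)].sum()
    tn = counts[np.ix_(neg, neg)].sum()
    fp = counts[np.ix_(neg, pos)].sum()
    binary_correct = tp + tn
    return {
        "total": int(total),
        "correct": int(diag.sum()),
        "total_accuracy": float(diag.sum() / total),
        "total_accuracy_pct": float(100.0 * diag.sum() / total),
        "per_class_accuracy": per_class,
        "per_class_accuracy_pct": 100.0 * per_class,
        "tpr": float(tp / (tp + fn)) if (tp + fn) else float("nan"),
        "tpr_pct": float(100.0 * tp / (tp + fn)) if (tp + fn) else float("nan"),
        "tnr": float(tn / (tn + fp)) if (tn + fp) else float("nan"),
        "tnr_pct": float(100.0 * tn / (tn + fp)) if (tn + fp) else float("nan"),
        "binary_accuracy": float(binary_correct / total),
        "binary_accuracy_pct": float(100.0 * binary_correct / total),
        "counts": {"tp": int(tp), "fn": int(fn), "tn": int(tn), "fp": int(fp)},
    }


def learning_curve(
    dataset,
    sizes,
    k: int = 5,
    seed: int = 0,
    repeats: int = 5,
    **fit_kwargs,
) -> pd.DataFrame:
    """Cross-validated metrics on random class-balanced subsets of growing size.

    For each requested per-class size and each repeat, a class-balanced random
    subset (whole replicate groups) is drawn and evaluated with grouped k-fold
    CV.  Returns a tidy DataFrame with one row per (size, repeat).
    """
    counts = dataset.class_counts()
    for s in sizes:
        if s > counts.min():
            raise ValueError(f"size {s} exceeds smallest class count {counts.min()}")
    rows = []
    for rep in range(repeats):
        rng = np.random.default_rng(seed + 1000 * rep)
        for size in sizes:
            idx_parts = []
            for c in range(dataset.n_classes):
                cls_idx = np.where(dataset.y == c)[0]
                # sample whole groups until the target size is reached
                groups_c = np.unique(dataset.groups[cls_idx])
                order = rng.permutation(groups_c)
                chosen, count = [], 0
                for g in order:
                    gi = cls_idx[dataset.groups[cls_idx] == g]
                    chosen.append(gi)
                    count += len(gi)
                    if count >= size:
                        break
                idx_parts.append(np.concatenate(chosen)[:size])
            sub = dataset.subset(np.concatenate(idx_parts))
            cm = cross_validate(sub, k=k, seed=seed + 1000 * rep, **fit_kwargs)
            met = confusion_metrics(cm)
            rows.append(
                {
                    "size_per_class": size,
                    "repeat": rep,
                    "total_accuracy_pct": met["total_accuracy_pct"],
                    "tpr_pct": met["tpr_pct"],
                    "tnr_pct": met["tnr_pct"],
                }
            )
    return pd.DataFrame(rows)


def binary_validation(
    train, validation, no_bleeding_class: int = 0, return_distances: bool = False,
    **fit_kwargs,
):
    """Binary (bleeding vs no-bleeding) protocol on an unseen dataset.

    All training subspaces (one per class) are fitted on the *full* training
    data; a validation observation is "no bleeding" iff its smallest distance
    is to the no-bleeding subspace, else "bleeding".  The validation labels
    are binarized the same way.  Returns a 2x2 confusion matrix (rows/cols:
    no bleeding, bleeding); optionally also the per-observation distance to
    the training no-bleeding subspace.
    """
    if no_bleeding_class not in np.unique(train.y):
        raise ValueError("training data lacks the no-bleeding class")
    res = NearestSubspaceModel.from_dataset(train).fit(**fit_kwargs)
    d = res.distances(validation.X)
    pred_class = np.asarray(res.classes_)[np.argmin(d, axis=1)]
    pred_bleeding = (pred_class != no_bleeding_class).astype(int)
    actual_bleeding = (validation.y != 0).astype(int)
    counts = np.zeros((2, 2), dtype=int)
    for a, p in zip(actual_bleeding, pred_bleeding):
        counts[a, p] += 1
    cm = ConfusionMatrix(counts, ["no_bleeding", "bleeding"])
    if return_distances:
        nb_col = list(res.classes_).index(no_bleeding_class)
        return cm, d[:, nb_col]
    return cm


def whittaker_smooth(y, d: int = 2, lam: float = 10.0) -> np.ndarray:
    """Whittaker-Eilers smoother: argmin_z ||y - z||^2 + lam ||Delta^d z||^2.

    Solved by one sparse banded system (I + lam D^T D) z = y.  ``d`` is the
    difference order and ``lam`` the roughness penalty; ``lam = 0`` returns
    the input unchanged.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("y must be one-dimensional")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in input series")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    m = len(y)
    if m <= d:
        raise ValueError(f"series length {m} must exceed difference order {d}")
    if lam == 0:
        return y.copy()
    E = sp.identity(m, format="csc")
    D = _sparse_diff(m, d)
    A = E + lam * (D.T @ D)
    return spla.spsolve(A.tocsc(), y)


def _sparse_diff(m: int, d: int) -> sp.csc_matrix:
    D = sp.identity(m, format="csc")
    for _ in range(d):
        n = D.shape[0]
        S = sp.diags([-1.0, 1.0], [0, 1], shape=(n - 1, n), format="csc")
        D = S @ D
    return D.tocsc()
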