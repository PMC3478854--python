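"""Stratified splitting, K-fold cross validation, and confusion matrices.

The confusion matrix follows the column-target convention: entry (i, j)
counts test samples of target class j predicted as class i, so column
sums are the per-class test counts and the diagonal holds the correct
classifications.  Per-class success rates are diagonal over column sum;
overall accuracy is trace over total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from fruitvision import mcsvm, reduction


@dataclass
class CVFoldPlan:
    """A stratified K-fold assignment: fold id (0..K-1) per sample."""

    K: int
    fold_ids: np.ndarray
    seed: int


def stratified_split(
    labels: np.ndarray, train_fraction: float = 0.8, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test split at a fixed global train size.

    Per class, floor(train_fraction * n_c) samples go to the training
    set; the global train size is then topped up to
    floor(train_fraction * N) by promoting one test sample from each of
    the classes with the largest fractional remainders (ties broken by
    class order).  Deterministic given the seed.
    """
    labels = np.asarray(labels)
    n = len(labels)
    rng = np.random.default_rng(seed)
    classes = np.unique(labels)
    take = {}
    remainders = []
    for c in classes:
        n_c = int((labels == c).sum())
        if n_c < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        exact = train_fraction * n_c
        take[c] = int(np.floor(exact))
        remainders.append(exact - take[c])
    target = int(np.floor(train_fraction * n))
    short = target - sum(take.values())
    if short > 0:
        order = np.argsort(np.asarray(remainders) * -1, kind="stable")
        for idx in order[:short]:
            take[classes[idx]] += 1
    elif short < 0:  # train_fraction portions can only under-shoot, but be safe
        order = np.argsort(np.asarray(remainders), kind="stable")
        for idx in order[: -short]:
            take[classes[idx]] -= 1

    train_ids, test_ids = [], []
    for c in classes:
        ids = np.nonzero(labels == c)[0]
        ids = rng.permutation(ids)
        train_ids.append(ids[: take[c]])
        test_ids.append(ids[take[c] :])
    return np.sort(np.concatenate(train_ids)), np.sort(np.concatenate(test_ids))


def stratified_kfold(labels: np.ndarray, K: int = 5, seed: int = 0) -> CVFoldPlan:
    """Stratified K-fold plan: per-class shuffle then round-robin folds.

    The starting fold rotates between classes by the running remainder so
    overall fold sizes also differ by at most one.
    """
    labels = np.asarray(labels)
    if K < 2:
        raise ValueError("K must be >= 2")
    rng = np.random.default_rng(seed)
    fold_ids = np.empty(len(labels), dtype=np.int64)
    offset = 0
    for c in np.unique(labels):
        ids = rng.permutation(np.nonzero(labels == c)[0])
        fold_ids[ids] = (offset + np.arange(len(ids))) % K
        offset = (offset + len(ids)) % K
    return CVFoldPlan(K=K, fold_ids=fold_ids, seed=seed)


@dataclass
class ConfusionMatrix:
    """C x C count table; rows = predicted class, columns = target class."""

    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    def per_class_rates(self, decimals: int | None = None) -> list[float | None]:
        """Per-class success rate (diagonal / column sum) in percent.

        Classes with no test samples report ``None``.  ``decimals``
        rounds the percentage (the customary report uses 1 or 2).
        """
        rates: list[float | None] = []
        col = self.counts.sum(axis=0)
        for j in range(self.counts.shape[0]):
            if col[j] == 0:
                rates.append(None)
                continue
            r = 100.0 * self.counts[j, j] / col[j]
            rates.append(round(float(r), decimals) if decimals is not None else float(r))
        return rates


def confusion_matrix(
    predicted: np.ndarray, target: np.ndarray, n_classes: int
) -> ConfusionMatrix:
    """Count table with predicted class on rows and target class on columns."""
    predicted = np.asarray(predicted, dtype=np.int64)
    target = np.asarray(target, dtype=np.int64)
    if predicted.shape != target.shape:
        raise ValueError("predicted and target must have equal length")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (predicted - 1, target - 1), 1)
    return ConfusionMatrix(counts=counts)


def class_accuracy(
    cm: ConfusionMatrix, decimals: int = 1
) -> tuple[list[float | None], float]:
    """Per-class percentage rates (rounded) and the overall accuracy."""
    return cm.per_class_rates(decimals), cm.overall_accuracy


@dataclass
class CVResult:
    fold_accuracies: list[float]
    mean_accuracy: float
    confusion: ConfusionMatrix            # pooled over held-out folds
    selected_k: list[int] = field(default_factory=list)


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    plan: CVFoldPlan,
    scheme: str = "MWV",
    kernel: mcsvm.KernelSpec | None = None,
    C_reg: float = 1.0,
    energy: float = 0.95,
    tol: float = 1e-3,
) -> CVResult:
    """Leakage-free K-fold CV of the reduce-then-classify pipeline.

    Normalization and PCA are refit on the K-1 training folds of every
    round and applied unchanged to the held-out fold; a fresh multiclass
    SVM bank is trained per round.  When ``kernel`` is None, a GRB kernel
    with the data-driven default scale of the reduced training features
    is used.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64).ravel()
    C = int(y.max())
    fold_accs: list[float] = []
    ks: list[int] = []
    pooled = np.zeros((C, C), dtype=np.int64)
    for f in range(plan.K):
        tr = plan.fold_ids != f
        te = plan.fold_ids == f
        if len(np.unique(y[tr])) < C:
            raise ValueError(f"fold {f}: a class is missing from the training folds")
        red = reduction.fit_reduction(X[tr], energy=energy)
        Z_tr = red.transform(X[tr])
        Z_te = red.transform(X[te])
        spec = kernel
        if spec is None:
            spec = mcsvm.KernelSpec("GRB", gamma=mcsvm.default_gamma(Z_tr))
        model = mcsvm.train_multiclass(Z_tr, y[tr], scheme, spec, C_reg, tol)
        pred = np.atleast_1d(mcsvm.predict(model, Z_te))
        fold_accs.append(float(np.mean(pred == y[te])))
        ks.append(red.k)
        cm = confusion_matrix(pred, y[te], C)
        pooled += cm.counts
    return CVResult(
        fold_accuracies=fold_accs,
        mean_accuracy=float(np.mean(fold_accs)),
        confusion=ConfusionMatrix(pooled),
        selected_k=ks,
    )
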