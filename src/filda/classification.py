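"""K-nearest-neighbour classification and confusion-matrix evaluation.

KNN in the low-dimensional discriminant space: a test sample takes the
majority label among its K nearest training samples (Euclidean metric).
Ties are resolved deterministically -- distance ties by sample id after a
stable sort, vote ties by the label of the single nearest neighbour -- so
predictions never depend on training-sample order.

K is either given or selected by leave-one-out cross-validation on the
training projections over odd values {1, 3, 5, 7, 9, 11}, preferring the
smallest K on ties.

An alternative decision rule is also provided: assign each sample to the
class in which its fuzzy membership is largest (:func:`max_membership_predict`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .fuzzy import membership_matrix
from .spectra import SpectraSet, ValidationError

__all__ = [
    "KNNModel",
    "ConfusionResult",
    "knn_fit",
    "knn_predict",
    "select_k",
    "max_membership_predict",
]

K_CANDIDATES = (1, 3, 5, 7, 9, 11)


@dataclass
class KNNModel:
    """Stored training projections, labels and ids plus the vote count K."""

    reference_points: np.ndarray
    reference_labels: np.ndarray
    reference_ids: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.reference_points = np.asarray(self.reference_points, dtype=float)
        self.reference_labels = np.asarray(self.reference_labels, dtype=int)
        self.reference_ids = np.asarray(self.reference_ids, dtype=str)
        m = self.reference_points.shape[0]
        if self.reference_labels.size != m or self.reference_ids.size != m:
            raise ValidationError("reference labels/ids length must match reference points")
        if not 1 <= self.k <= m:
            raise ValidationError(f"K must be in [1, {m}], got {self.k}")


@dataclass
class ConfusionResult:
    """c x c count matrix (rows true, columns predicted) with accuracy."""

    counts: np.ndarray
    accuracy: float
    per_class_errors: list[tuple[int, int, int]]

    @classmethod
    def from_labels(
        cls, true: np.ndarray, predicted: np.ndarray, n_classes: int | None = None
    ) -> "ConfusionResult":
        true = np.asarray(true, dtype=int)
        predicted = np.asarray(predicted, dtype=int)
        c = n_classes if n_classes is not None else int(max(true.max(), predicted.max())) + 1
        counts = np.zeros((c, c), dtype=int)
        np.add.at(counts, (true, predicted), 1)
        accuracy = float(np.trace(counts)) / float(counts.sum())
        errors = [
            (i, j, int(counts[i, j]))
            for i in range(c)
            for j in range(c)
            if i != j and counts[i, j] > 0
        ]
        return cls(counts=counts, accuracy=accuracy, per_class_errors=errors)


def knn_fit(train_projected: SpectraSet, k: int) -> KNNModel:
    """Store the training projections; KNN has no learning beyond storage."""
    n = train_projected.n_samples
    if not 1 <= k <= n:
        raise ValidationError(f"K must be in [1, {n}], got {k}")
    return KNNModel(
        reference_points=train_projected.absorbance.copy(),
        reference_labels=train_projected.labels.copy(),
        reference_ids=np.asarray(train_projected.sample_ids, dtype=str),
        k=k,
    )


def _vote(order: np.ndarray, labels: np.ndarray, k: int) -> int:
    """Majority vote among the first k of ``order``; vote ties fall back to
    the label of the single nearest neighbour."""
    klabels = labels[order[:k]]
    counts = np.bincount(klabels)
    winners = np.flatnonzero(counts == counts.max())
    if winners.size == 1:
        return int(winners[0])
    return int(labels[order[0]])


def _neighbour_order(dist_row: np.ndarray, ids: np.ndarray) -> np.ndarray:
    # stable sort by (distance, sample id): permutation-invariant tie-break
    return np.lexsort((ids, dist_row))


def knn_predict(
    model: KNNModel, test_projected: SpectraSet, n_classes: int | None = None
) -> tuple[np.ndarray, ConfusionResult]:
    """Predict labels for the test projections and tabulate the confusion.

    Returns ``(predicted_labels, ConfusionResult)``; the confusion is
    computed against the labels carried by ``test_projected``.
    """
    if test_projected.n_samples == 0:
        raise ValidationError("empty test set")
    if test_projected.n_features != model.reference_points.shape[1]:
        raise ValidationError(
            f"test projections have {test_projected.n_features} features but the "
            f"model expects {model.reference_points.shape[1]}"
        )
    d = cdist(test_projected.absorbance, model.reference_points)
    predicted = np.empty(test_projected.n_samples, dtype=int)
    for i in range(d.shape[0]):
        order = _neighbour_order(d[i], model.reference_ids)
        predicted[i] = _vote(order, model.reference_labels, model.k)
    if n_classes is None:
        n_classes = int(max(test_projected.labels.max(), model.reference_labels.max())) + 1
    confusion = ConfusionResult.from_labels(test_projected.labels, predicted, n_classes)
    return predicted, confusion


def select_k(
    train_projected: SpectraSet, candidates: tuple[int, ...] = K_CANDIDATES
) -> tuple[int, dict[int, float]]:
    """Choose K by leave-one-out cross-validation on the training set.

    Each training sample is classified from the remaining ones; the K with
    the highest leave-one-out accuracy wins, the smallest K on ties.
    Returns ``(best_k, {k: loo_accuracy})``.
    """
    x = train_projected.absorbance
    labels = train_projected.labels
    ids = np.asarray(train_projected.sample_ids, dtype=str)
    n = x.shape[0]
    ks = sorted(k for k in candidates if 1 <= k <= n - 1)
    if not ks:
        raise ValidationError(f"no admissible K among {candidates} for n={n}")
    d = cdist(x, x)
    orders = []
    for i in range(n):
        row = d[i].copy()
        row[i] = np.inf  # exclude self
        orders.append(_neighbour_order(row, ids))
    accuracies: dict[int, float] = {}
    for k in ks:
        hits = sum(_vote(orders[i], labels, k) == labels[i] for i in range(n))
        accuracies[k] = hits / n
    best = max(ks, key=lambda k: (accuracies[k], -k))
    return best, accuracies


def max_membership_predict(
    test_projected: SpectraSet,
    centers: np.ndarray,
    eta: float,
    n_classes: int | None = None,
) -> tuple[np.ndarray, ConfusionResult]:
    """Assign each sample to the class with the largest fuzzy membership.

    ``centers`` are the trained class centers in the same space as the
    test projections (one row per class code, in sorted code order).
    """
    u = membership_matrix(test_projected.absorbance, centers, eta)
    predicted = np.argmax(u, axis=1)
    if n_classes is None:
        n_classes = max(int(test_projected.labels.max()) + 1, centers.shape[0])
    confusion = ConfusionResult.from_labels(test_projected.labels, predicted, n_classes)
    return predicted, confusion
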