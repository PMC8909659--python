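"""Crisp and fuzzy scatter matrices.

The raw material of Fisher-type discriminants: sums of outer products of
deviations of the score vectors from the grand mean (total scatter S_t),
of the class means from the grand mean (between-class S_b) and of samples
from their class means (within-class S_w).

The crisp between-class scatter here is the plain sum over class means,
NOT weighted by class size; ``class_weighted_sb=True`` switches to the
conventional n_j-weighted form (identical up to a constant factor for
balanced designs).

The fuzzy variants weight every (sample, class) pair by the membership
``u_ij`` raised to the fuzziness exponent eta, so samples that sit
ambiguously between classes contribute little to any class's statistics --
the mechanism behind the noise robustness of the fuzzy discriminant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fuzzy import FuzzyPartition
from .spectra import SpectraSet, ValidationError, class_means

__all__ = ["ScatterSet", "scatter_matrices", "fuzzy_scatter_matrices"]


@dataclass
class ScatterSet:
    """Total, between-class and within-class scatter (k x k each)."""

    s_t: np.ndarray
    s_b: np.ndarray
    s_w: np.ndarray
    fuzzy: bool = False


def _check_classes(labels: np.ndarray, allow_single_class: bool) -> np.ndarray:
    codes = np.unique(labels)
    expected = np.arange(labels.max() + 1) if labels.size else np.array([], dtype=int)
    missing = np.setdiff1d(expected, codes)
    if missing.size:
        raise ValidationError(f"class codes absent from the data: {missing.tolist()}")
    if codes.size < 2 and not allow_single_class:
        raise ValidationError("scatter matrices need at least 2 classes")
    return codes


def scatter_matrices(
    scores: SpectraSet,
    class_weighted_sb: bool = False,
    allow_single_class: bool = False,
) -> ScatterSet:
    """Crisp S_t, S_b, S_w from labelled score vectors.

    S_t = sum_i (d_i - dbar)(d_i - dbar)^T over all samples;
    S_b = sum_j (v_j - dbar)(v_j - dbar)^T over class means (optionally
    weighted by the class size n_j); S_w = sum_j sum_{d in class j}
    (d - v_j)(d - v_j)^T.
    """
    x = scores.absorbance
    labels = scores.labels
    codes = _check_classes(labels, allow_single_class)
    dbar = x.mean(axis=0)
    xc = x - dbar
    s_t = xc.T @ xc

    _, means = class_means(x, labels)
    k = x.shape[1]
    s_b = np.zeros((k, k))
    s_w = np.zeros((k, k))
    for j, c in enumerate(codes):
        vdev = means[j] - dbar
        w_j = np.count_nonzero(labels == c) if class_weighted_sb else 1.0
        s_b += w_j * np.outer(vdev, vdev)
        dev = x[labels == c] - means[j]
        s_w += dev.T @ dev
    return ScatterSet(s_t=s_t, s_b=s_b, s_w=s_w, fuzzy=False)


def fuzzy_scatter_matrices(scores: SpectraSet, part: FuzzyPartition) -> ScatterSet:
    """Membership-weighted S_ft, S_fb, S_fw.

    With weights w_ij = u_ij^eta:
    S_ft = sum_j sum_i w_ij (d_i - dbar)(d_i - dbar)^T,
    S_fb = sum_j sum_i w_ij (v_j - dbar)(v_j - dbar)^T,
    S_fw = sum_j sum_i w_ij (d_i - v_j)(d_i - v_j)^T,
    where dbar is the grand mean of the scores and v_j are the partition's
    centers.  Summation runs class-outer / sample-inner in a fixed order.
    """
    x = scores.absorbance
    n, k = x.shape
    if part.U.shape[0] != n:
        raise ValidationError(
            f"membership matrix has {part.U.shape[0]} rows but scores have {n} samples"
        )
    if part.centers.shape != (part.c, k):
        raise ValidationError(
            f"centers shape {part.centers.shape} does not match (c={part.c}, k={k})"
        )
    w = part.U**part.eta  # n x c
    dbar = x.mean(axis=0)
    xc = x - dbar
    s_t = np.zeros((k, k))
    s_b = np.zeros((k, k))
    s_w = np.zeros((k, k))
    for j in range(part.c):  # class-outer, fixed order
        wj = w[:, j]
        s_t += (xc * wj[:, None]).T @ xc
        vdev = part.centers[j] - dbar
        s_b += wj.sum() * np.outer(vdev, vdev)
        dev = x - part.centers[j]
        s_w += (dev * wj[:, None]).T @ dev
    return ScatterSet(s_t=s_t, s_b=s_b, s_w=s_w, fuzzy=True)
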