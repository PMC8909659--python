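"""Fuzzy class memberships in score space.

Instead of assigning each training sample wholly to its labelled class, a
fuzzy partition grades membership of every sample in every class from the
sample's distances to the class centers, using the fuzzy c-means (FCM)
membership formula

    u_ij = 1 / sum_k (||x_i - v_j|| / ||x_i - v_k||)^(2/(eta-1))

where eta > 1 is the fuzziness exponent (larger -> softer memberships).
Centers are initialised to the labelled per-class means of the training
scores.  The default ``supervised_oneshot`` mode stops there, which is
deterministic and label-faithful; ``fcm_iterative`` additionally runs the
unsupervised FCM alternating updates to convergence from that
initialisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .spectra import SpectraSet, ValidationError, class_means

__all__ = ["FuzzyPartition", "fuzzy_memberships", "membership_matrix"]

DEFAULT_ETA = 4.0
MEMBERSHIP_MODES = ("supervised_oneshot", "fcm_iterative")


@dataclass
class FuzzyPartition:
    """Membership matrix U (n x c), class centers (c x k) and exponent eta."""

    U: np.ndarray
    centers: np.ndarray
    eta: float
    c: int

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.centers = np.asarray(self.centers, dtype=float)
        if self.eta <= 1:
            raise ValidationError(f"eta must be > 1, got {self.eta}")
        if self.U.ndim != 2 or self.U.shape[1] != self.c:
            raise ValidationError(f"U must be n x c with c={self.c}, got shape {self.U.shape}")
        if self.centers.shape[0] != self.c:
            raise ValidationError(
                f"centers must have c={self.c} rows, got {self.centers.shape[0]}"
            )
        if np.any(self.U < -1e-12) or np.any(self.U > 1 + 1e-12):
            raise ValidationError("memberships must lie in [0, 1]")
        if np.max(np.abs(self.U.sum(axis=1) - 1.0)) > 1e-10:
            raise ValidationError("membership rows must sum to 1")


def membership_matrix(x: np.ndarray, centers: np.ndarray, eta: float) -> np.ndarray:
    """FCM memberships of the rows of ``x`` w.r.t. the given centers.

    A sample coinciding with a center gets membership 1 there and 0
    elsewhere (the zero-distance limit of the formula).
    """
    d = cdist(np.asarray(x, dtype=float), np.asarray(centers, dtype=float))
    u = np.zeros_like(d)
    zero = d <= 0.0
    hit = zero.any(axis=1)
    if np.any(hit):
        # at most one center can coincide (centers are distinct)
        u[hit] = zero[hit].astype(float)
        u[hit] /= u[hit].sum(axis=1, keepdims=True)
    rest = ~hit
    if np.any(rest):
        r = d[rest] ** (-2.0 / (eta - 1.0))
        u[rest] = r / r.sum(axis=1, keepdims=True)
    return u


def _check_distinct_centers(centers: np.ndarray) -> None:
    pd = cdist(centers, centers)
    iu = np.triu_indices(centers.shape[0], k=1)
    if pd[iu].size and pd[iu].min() <= 1e-12:
        raise ValidationError("duplicate identical class centers; memberships undefined")


def fuzzy_memberships(
    scores: SpectraSet,
    eta: float = DEFAULT_ETA,
    mode: str = "supervised_oneshot",
    tol: float = 1e-6,
    max_iter: int = 300,
) -> FuzzyPartition:
    """Build a fuzzy partition of labelled training scores.

    Centers start at the labelled class means.  ``supervised_oneshot``
    evaluates the membership formula once against those centers;
    ``fcm_iterative`` then alternates the standard FCM center/membership
    updates until the membership matrix changes by less than ``tol``
    (max ``max_iter`` sweeps).
    """
    if eta <= 1:
        raise ValidationError(f"eta must be > 1, got {eta}")
    if mode not in MEMBERSHIP_MODES:
        raise ValidationError(f"mode must be one of {MEMBERSHIP_MODES}, got {mode!r}")
    codes = scores.classes
    if codes.size < 2:
        raise ValidationError("fuzzy memberships need at least 2 classes")
    x = scores.absorbance
    _, centers = class_means(x, scores.labels)
    _check_distinct_centers(centers)
    u = membership_matrix(x, centers, eta)

    if mode == "fcm_iterative":
        for _ in range(max_iter):
            w = u**eta
            centers = (w.T @ x) / w.sum(axis=0)[:, None]
            _check_distinct_centers(centers)
            u_new = membership_matrix(x, centers, eta)
            delta = np.max(np.abs(u_new - u))
            u = u_new
            if delta < tol:
                break

    return FuzzyPartition(U=u, centers=centers, eta=float(eta), c=int(codes.size))
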