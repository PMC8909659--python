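"""Small shared linear-algebra helpers."""

from __future__ import annotations

import numpy as np
import scipy.linalg

__all__ = ["fix_signs", "sym_expm", "top_generalized_eig", "exp_discriminant_eig"]


def fix_signs(w: np.ndarray) -> np.ndarray:
    """Deterministic sign convention for eigenvector columns.

    Each column is flipped, if necessary, so that its largest-magnitude
    entry is positive; magnitude ties resolve to the lowest index (numpy
    argmax convention).
    """
    w = np.array(w, dtype=float, copy=True)
    for j in range(w.shape[1]):
        i = int(np.argmax(np.abs(w[:, j])))
        if w[i, j] < 0:
            w[:, j] = -w[:, j]
    return w


def sym_expm(s: np.ndarray) -> np.ndarray:
    """Matrix exponential of a symmetric matrix via eigendecomposition.

    For symmetric ``S = V diag(w) V^T`` the exponential is
    ``V diag(exp(w)) V^T``, which is symmetric positive definite by
    construction -- the property the exponential discriminant relies on.
    """
    w, v = np.linalg.eigh(np.asarray(s, dtype=float))
    return (v * np.exp(w)) @ v.T


def exp_discriminant_eig(
    s_b: np.ndarray, s_w: np.ndarray, q: int
) -> tuple[np.ndarray, np.ndarray]:
    """Top-``q`` eigenpairs of ``exp(S_w)^{-1} exp(S_b)`` for symmetric inputs.

    Solved through symmetric whitening: with ``M = exp(-S_w/2)`` (spectral,
    always well defined), the eigenpairs of ``C = M exp(S_b) M`` give the
    generalized pairs ``exp(S_b) w = t exp(S_w) w`` via ``w = M y``.  This
    stays numerically stable even when ``exp(S_w)`` is so ill-conditioned
    that a Cholesky-based generalized solver would fail: directions with
    huge within-class spread are squashed towards zero by underflow, which
    matches the analytic behaviour of the exponential discriminant.

    Returns descending eigenvalues and sign-fixed columns normalized so
    that ``w^T exp(S_w) w = 1`` (the natural normalization of the
    generalized problem, inherited from ``W = M Y`` with orthonormal
    ``Y``): the projected space is whitened with respect to the
    exponentiated within-class scatter, which is what a Euclidean
    classifier downstream should see.
    """
    wv, v = np.linalg.eigh(np.asarray(s_w, dtype=float))
    m = (v * np.exp(-wv / 2.0)) @ v.T
    c = m @ sym_expm(s_b) @ m
    c = (c + c.T) / 2.0
    vals, y = np.linalg.eigh(c)
    order = np.arange(vals.size)[::-1]
    vals = vals[order][:q]
    w = m @ y[:, order][:, :q]
    return vals, fix_signs(w)


def top_generalized_eig(a: np.ndarray, b_spd: np.ndarray, q: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-``q`` eigenpairs of the symmetric-definite problem ``A w = t B w``.

    ``A`` symmetric, ``B`` symmetric positive definite.  Returns
    ``(eigenvalues, W)`` with eigenvalues in descending order (stable with
    respect to the underlying solver's ordering on ties) and sign-fixed
    eigenvector columns.
    """
    vals, vecs = scipy.linalg.eigh(a, b_spd)
    order = np.arange(vals.size)[::-1]  # eigh returns ascending
    vals = vals[order][:q]
    w = vecs[:, order][:, :q]
    return vals, fix_signs(w)
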