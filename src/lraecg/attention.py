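"""Attention transforms used to weight ECG feature dimensions.

Three variants are provided:

* :func:`self_attention` — classical scaled dot-product self-attention with
  trainable query/key/value maps.
* :func:`simplified_self_attention` — the parameter-free form that scores
  sample-to-sample similarity directly from the input, ``A = softmax(X X^T)``.
* :func:`lra_weights` — the low-rank *dimension* attention: the Gram matrix
  ``G = X^T X`` is factored by SVD, the product of left and right
  singular-vector matrices is double-normalized, and the resulting d×d matrix
  weights feature dimensions rather than samples.

All functions take samples-as-rows matrices (n samples × d feature
dimensions) and are pure: no state, no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SelfAttentionParams",
    "SVDFactors",
    "self_attention",
    "simplified_self_attention",
    "double_norm",
    "svd_gram",
    "lra_weights",
]


def _check_finite_2d(X: np.ndarray, name: str = "X") -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"{name} must be a 2-D matrix, got shape {X.shape}")
    if X.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(np.isfinite(X)):
        raise ValueError(f"{name} contains non-finite entries")
    return X


@dataclass
class SelfAttentionParams:
    """Query/key/value maps for scaled dot-product attention.

    ``Wq`` and ``Wk`` map the d feature dimensions to a dk-dimensional
    query/key space (shape dk×d, acting on the feature axis); ``Wv`` is a
    d×d value map.
    """

    Wq: np.ndarray
    Wk: np.ndarray
    Wv: np.ndarray

    @property
    def dk(self) -> int:
        return self.Wq.shape[0]

    def validate(self, d: int) -> None:
        Wq, Wk, Wv = (np.asarray(m, dtype=float) for m in (self.Wq, self.Wk, self.Wv))
        if Wq.shape != Wk.shape:
            raise ValueError(f"Wq {Wq.shape} and Wk {Wk.shape} must share a shape")
        if Wq.ndim != 2 or Wq.shape[1] != d:
            raise ValueError(f"Wq must be dk×{d}, got {Wq.shape}")
        if Wv.shape != (d, d):
            raise ValueError(f"Wv must be {d}×{d}, got {Wv.shape}")
        if self.dk < 1:
            raise ValueError("dk must be >= 1")


@dataclass
class SVDFactors:
    """Sign-fixed SVD of a symmetric PSD Gram matrix G = U diag(S) Vr^T."""

    U: np.ndarray
    S: np.ndarray
    Vr: np.ndarray


def _row_softmax(M: np.ndarray) -> np.ndarray:
    Z = np.exp(M - M.max(axis=1, keepdims=True))
    return Z / Z.sum(axis=1, keepdims=True)


def self_attention(X: np.ndarray, params: SelfAttentionParams) -> np.ndarray:
    """Scaled dot-product self-attention over samples.

    Returns ``A V`` with ``A = row-softmax(Q K^T / sqrt(dk))``,
    ``Q = X Wq^T``, ``K = X Wk^T``, ``V = X Wv^T``.
    """
    X = _check_finite_2d(X)
    params.validate(X.shape[1])
    Q = X @ np.asarray(params.Wq, float).T
    K = X @ np.asarray(params.Wk, float).T
    V = X @ np.asarray(params.Wv, float).T
    A = _row_softmax(Q @ K.T / np.sqrt(params.dk))
    return A @ V


def simplified_self_attention(X: np.ndarray) -> np.ndarray:
    """Parameter-free self-attention: ``row-softmax(X X^T) X``."""
    X = _check_finite_2d(X)
    return _row_softmax(X @ X.T) @ X


def double_norm(M: np.ndarray, return_parts: bool = False):
    """Double normalization of a square score matrix.

    First each *column* is softmax-normalized over the row index
    (``a~_ij = exp(m_ij) / sum_i exp(m_ij)``, computed with per-column max
    subtraction for overflow safety), then each *row* is sum-normalized
    (``a_ij = a~_ij / sum_j a~_ij``).  Every entry of the result is strictly
    positive and every row sums to 1.

    Parameters
    ----------
    M : square matrix of finite reals.
    return_parts : if True also return the column-softmaxed intermediate.
    """
    M = _check_finite_2d(M, "M")
    if M.shape[0] != M.shape[1]:
        raise ValueError(f"M must be square, got {M.shape}")
    Z = np.exp(M - M.max(axis=0, keepdims=True))
    atilde = Z / Z.sum(axis=0, keepdims=True)
    A = atilde / atilde.sum(axis=1, keepdims=True)
    if return_parts:
        return A, atilde
    return A


def _fix_signs(U: np.ndarray, Vr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # For each column k: if the largest-|.| entry of U[:, k] is negative
    # (ties -> lowest row index), flip the sign of U[:, k] and Vr[:, k].
    # Flipping matched pairs preserves U diag(S) Vr^T.
    idx = np.argmax(np.abs(U), axis=0)
    flip = U[idx, np.arange(U.shape[1])] < 0
    U = U.copy()
    Vr = Vr.copy()
    U[:, flip] *= -1.0
    Vr[:, flip] *= -1.0
    return U, Vr


def svd_gram(X: np.ndarray) -> SVDFactors:
    """SVD of the Gram matrix ``X^T X`` with a deterministic sign convention.

    Singular vectors are sign-ambiguous; each matched (U, Vr) column pair is
    flipped so the largest-magnitude entry of the U column is positive.  For
    degenerate (repeated) singular values the factorization is only unique up
    to rotations within the degenerate subspace; determinism then holds for a
    fixed LAPACK backend but not across backends.
    """
    X = _check_finite_2d(X)
    G = X.T @ X
    try:
        U, S, Vt = np.linalg.svd(G)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - LAPACK failure
        raise FloatingPointError(f"SVD did not converge for Gram matrix:\n{G}") from exc
    U, Vr = _fix_signs(U, Vt.T)
    return SVDFactors(U=U, S=S, Vr=Vr)


def lra_weights(X: np.ndarray, product: str = "uv") -> np.ndarray:
    """Low-rank dimension-attention weights of the feature matrix.

    Computes ``G = X^T X``; factors ``G = U diag(S) Vr^T`` with the sign
    convention of :func:`svd_gram`; forms the singular-vector product
    ``P = U @ Vr`` and returns ``double_norm(P)`` — a d×d matrix with unit
    row sums that scores the pairwise affinity of feature dimensions.

    The result is a deterministic function of X but is *not* meant to be
    differentiated through: downstream consumers treat it as constant data
    (the autoencoder's backward pass never propagates into the SVD).

    ``product="uvt"`` forms ``U @ Vr.T`` instead; for the symmetric PSD Gram
    matrix that product is (numerically) the identity, making the attention
    independent of X, and is exposed only for comparison.
    """
    if product not in ("uv", "uvt"):
        raise ValueError(f"unknown product mode {product!r}")
    f = svd_gram(X)
    P = f.U @ (f.Vr.T if product == "uvt" else f.Vr)
    return double_norm(P)
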