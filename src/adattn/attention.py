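"""Scaled dot-product self-attention over a feature group.

Each scalar feature in a group becomes a token: a learned embedding maps
value v_i to the d-vector w_i·v_i + b_i, so a group of n features yields an
n × d token matrix X.  Attention then scores every token against every other
via X·Xᵀ, scales, row-softmaxes into a row-stochastic weight matrix, and
re-weights the tokens:

    Attention(X) = softmax(X Xᵀ / √d_k) X

with d_k the embedding dimension.  The context rows are convex combinations
of the tokens; mean-pooling them gives one fixed-length context vector per
group.  The softmax is stabilized by row-max subtraction.  A ``linear``
score scale (divide by d_k instead of √d_k) is available as a config switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class AttentionError(ValueError):
    pass


@dataclass
class GroupEmbedParams:
    """Per-feature scalar-to-d embedding: token_i = w_i * v_i + b_i."""

    w: np.ndarray  # (n_features, d)
    b: np.ndarray  # (n_features, d)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.w.shape != self.b.shape or self.w.ndim != 2:
            raise AttentionError("embedding w and b must share shape (n, d)")

    @property
    def n_features(self) -> int:
        return self.w.shape[0]

    @property
    def dim(self) -> int:
        return self.w.shape[1]


@dataclass
class AttentionResult:
    """Row-stochastic attention weights plus the attended context rows."""

    weights: np.ndarray  # (n, n), rows sum to 1
    context: np.ndarray  # (n, d)


def _score_scale(d: int, mode: str) -> float:
    if mode == "sqrt":
        return float(np.sqrt(d))
    if mode == "linear":
        return float(d)
    raise AttentionError(f"unknown score_scale mode {mode!r}")


def softmax_rows(scores: np.ndarray) -> np.ndarray:
    """Numerically stabilized softmax along the last axis."""
    shifted = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def scaled_dot_attention(X: np.ndarray, score_scale: str = "sqrt") -> AttentionResult:
    """Self-attention of a token matrix with itself.

    weights = row-softmax(X Xᵀ / scale), context = weights · X.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 1:
        raise AttentionError("X must be a non-empty n × d matrix")
    if not np.isfinite(X).all():
        raise AttentionError("attention input must be finite")
    scale = _score_scale(X.shape[1], score_scale)
    weights = softmax_rows(X @ X.T / scale)
    return AttentionResult(weights=weights, context=weights @ X)


def embed_group(values: np.ndarray, params: GroupEmbedParams) -> np.ndarray:
    """Map one group's normalized feature values to its n × d token matrix."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.shape[0] != params.n_features:
        raise AttentionError(
            f"expected {params.n_features} values, got shape {v.shape}"
        )
    return params.w * v[:, None] + params.b


def pool_context(result: AttentionResult) -> np.ndarray:
    """Group context vector: mean over the context rows (length d)."""
    return result.context.mean(axis=0)
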