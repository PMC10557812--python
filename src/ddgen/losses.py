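"""Training objective: weighted cross-entropy, prior-alignment loss, and
their lambda-weighted combination.

The classification term is a class-weighted cross-entropy with weights
inverse to the per-class training counts, so rare classes are not drowned
out.  The alignment term couples each class's attention channel to that
class's frozen saliency prior: per sample i and class k it takes the
Euclidean (L2) norm over voxels of M_{i,k} - P_k and sums over i and k.
The total objective is WCE + lambda * alignment, with lambda defaulting to
5e-5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "WeightVector",
    "LossConfig",
    "class_weights",
    "weighted_cross_entropy",
    "similarity_loss",
    "similarity_loss_grad",
    "total_loss",
    "LOG_FLOOR",
]

LOG_FLOOR = 1e-12  # probabilities are clamped here before the log


@dataclass
class WeightVector:
    weights: np.ndarray
    class_counts: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.class_counts = np.asarray(self.class_counts, dtype=np.int64)
        if (self.weights <= 0).any():
            raise ValueError("class weights must be positive")


@dataclass
class LossConfig:
    """lambda_ weights the alignment term; reduction is applied over the
    batch dimension to both terms ('mean' keeps gradient scale independent
    of batch size); squared switches the per-(i,k) distance from the
    Euclidean norm to its square; ground_truth_only restricts the
    alignment sum to each sample's true-class channel."""

    lambda_: float = 5e-5
    reduction: str = "mean"
    squared: bool = False
    ground_truth_only: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.lambda_) or self.lambda_ < 0:
            raise ValueError("lambda_ must be finite and >= 0")
        if self.reduction not in ("mean", "sum"):
            raise ValueError("reduction must be 'mean' or 'sum'")


def class_weights(class_counts, normalize: bool = False) -> WeightVector:
    """weights_k = 1 / counts_k (optionally rescaled to mean 1)."""
    counts = np.asarray(class_counts, dtype=np.int64)
    if (counts < 1).any():
        zero = np.where(counts < 1)[0].tolist()
        raise ValueError(
            f"classes {zero} have zero samples; drop them before computing "
            f"weights"
        )
    w = 1.0 / counts
    if normalize:
        w = w / w.mean()
    return WeightVector(weights=w, class_counts=counts)


def weighted_cross_entropy(
    probs_batch: np.ndarray,
    labels: np.ndarray,
    w: WeightVector,
    reduction: str = "mean",
) -> float:
    """-sum_i w_{y_i} log p_i[y_i], with 'mean' dividing by the batch size."""
    probs = np.asarray(probs_batch, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if probs.ndim != 2 or len(labels) != probs.shape[0]:
        raise ValueError("probs_batch must be (N, K) with one label per row")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("each probability row must sum to 1")
    p_true = probs[np.arange(len(labels)), labels]
    if (p_true < LOG_FLOOR).any():
        warnings.warn(
            "true-class probability below the log floor; clamping",
            RuntimeWarning,
            stacklevel=2,
        )
    loss = -(w.weights[labels] * np.log(np.maximum(p_true, LOG_FLOOR))).sum()
    if reduction == "mean":
        loss /= len(labels)
    return float(loss)


def _pair_distance(m: np.ndarray, p: np.ndarray, squared: bool) -> float:
    d2 = float(((m - p) ** 2).sum())
    return d2 if squared else np.sqrt(d2)


def similarity_loss(
    attention_batch: np.ndarray,
    priors: np.ndarray,
    config: LossConfig | None = None,
    labels: np.ndarray | None = None,
) -> float:
    """Alignment loss: sum over samples i and classes k of the L2 distance
    between attention map M_{i,k} and prior P_k (both on the same grid).

    ``attention_batch`` is (N, K, D', H', W'); ``priors`` is (K, D', H', W').
    With ``config.ground_truth_only`` only the channel of each sample's
    true class contributes (``labels`` then required).
    """
    config = config or LossConfig()
    m = np.asarray(attention_batch, dtype=np.float64)
    p = np.asarray(priors, dtype=np.float64)
    if m.ndim != 5 or p.ndim != 4:
        raise ValueError("attention_batch must be (N,K,D,H,W), priors (K,D,H,W)")
    if m.shape[1:] != p.shape:
        raise ValueError(
            f"attention grid {m.shape[1:]} does not match prior grid "
            f"{p.shape}; resample the priors to the attention grid first "
            f"(priors.resample_prior)"
        )
    n, k = m.shape[:2]
    total = 0.0
    for i in range(n):
        if config.ground_truth_only:
            if labels is None:
                raise ValueError("ground_truth_only mode requires labels")
            ks = [int(labels[i])]
        else:
            ks = range(k)
        for kk in ks:
            total += _pair_distance(m[i, kk], p[kk], config.squared)
    if config.reduction == "mean":
        total /= n
    return float(total)


def similarity_loss_grad(
    attention_batch: np.ndarray,
    priors: np.ndarray,
    config: LossConfig | None = None,
    labels: np.ndarray | None = None,
) -> np.ndarray:
    """d similarity_loss / d attention_batch, same shape as the batch.

    Per (i, k) block the gradient of the Euclidean norm is
    (M - P) / ||M - P|| (zero at M = P); for the squared variant it is
    2 (M - P)."""
    config = config or LossConfig()
    m = np.asarray(attention_batch, dtype=np.float64)
    p = np.asarray(priors, dtype=np.float64)
    n, k = m.shape[:2]
    g = np.zeros_like(m)
    for i in range(n):
        for kk in range(k):
            if config.ground_truth_only and (labels is None or kk != int(labels[i])):
                continue
            diff = m[i, kk] - p[kk]
            if config.squared:
                g[i, kk] = 2.0 * diff
            else:
                norm = np.sqrt((diff**2).sum())
                if norm > 0:
                    g[i, kk] = diff / norm
    if config.reduction == "mean":
        g /= n
    return g


def total_loss(wce: float, sim: float, config: LossConfig | None = None) -> float:
    """Combined objective: wce + lambda * sim."""
    config = config or LossConfig()
    if not (np.isfinite(wce) and np.isfinite(sim)):
        raise ValueError("loss components must be finite")
    return float(wce + config.lambda_ * sim)
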