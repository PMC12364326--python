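"""Loss terms for adversarial, deeply supervised, edge-aware training.

All per-pixel losses are sums over pixels (batch inputs take the mean of
per-image sums); a mean-over-pixels reduction exists for scale stability
but is off by default.  Functions accept autodiff tensors for the
predicted quantities and plain arrays for labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ShapeError
from .nn import Tensor, as_tensor

__all__ = [
    "LossWeights", "LossReport",
    "adversarial_loss", "balanced_positive_weight", "weighted_bce_level",
    "aggregated_mask_loss", "discriminator_loss", "edge_loss",
    "dice_loss", "generator_loss",
]

DICE_EPS = 1e-6


@dataclass(frozen=True)
class LossWeights:
    """Coefficients of the edge and Dice terms in the generator loss."""

    omega_e: float = 1.0
    omega_s: float = 1.0

    def __post_init__(self):
        if not (np.isfinite(self.omega_e) and np.isfinite(self.omega_s)):
            raise ValueError("loss weights must be finite")
        if self.omega_e < 0 or self.omega_s < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclass
class LossReport:
    """Scalar loss ledger for one iteration."""

    L_a: float = 0.0
    L_ds: float = 0.0
    L_d: float = 0.0
    L_ge: float = 0.0
    L_gs: float = 0.0
    L_g: float = 0.0
    per_level_mask: list = field(default_factory=list)   # L_dk, k = 1..4
    per_level_edge: list = field(default_factory=list)   # L_gk, k = 1..4
    balance_weights_mask: list = field(default_factory=list)
    balance_weights_edge: list = field(default_factory=list)
    lr: float = 0.0
    iteration: int = 0

    def as_dict(self) -> dict:
        return {
            "iteration": self.iteration, "lr": self.lr,
            "L_a": self.L_a, "L_ds": self.L_ds, "L_d": self.L_d,
            "L_ge": self.L_ge, "L_gs": self.L_gs, "L_g": self.L_g,
        }

    def all_finite(self) -> bool:
        vals = [self.L_a, self.L_ds, self.L_d, self.L_ge, self.L_gs, self.L_g]
        return bool(np.isfinite(vals).all())


def adversarial_loss(score_fake, score_real) -> Tensor:
    """|D(x*yhat) - D(x*y)| on batch-mean critic scores."""
    return (as_tensor(score_fake) - as_tensor(score_real)).abs()


def balanced_positive_weight(label: np.ndarray):
    """N_neg/N_pos when positives exist, else 1.

    For a batched label (N, ...) a weight is returned per image.
    """
    label = np.asarray(label)
    if label.ndim <= 2:
        n_pos = label.sum()
        return float((label.size - n_pos) / n_pos) if n_pos > 0 else 1.0
    flat = label.reshape(label.shape[0], -1)
    n_pos = flat.sum(axis=1)
    n_neg = flat.shape[1] - n_pos
    return np.where(n_pos > 0, n_neg / np.maximum(n_pos, 1), 1.0)


def weighted_bce_level(logits: Tensor, label: np.ndarray, weight,
                       reduction: str = "sum") -> Tensor:
    """Class-balanced binary cross entropy of one side-output level.

    ``-sum_i [w * y_i * log s(F_i) + (1 - y_i) * log(1 - s(F_i))]`` with a
    numerically stable log-sigmoid.  Batched inputs return the mean of
    per-image sums; ``reduction="mean"`` divides by the pixel count instead.
    """
    logits = as_tensor(logits)
    label = np.asarray(label, dtype=np.float64)
    if logits.shape != label.shape:
        raise ShapeError(
            f"logits {logits.shape} and label {label.shape} differ")
    if label.ndim > 2:
        w = np.asarray(weight, dtype=np.float64).reshape(
            (-1,) + (1,) * (label.ndim - 1))
    else:
        w = float(weight)

    log_sig = -(-logits).softplus()      # log sigmoid(F)
    log_one_minus = -logits.softplus()   # log(1 - sigmoid(F))
    pixel = -(Tensor(w * label) * log_sig + Tensor(1.0 - label) * log_one_minus)

    if label.ndim > 2:
        per_image = pixel.sum(axis=tuple(range(1, label.ndim)))
        total = per_image.mean()
        if reduction == "mean":
            total = total * (1.0 / label[0].size)
        return total
    total = pixel.sum()
    if reduction == "mean":
        total = total * (1.0 / label.size)
    return total


def _pyramid_bce(native_logits, pyramid_levels, reduction):
    if len(native_logits) != len(pyramid_levels):
        raise ValueError(
            f"{len(native_logits)} side outputs vs "
            f"{len(pyramid_levels)} pyramid levels")
    per_level, weights = [], []
    total = None
    for s_k, y_k in zip(native_logits, pyramid_levels):
        y_k = np.asarray(y_k)
        s_k = as_tensor(s_k)
        if s_k.ndim == 4 and s_k.shape[1] == 1:  # drop the channel axis
            s_k = s_k.reshape(s_k.shape[0], *s_k.shape[2:])
        w_k = balanced_positive_weight(y_k)
        l_k = weighted_bce_level(s_k, y_k, w_k, reduction)
        per_level.append(l_k)
        weights.append(w_k)
        total = l_k if total is None else total + l_k
    return total, per_level, weights


def aggregated_mask_loss(native_logits, mask_pyramid_levels,
                         reduction: str = "sum"):
    """Sum of balanced BCE over the 4 levels against the mask pyramid.

    Returns ``(L_ds, [L_dk...], [w_k...])``; each level's positive weight is
    recomputed from that level's label.
    """
    return _pyramid_bce(native_logits, mask_pyramid_levels, reduction)


def edge_loss(native_logits, edge_pyramid_levels, reduction: str = "sum"):
    """Same form as the mask loss but against the edge pyramid (L_ge)."""
    return _pyramid_bce(native_logits, edge_pyramid_levels, reduction)


def discriminator_loss(L_a, L_ds) -> Tensor:
    """L_d = -L_a - L_ds; minimizing it maximizes the adversarial gap."""
    return -as_tensor(L_a) - as_tensor(L_ds)


def dice_loss(pred: Tensor, truth: np.ndarray, eps: float = DICE_EPS) -> Tensor:
    """1 - 2|y*yhat|/(|y| + |yhat|), smoothed by ``eps`` against 0/0."""
    pred = as_tensor(pred)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ShapeError(f"pred {pred.shape} and truth {truth.shape} differ")
    inter = (pred * Tensor(truth)).sum()
    denom = pred.sum() + float(truth.sum())
    return 1.0 - (2.0 * inter + eps) / (denom + eps)


def generator_loss(L_a, L_ge, L_gs, weights: LossWeights = LossWeights()) -> Tensor:
    """L_g = L_a + w_e * L_ge + w_s * L_gs."""
    return as_tensor(L_a) + weights.omega_e * as_tensor(L_ge) \
        + weights.omega_s * as_tensor(L_gs)
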