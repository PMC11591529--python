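"""Focal, Dice and combined segmentation losses.

The training objective is ``L = L_focal + L_dice``.  Focal loss is
cross-entropy reweighted by ``(1 - p_t)^gamma`` with a class-balance factor
``alpha_t``, which counters the extreme background/foreground pixel imbalance
of Doppler frames where the regurgitant jet can be a small fraction of the
image.  Dice loss is one minus the (squared-denominator) Dice overlap
coefficient, optimizing region overlap directly and therefore behaving well
on small structures.

Two surfaces are provided:

* plain-NumPy functions (:func:`focal_loss`, :func:`dice_loss`,
  :func:`combined_loss`) operating on per-pixel probability/indicator arrays,
  used for analysis and as the reference the training losses are tested
  against;
* autograd counterparts (:func:`focal_loss_t`, :func:`dice_loss_t`,
  :func:`combined_loss_t`) over ``mrseg.nn`` tensors, consumed by the
  training engine on B x K x H x W probability maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.tensor import Tensor

EPS = 1e-7

__all__ = [
    "LossConfig",
    "focal_loss",
    "dice_loss",
    "combined_loss",
    "focal_loss_t",
    "dice_loss_t",
    "combined_loss_t",
]


@dataclass(frozen=True)
class LossConfig:
    """alpha_t: class-balance weight in (0, 1]; gamma: focusing exponent >= 0;
    dice_smooth: additive smoothing protecting empty classes from 0/0."""

    alpha_t: float = 0.25
    gamma: float = 2.0
    dice_smooth: float = 1e-5
    focal_weight: float = 1.0
    dice_weight: float = 1.0

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not (0 < self.alpha_t <= 1):
            raise ValueError("alpha_t must be in (0, 1]")
        if self.dice_smooth < 0:
            raise ValueError("dice_smooth must be >= 0")


def focal_loss(p_true: np.ndarray, cfg: LossConfig = LossConfig()) -> float:
    """Mean over pixels of ``-alpha_t * (1 - p_t)^gamma * log(p_t)``.

    ``p_true`` holds the predicted probability of the *true* class at each
    pixel (any shape).
    """
    p = np.clip(np.asarray(p_true, dtype=np.float64), EPS, 1.0 - EPS)
    return float(np.mean(-cfg.alpha_t * (1.0 - p) ** cfg.gamma * np.log(p)))


def dice_loss(
    p: np.ndarray, g: np.ndarray, smooth: float = 1e-5
) -> float:
    """``1 - (2*sum(p*g) + s) / (sum(p^2) + sum(g^2) + s)`` for one class."""
    p = np.asarray(p, dtype=np.float64).ravel()
    g = np.asarray(g, dtype=np.float64).ravel()
    if p.size == 0:
        raise ValueError("dice_loss needs at least one pixel")
    num = 2.0 * np.sum(p * g) + smooth
    den = np.sum(p * p) + np.sum(g * g) + smooth
    if den == 0.0:
        return 0.0  # both empty and s=0: define perfect agreement
    return float(1.0 - num / den)


def combined_loss(
    p_true: np.ndarray,
    p_fg: np.ndarray,
    g_fg: np.ndarray,
    cfg: LossConfig = LossConfig(),
) -> float:
    """Sum of focal (on true-class probabilities) and Dice (on one
    foreground-class probability/indicator pair)."""
    return cfg.focal_weight * focal_loss(p_true, cfg) + cfg.dice_weight * dice_loss(
        p_fg, g_fg, cfg.dice_smooth
    )


# ---------------------------------------------------------------------------
# autograd versions on B x K x H x W probability maps


def _one_hot(labels: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((labels.shape[0], k) + labels.shape[1:], dtype=np.float32)
    for c in range(k):
        out[:, c] = labels == c
    return out


def focal_loss_t(probs: Tensor, labels: np.ndarray, cfg: LossConfig = LossConfig()) -> Tensor:
    """Multiclass focal loss; ``probs`` B x K x H x W, ``labels`` B x H x W."""
    k = probs.shape[1]
    onehot = _one_hot(labels, k)
    p_t = (probs * Tensor(onehot)).sum(axis=1).clip(EPS, 1.0 - EPS)
    focus = (1.0 - p_t).pow(cfg.gamma) if cfg.gamma != 0 else 1.0
    return (focus * p_t.log() * (-cfg.alpha_t)).mean()


def dice_loss_t(
    probs: Tensor,
    labels: np.ndarray,
    cfg: LossConfig = LossConfig(),
    classes: tuple[int, ...] = (1, 2),
) -> Tensor:
    """Dice loss averaged one-vs-rest over ``classes`` (foreground only by
    default: MR jet and left atrium)."""
    from .nn.tensor import narrow

    k = probs.shape[1]
    onehot = _one_hot(labels, k)
    p = probs.reshape(probs.shape[0], k, -1)
    total = None
    for c in classes:
        p_c = narrow(p, 1, c, 1)
        g_c = Tensor(onehot[:, c].reshape(onehot.shape[0], 1, -1))
        num = (p_c * g_c).sum() * 2.0 + cfg.dice_smooth
        den = (p_c * p_c).sum() + (g_c * g_c).sum() + cfg.dice_smooth
        term = 1.0 - num / den
        total = term if total is None else total + term
    return total * (1.0 / len(classes))


def combined_loss_t(
    probs: Tensor,
    labels: np.ndarray,
    cfg: LossConfig = LossConfig(),
    classes: tuple[int, ...] = (1, 2),
) -> Tensor:
    return focal_loss_t(probs, labels, cfg) * cfg.focal_weight + dice_loss_t(
        probs, labels, cfg, classes
    ) * cfg.dice_weight
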