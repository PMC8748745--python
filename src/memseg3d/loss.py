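"""Confidence-regularized weighted Dice loss for 3-class voxel segmentation.

The semantic network classifies each voxel as background, membrane, or cell
foreground. Plain Dice loss lets the network claim foreground voxels near
membranes with low confidence, which fuses neighboring cell masks (the
clumped-cell problem). Two modifications counter this:

* a per-voxel weight ``w`` from a reverse distance transform of each class
  mask, so positive voxels near the mask boundary (i.e. near membranes)
  carry the largest weight in the Dice numerator;
* in the foreground term only, the confidence ``p`` is replaced by
  ``p / (p + alpha)``, which rises steeply at small ``p`` and stays below 1
  even at ``p = 1`` — a regularizer that penalizes low-confidence foreground
  heavily and keeps a small residual penalty at perfect predictions.

For weighted Dice terms ``1 - 2 Σ p g w / (Σ p² + Σ g²)`` (weights in the
numerator only), the per-voxel analytic gradients are closed-form; they are
the exact gradients used by the numpy training loop and double as the oracle
against finite differences in the test suite.

Channel order everywhere: 0 = background, 1 = membrane, 2 = foreground.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .phantom import SemanticMasks

__all__ = [
    "BACKGROUND",
    "MEMBRANE",
    "FOREGROUND",
    "ClassProbabilityVolume",
    "LossBreakdown",
    "reverse_distance_weights",
    "weight_stack",
    "confidence_transform",
    "dice_term",
    "foreground_term",
    "total_loss",
    "grad_dice_term",
    "grad_foreground_term",
    "loss_gradient",
    "loss_gradient_foreground",
]

BACKGROUND, MEMBRANE, FOREGROUND = 0, 1, 2


@dataclasses.dataclass
class ClassProbabilityVolume:
    """Per-voxel probabilities over (background, membrane, foreground).

    ``probs`` has shape (3, Z, Y, X) and sums to 1 over the class axis
    within 1e-5 (softmax output contract).
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs)
        if self.probs.ndim != 4 or self.probs.shape[0] != 3:
            raise ValueError(f"expected (3, Z, Y, X) probabilities, got {self.probs.shape}")
        s = self.probs.sum(axis=0)
        if not np.allclose(s, 1.0, atol=1e-5):
            raise ValueError("class probabilities must sum to 1 per voxel (within 1e-5)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.probs.shape[1:]


@dataclasses.dataclass
class LossBreakdown:
    """Total loss and its two components; total = foreground + others."""

    total: float
    foreground_term: float
    others_term: float
    alpha: float


def reverse_distance_weights(class_mask: np.ndarray, w_min: float = 0.5) -> np.ndarray:
    """Reverse-distance-transform weights for one class mask.

    For in-mask voxels, let ``d`` be the Euclidean distance to the nearest
    out-of-mask voxel (the volume border counts as out-of-mask). Weights are
    the affine rescaling ``w_min + (1 - w_min)(d_max - d)/(d_max - d_min)``
    over in-mask voxels: boundary-adjacent voxels get weight 1, the deepest
    interior gets ``w_min``. Out-of-mask voxels get weight 1 (they never
    enter the numerator, where these weights are applied). A mask of uniform
    depth (or an empty mask) yields all-ones weights.
    """
    mask = np.asarray(class_mask).astype(bool)
    w = np.ones(mask.shape, dtype=np.float64)
    if not mask.any():
        return w
    if not 0.0 < w_min <= 1.0:
        raise ValueError("w_min must lie in (0, 1]")
    padded = np.pad(mask, 1, mode="constant", constant_values=False)
    d = ndimage.distance_transform_edt(padded)[1:-1, 1:-1, 1:-1]
    dpos = d[mask]
    d_min, d_max = dpos.min(), dpos.max()
    if d_max > d_min:
        w[mask] = w_min + (1.0 - w_min) * (d_max - dpos) / (d_max - d_min)
    return w


def weight_stack(masks: SemanticMasks, w_min: float = 0.5) -> np.ndarray:
    """(3, Z, Y, X) reverse-distance weights, one channel per class."""
    return np.stack(
        [
            reverse_distance_weights(masks.background, w_min),
            reverse_distance_weights(masks.membrane, w_min),
            reverse_distance_weights(masks.foreground, w_min),
        ]
    )


def confidence_transform(p, alpha: float):
    """The regularizing replacement ``p / (p + alpha)``.

    Strictly increasing in ``p`` on [0, 1]; equals 0.5 at ``p = alpha`` and
    stays below 1 for all ``p <= 1``, so even a perfect prediction retains a
    small penalty.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    return np.asarray(p, dtype=np.float64) / (np.asarray(p, dtype=np.float64) + alpha)


def _dice_sums(q: np.ndarray, g: np.ndarray, w) -> tuple[float, float]:
    gw = g if w is None else g * w
    num = 2.0 * float(np.sum(q * gw))
    den = float(np.sum(q * q)) + float(np.sum(g * g))
    return num, den


def dice_term(p: np.ndarray, g: np.ndarray, w: np.ndarray | None = None) -> float:
    """Weighted Dice loss term ``1 - 2 Σ p g w / (Σ p² + Σ g²)``.

    Weights multiply the numerator only. When both ``p`` and ``g`` are
    identically zero (an empty-class cuboid under random cropping) the term
    is defined as 0, not NaN.
    """
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    num, den = _dice_sums(p, g, w)
    if den == 0.0:
        return 0.0
    return 1.0 - num / den


def foreground_term(p: np.ndarray, g: np.ndarray, w: np.ndarray | None, alpha: float) -> float:
    """Foreground Dice term with the confidence replacement ``p/(p+alpha)``.

    Because the replacement stays below 1, this term is strictly positive
    even at a perfect binary prediction (0.004525 at alpha = 0.1).
    """
    r = confidence_transform(p, alpha)
    g = np.asarray(g, dtype=np.float64)
    num, den = _dice_sums(r, g, w)
    if den == 0.0:
        return 0.0
    return 1.0 - num / den


def total_loss(
    p: ClassProbabilityVolume | np.ndarray,
    g: SemanticMasks | np.ndarray,
    w: np.ndarray | None = None,
    alpha: float = 0.1,
    plain_dice: bool = False,
) -> LossBreakdown:
    """Total segmentation loss over the three class channels.

    The "others" component averages the weighted Dice terms of the
    background and membrane channels; the foreground component uses the
    confidence replacement. ``plain_dice=True`` is the ablation switch that
    drops the replacement (foreground becomes an ordinary weighted Dice
    term; pass ``w=None`` as well for the fully plain ablation).
    """
    ps = p.probs if isinstance(p, ClassProbabilityVolume) else np.asarray(p)
    gs = g.stack() if isinstance(g, SemanticMasks) else np.asarray(g)
    if ps.shape != gs.shape:
        raise ValueError(f"probability shape {ps.shape} != mask shape {gs.shape}")
    if w is not None and np.asarray(w).shape != ps.shape:
        raise ValueError("weight stack shape mismatch")
    wc = (lambda c: None) if w is None else (lambda c: np.asarray(w)[c])
    others = 0.5 * (
        dice_term(ps[BACKGROUND], gs[BACKGROUND], wc(BACKGROUND))
        + dice_term(ps[MEMBRANE], gs[MEMBRANE], wc(MEMBRANE))
    )
    if plain_dice:
        fg = dice_term(ps[FOREGROUND], gs[FOREGROUND], wc(FOREGROUND))
    else:
        fg = foreground_term(ps[FOREGROUND], gs[FOREGROUND], wc(FOREGROUND), alpha)
    return LossBreakdown(total=fg + others, foreground_term=fg, others_term=others, alpha=alpha)


def grad_dice_term(p: np.ndarray, g: np.ndarray, w: np.ndarray | None = None) -> np.ndarray:
    """Closed-form per-voxel gradient of :func:`dice_term` w.r.t. ``p``."""
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    num, den = _dice_sums(p, g, w)
    if den == 0.0:
        return np.zeros_like(p)
    gw = g if w is None else g * w
    # d/dp_k [1 - num/den] = 2 * (-g_k w_k * den + 2 p_k * (num/2)) / den^2
    return 2.0 * (-gw * den + p * num) / den**2


def grad_foreground_term(
    p: np.ndarray, g: np.ndarray, w: np.ndarray | None, alpha: float
) -> np.ndarray:
    """Closed-form gradient of :func:`foreground_term` w.r.t. ``p``.

    Chain rule through the replacement: the Dice gradient w.r.t.
    ``r = p/(p+alpha)`` times ``dr/dp = alpha/(p+alpha)²``.
    """
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    r = confidence_transform(p, alpha)
    num, den = _dice_sums(r, g, w)
    if den == 0.0:
        return np.zeros_like(p)
    gw = g if w is None else g * w
    dr = 2.0 * (-gw * den + r * num) / den**2
    return dr * (alpha / (p + alpha) ** 2)


def loss_gradient(
    p: np.ndarray,
    g: SemanticMasks | np.ndarray,
    w: np.ndarray | None = None,
    alpha: float = 0.1,
    plain_dice: bool = False,
) -> np.ndarray:
    """Per-voxel gradient of :func:`total_loss` w.r.t. all 3 channels."""
    ps = p.probs if isinstance(p, ClassProbabilityVolume) else np.asarray(p)
    gs = g.stack() if isinstance(g, SemanticMasks) else np.asarray(g)
    wc = (lambda c: None) if w is None else (lambda c: np.asarray(w)[c])
    out = np.empty(ps.shape, dtype=np.float64)
    out[BACKGROUND] = 0.5 * grad_dice_term(ps[BACKGROUND], gs[BACKGROUND], wc(BACKGROUND))
    out[MEMBRANE] = 0.5 * grad_dice_term(ps[MEMBRANE], gs[MEMBRANE], wc(MEMBRANE))
    if plain_dice:
        out[FOREGROUND] = grad_dice_term(ps[FOREGROUND], gs[FOREGROUND], wc(FOREGROUND))
    else:
        out[FOREGROUND] = grad_foreground_term(
            ps[FOREGROUND], gs[FOREGROUND], wc(FOREGROUND), alpha
        )
    return out


def loss_gradient_foreground(
    p: np.ndarray, g: np.ndarray, w: np.ndarray | None = None, alpha: float = 0.1
) -> np.ndarray:
    """Single-channel regularizer profile: Dice gradient + replaced-Dice gradient.

    This is the quantity whose magnitude-vs-confidence curve explains the
    regularization: much steeper than plain Dice below p ~ 0.2, flatter near
    1. It treats one probability field as both the plain and the replaced
    channel, matching the one-dimensional simulation of the loss's behavior.
    """
    return grad_dice_term(p, g, w) + grad_foreground_term(p, g, w, alpha)
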