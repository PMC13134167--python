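"""Loss terms for dual-consistency semi-supervised segmentation.

Supervised arm: a deeply supervised sum over all prediction levels of an
equal-weight Dice + cross-entropy mix against the ground-truth mask.

Unsupervised arm, computed on unlabeled images only by default:

* hierarchical consistency — each level's probability map is pulled toward
  the across-level average map;
* uncertainty rectification — each pixel's consistency penalty is scaled by
  w = exp(-D), where D is the KL divergence between the level's prediction
  and the average prediction at that pixel, so unreliable (high-divergence)
  pixels contribute less;
* coarse--fine consistency — the coarse map p_1 is pulled toward the
  (gradient-blocked) fine fused map p_0, which acts as a soft pseudo-label.

The two unsupervised terms are mixed by beta and scaled by a Gaussian
warm-up weight lambda(t) = k * exp(-5 (1 - t/T)^2) that ramps from
k*e^-5 at t=0 up to k at t=T.

Distance convention: every consistency term uses the squared L2 distance
per pixel (summed over class channels), averaged over pixels and batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, as_tensor, clip_min, log

__all__ = [
    "LossBundle", "UncertaintyMap", "ScheduleConfig",
    "supervised_loss", "average_prediction", "hierarchical_consistency",
    "uncertainty_map", "rectified_consistency", "cfgc_loss",
    "lambda_schedule", "total_loss",
]

_LOG_EPS = 1e-8
_DICE_SMOOTH = 1e-5


@dataclass
class LossBundle:
    """All loss terms of one optimization step (floats, for logging)."""
    l_sup: float
    l_hc: float
    l_urc: float
    l_cr: float
    l_unsup: float
    l_total: float
    lam: float


@dataclass
class ScheduleConfig:
    k: float = 0.1            # ramp ceiling of the warm-up weight
    total_iters: int = 1000   # T
    beta: float = 0.5         # mix between rectified HC and coarse-fine terms
    alpha: tuple | None = None  # per-level supervision weights; None = all 1.0

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.total_iters < 1:
            raise ValueError("total_iters must be >= 1")
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError("beta must lie in [0, 1]")


@dataclass
class UncertaintyMap:
    """Per-level, per-pixel KL divergence ``d`` and weight ``w = exp(-d)``."""
    d: np.ndarray   # (S, N, H, W), nonnegative
    w: np.ndarray   # (S, N, H, W), in (0, 1]


def _as_batched(p) -> Tensor:
    """Coerce a (K,H,W) or (N,K,H,W) probability map to a batched Tensor."""
    t = as_tensor(p)
    if t.ndim == 3:
        t = t.reshape(1, *t.shape)
    return t


def _one_hot(mask: np.ndarray, k: int) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() >= k:
        raise ValueError(f"mask contains classes outside [0, {k})")
    oh = np.zeros((mask.size, k), dtype=np.float32)
    oh[np.arange(mask.size), mask.ravel()] = 1.0
    return oh.reshape(*mask.shape, k).transpose(
        0, mask.ndim, *range(1, mask.ndim))


def dice_ce_loss(p: Tensor, mask: np.ndarray) -> Tensor:
    """0.5 * cross-entropy + 0.5 * soft Dice against integer labels."""
    p = _as_batched(p)
    mask = np.asarray(mask)
    if mask.ndim == p.ndim - 2:
        mask = mask[None]
    n, k, h, w = p.shape
    if mask.shape != (n, h, w):
        raise ValueError(f"mask shape {mask.shape} does not match "
                         f"prediction {(n, h, w)}")
    oh = _one_hot(mask, k)                               # (N,K,H,W)
    ce = -(log(clip_min(p, _LOG_EPS)) * oh).sum(axis=1).mean()
    inter = (p * oh).sum(axis=(0, 2, 3))
    denom = p.sum(axis=(0, 2, 3)) + oh.sum(axis=(0, 2, 3))
    dice = 1.0 - ((inter * 2.0 + _DICE_SMOOTH) /
                  (denom + _DICE_SMOOTH)).mean()
    return ce * 0.5 + dice * 0.5


def supervised_loss(preds, mask, alpha=None) -> Tensor:
    """Deep supervision: sum over levels s of alpha_s * (0.5 CE + 0.5 Dice).

    ``preds`` is a MultiLevelPrediction or a list of probability maps indexed
    by level (p_0 first); a ``None`` entry (absent fine head) is skipped.
    ``alpha`` aligns with the level index.
    """
    maps = preds.maps if hasattr(preds, "maps") else list(preds)
    if alpha is None:
        alpha = [1.0] * len(maps)
    total = None
    for a, p in zip(alpha, maps):
        if p is None or a == 0.0:
            continue
        term = dice_ce_loss(p, mask) * float(a)
        total = term if total is None else total + term
    if total is None:
        raise ValueError("no prediction levels to supervise")
    return total


def average_prediction(heads) -> Tensor:
    """Mean of the deeply supervised maps p_1..p_S (the fine map excluded)."""
    heads = [_as_batched(p) for p in heads]
    if len(heads) < 2:
        raise ValueError("averaging requires at least two levels")
    acc = heads[0]
    for p in heads[1:]:
        acc = acc + p
    return acc * (1.0 / len(heads))


def _sq_dist_map(a: Tensor, b: Tensor) -> Tensor:
    """Per-pixel squared L2 distance, summed over the class channel."""
    d = a - b
    return (d * d).sum(axis=1)


def hierarchical_consistency(heads, p_avg=None) -> Tensor:
    """Mean over levels of the pixel-averaged squared distance to the average map."""
    heads = [_as_batched(p) for p in heads]
    if p_avg is None:
        p_avg = average_prediction(heads)
    else:
        p_avg = _as_batched(p_avg)
    acc = None
    for p in heads:
        term = _sq_dist_map(p, p_avg).mean()
        acc = term if acc is None else acc + term
    return acc * (1.0 / len(heads))


def uncertainty_map(heads, p_avg=None) -> UncertaintyMap:
    """Per-pixel KL(p_s || p_avg) over class channels, and w = exp(-d).

    Computed outside the autodiff tape: the weights act as constants when
    rectifying the consistency loss.
    """
    arrs = [(_as_batched(p)).data for p in heads]
    if p_avg is None:
        avg = np.mean(arrs, axis=0)
    else:
        avg = _as_batched(p_avg).data
    avg_c = np.maximum(avg, _LOG_EPS)
    d = np.stack([
        np.sum(np.maximum(p, _LOG_EPS) *
               (np.log(np.maximum(p, _LOG_EPS)) - np.log(avg_c)), axis=1)
        for p in arrs])
    d = np.maximum(d, 0.0)          # guard tiny negative rounding
    return UncertaintyMap(d=d, w=np.exp(-d))


def rectified_consistency(heads, p_avg=None, umap: UncertaintyMap | None = None
                          ) -> Tensor:
    """Uncertainty-rectified consistency: per level, the w-weighted average
    over pixels of the squared distance to the average map, then averaged
    over levels.  With w identically 1 this equals hierarchical_consistency.
    """
    heads = [_as_batched(p) for p in heads]
    if p_avg is None:
        p_avg = average_prediction(heads)
    else:
        p_avg = _as_batched(p_avg)
    if umap is None:
        umap = uncertainty_map(heads, p_avg)
    acc = None
    for s, p in enumerate(heads):
        w = umap.w[s]
        wsum = float(w.sum())
        if wsum <= 0:
            raise ValueError("uncertainty weights sum to zero")
        term = (_sq_dist_map(p, p_avg) * w).sum() * (1.0 / wsum)
        acc = term if acc is None else acc + term
    return acc * (1.0 / len(heads))


def cfgc_loss(p0, p1, stop_gradient: bool = True) -> Tensor:
    """Coarse--fine consistency: squared distance between the fine map p_0
    and the coarse map p_1, averaged over pixels.

    By default p_0 is detached (treated as a pseudo-label target), so the
    gradient flows only through p_1.
    """
    p0, p1 = _as_batched(p0), _as_batched(p1)
    if p0.shape != p1.shape:
        raise ValueError(f"shape mismatch: {p0.shape} vs {p1.shape}")
    if stop_gradient:
        p0 = p0.detach()
    return _sq_dist_map(p0, p1).mean()


def lambda_schedule(t: float, cfg: ScheduleConfig) -> float:
    """Gaussian warm-up lambda(t) = k * exp(-5 (1 - t/T)^2); t > T clamps to T."""
    t = min(max(float(t), 0.0), float(cfg.total_iters))
    frac = t / cfg.total_iters
    return cfg.k * float(np.exp(-5.0 * (1.0 - frac) ** 2))


def total_loss(sup, urc, cr, t: float, cfg: ScheduleConfig,
               hc: float = 0.0) -> LossBundle:
    """Assemble L_total = L_sup + lambda * (beta L_urc + (1-beta) L_cr)."""
    s = sup.item() if isinstance(sup, Tensor) else float(sup)
    u = urc.item() if isinstance(urc, Tensor) else float(urc)
    c = cr.item() if isinstance(cr, Tensor) else float(cr)
    lam = lambda_schedule(t, cfg)
    l_unsup = cfg.beta * u + (1.0 - cfg.beta) * c
    return LossBundle(l_sup=s, l_hc=float(hc), l_urc=u, l_cr=c,
                      l_unsup=l_unsup, l_total=s + lam * l_unsup, lam=lam)
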