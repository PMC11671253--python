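"""Loss functions: cross-view contrastive loss, BCE, and the weighted total.

The contrastive term is InfoNCE-style over node embeddings from two graph
views.  For node ``i`` the positive pair is its own embedding in the other
view; negatives are every other node in *both* views (intra- and inter-view).
With cosine similarity ``theta`` and temperature ``tau`` the one-sided
per-node term is

    l(x_i, y_i) = log[ e^{theta(x_i,y_i)/tau} /
                       ( e^{theta(x_i,y_i)/tau}
                         + sum_{k != i} ( e^{theta(x_i,x_k)/tau}
                                        + e^{theta(x_i,y_k)/tau} ) ) ]

and each side of the loss is the *negated* mean of ``l`` (a positive
penalty).  The classification term is plain binary cross-entropy on decoder
scores, and the total is ``classify + lambda * contrast``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor

__all__ = [
    "EmbeddingViews",
    "LossConfig",
    "pairwise_cosine",
    "contrastive_loss_one_side",
    "contrastive_total",
    "bce_loss",
    "total_loss",
]


@dataclass
class LossConfig:
    """Temperature, contrastive weight, and numeric clipping floor."""

    tau: float = 1.0
    lam: float = 0.2
    eps: float = 1e-7

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if not (0 < self.eps <= 1e-3):
            raise ValueError("eps must lie in (0, 1e-3]")


@dataclass
class EmbeddingViews:
    """Microbe/disease embeddings from the association and similarity views."""

    ZA_m: Tensor
    ZS_m: Tensor
    ZA_d: Tensor
    ZS_d: Tensor

    def __post_init__(self) -> None:
        self.ZA_m = as_tensor(self.ZA_m)
        self.ZS_m = as_tensor(self.ZS_m)
        self.ZA_d = as_tensor(self.ZA_d)
        self.ZS_d = as_tensor(self.ZS_d)
        if self.ZA_m.shape != self.ZS_m.shape:
            raise ValueError("microbe views must have matching shapes")
        if self.ZA_d.shape != self.ZS_d.shape:
            raise ValueError("disease views must have matching shapes")


def _row_normalize(X: Tensor, eps: float) -> Tensor:
    norms = ((X * X).sum(axis=1, keepdims=True) + eps * eps).sqrt()
    return X / norms

def pairwise_cosine(X, Y, eps: float = 1e-8) -> Tensor:
    """theta_ij = cos(x_i, y_j); zero rows are eps-stabilized toward 0."""
    X, Y = as_tensor(X), as_tensor(Y)
    return _row_normalize(X, eps) @ _row_normalize(Y, eps).T


def contrastive_loss_one_side(ZX, ZY, tau: float = 1.0,
                              eps: float = 1e-8) -> Tensor:
    """Negated mean log-ratio with intra- and inter-view negatives.

    Returns exactly 0 for n = 1 (no negatives: numerator equals denominator).
    """
    ZX, ZY = as_tensor(ZX), as_tensor(ZY)
    if ZX.shape != ZY.shape:
        raise ValueError("view shapes must match")
    n = ZX.shape[0]
    E_xy = (pairwise_cosine(ZX, ZY, eps) * (1.0 / tau)).exp()
    E_xx = (pairwise_cosine(ZX, ZX, eps) * (1.0 / tau)).exp()
    numer = E_xy.diagonal()
    # denominator: positive pair + all k != i in both views
    denom = (
        E_xy.sum(axis=1) + E_xx.sum(axis=1) - E_xx.diagonal()
    )
    losses = denom.log() - numer.log()
    return losses.mean()


def contrastive_total(views: EmbeddingViews, cfg: LossConfig) -> Tensor:
    """Symmetrized microbe-side plus disease-side contrastive loss."""
    loss_d = (
        contrastive_loss_one_side(views.ZA_d, views.ZS_d, cfg.tau)
        + contrastive_loss_one_side(views.ZS_d, views.ZA_d, cfg.tau)
    ) * 0.5
    loss_m = (
        contrastive_loss_one_side(views.ZA_m, views.ZS_m, cfg.tau)
        + contrastive_loss_one_side(views.ZS_m, views.ZA_m, cfg.tau)
    ) * 0.5
    return loss_d + loss_m


def bce_loss(scores, labels, eps: float = 1e-7) -> Tensor:
    """Binary cross-entropy with scores clipped to [eps, 1 - eps]."""
    scores = as_tensor(scores)
    labels = np.asarray(labels, dtype=np.float64).ravel()
    if scores.data.size != labels.size:
        raise ValueError("scores and labels must have equal length")
    if labels.size == 0:
        raise ValueError("need at least one labeled pair")
    if not np.isin(labels, (0.0, 1.0)).all():
        raise ValueError("labels must be 0 or 1")
    s = scores.clip(eps, 1.0 - eps)
    ll = as_tensor(labels) * s.log() + as_tensor(1.0 - labels) * (1.0 - s).log()
    return -ll.mean()


def total_loss(classify, contrast, lam: float):
    """Weighted sum classify + lam * contrast."""
    return classify + as_tensor(contrast) * lam
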