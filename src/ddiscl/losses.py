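"""The three-level training objective.

Training optimises the unweighted sum of three terms:

* a reconstruction term — per-drug mean squared error between the input
  similarity profile and the autoencoder's reconstruction, normalised by
  the feature dimensionality;
* a supervised contrastive term over the batch of pair embeddings (CFVs):
  for each anchor i with at least one same-class batchmate,

      l_i = -1/(N_yi - 1) * sum_{j != i, y_j = y_i}
              log[ exp(sim(CFV_i, CFV_j)/tau) / sum_{k != i} exp(sim(CFV_i, CFV_k)/tau) ]

  with sim = cosine similarity and temperature tau; the batch loss is the
  sum of the l_i divided by the batch size. Anchors whose class occurs only
  once in the batch contribute zero (the coefficient would divide by zero);
* a classification term: label-smoothed cross-entropy for the first part of
  training, switching to focal loss -(1-p_t)^gamma * log p_t once training
  reaches ``switch_epoch``, to re-weight learning toward rare, hard DDI
  types.

All loss functions accept plain arrays or autodiff tensors and return a
:class:`~ddiscl._autograd.Tensor`, so the same code path serves both unit
tests (via ``float(loss)``) and backpropagation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor, as_tensor, log_softmax

__all__ = [
    "LossBundle",
    "ContrastiveConfig",
    "ClassificationLossConfig",
    "mse_loss",
    "supervised_contrastive_loss",
    "smoothed_cross_entropy",
    "focal_loss",
    "select_classification_loss",
    "total_loss",
    "TrainingDivergenceError",
]


class TrainingDivergenceError(RuntimeError):
    """A loss component became non-finite."""


@dataclass(frozen=True)
class LossBundle:
    """Per-step loss components and their unweighted sum."""

    l_mse: float
    l_con: float
    l_cla: float
    total: float

    @staticmethod
    def from_components(l_mse: float, l_con: float, l_cla: float) -> "LossBundle":
        return total_loss(l_mse, l_con, l_cla)


@dataclass(frozen=True)
class ContrastiveConfig:
    temperature: float = 0.05
    similarity: str = "cosine"

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.similarity != "cosine":
            raise ValueError("only cosine similarity is implemented")


@dataclass(frozen=True)
class ClassificationLossConfig:
    smoothing: float = 0.3
    focal_gamma: float = 2.0
    switch_epoch: int = 40
    total_epochs: int = 120

    def __post_init__(self):
        if not 0.0 <= self.smoothing < 1.0:
            raise ValueError("smoothing must be in [0, 1)")
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be non-negative")
        if not 0 <= self.switch_epoch <= self.total_epochs:
            raise ValueError("need 0 <= switch_epoch <= total_epochs")


def mse_loss(x, x_recon) -> Tensor:
    """Sum of squared reconstruction errors divided by the feature
    dimensionality; for batched input, the mean over rows."""
    x, x_recon = as_tensor(x), as_tensor(x_recon)
    if x.shape != x_recon.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_recon.shape}")
    fea_dim = x.shape[-1]
    per = ((x - x_recon) ** 2.0).sum(axis=-1) * (1.0 / fea_dim)
    return per.mean() if per.ndim > 0 else per


def supervised_contrastive_loss(cfvs, labels, cfg: ContrastiveConfig | None = None) -> Tensor:
    """Supervised contrastive loss over a batch of pair embeddings.

    ``cfvs``: (N, d) embeddings; ``labels``: N integer class ids. Requires
    N >= 2 and non-zero rows (cosine similarity is undefined at zero).
    """
    cfg = cfg or ContrastiveConfig()
    cfvs = as_tensor(cfvs)
    labels = np.asarray(labels)
    if cfvs.ndim != 2:
        raise ValueError("cfvs must be a (N, d) batch")
    n = cfvs.shape[0]
    if n < 2:
        raise ValueError("contrastive loss needs a batch of at least 2")
    if labels.shape != (n,):
        raise ValueError("labels must have one entry per embedding")
    norms_sq = (cfvs ** 2.0).sum(axis=1, keepdims=True)
    if (norms_sq.data <= 0).any():
        raise ValueError("zero embedding vector: cosine similarity undefined")
    unit = cfvs * norms_sq ** -0.5
    logits = (unit @ unit.T) * (1.0 / cfg.temperature)  # (N, N) scaled cosines

    same = labels[:, None] == labels[None, :]
    eye = np.eye(n, dtype=bool)
    pos_mask = same & ~eye
    n_pos = pos_mask.sum(axis=1)  # N_yi - 1 per anchor

    # exclude k == i from every denominator via a large negative constant
    neg_inf = Tensor(np.where(eye, -1e30, 0.0))
    log_prob = log_softmax(logits + neg_inf, axis=1)

    anchors = n_pos > 0  # singleton-class anchors contribute 0
    if not anchors.any():
        return (cfvs * 0.0).sum()  # keeps the graph connected; value 0
    coeff = np.zeros((n, n))
    coeff[anchors] = pos_mask[anchors] / n_pos[anchors, None]
    per_anchor = (log_prob * Tensor(coeff)).sum(axis=1)
    return per_anchor.sum() * (-1.0 / n)


def _as_logit_batch(logits, labels):
    logits = as_tensor(logits)
    squeeze = logits.ndim == 1
    if squeeze:
        logits = logits.reshape(1, -1)
    labels = np.atleast_1d(np.asarray(labels, dtype=np.intp))
    n, c = logits.shape
    if labels.shape != (n,):
        raise ValueError("labels must have one entry per logit row")
    if (labels < 0).any() or (labels >= c).any():
        raise ValueError(f"label out of range [0, {c})")
    return logits, labels


def smoothed_cross_entropy(logits, labels, smoothing: float = 0.3,
                           n_classes: int | None = None) -> Tensor:
    """Cross-entropy against targets (1-eps)*onehot + eps/K (uniform over
    all K classes, the true class included)."""
    if not 0.0 <= smoothing < 1.0:
        raise ValueError("smoothing must be in [0, 1)")
    logits, labels = _as_logit_batch(logits, labels)
    n, c = logits.shape
    if n_classes is not None and n_classes != c:
        raise ValueError(f"logits have {c} columns, expected {n_classes}")
    target = np.full((n, c), smoothing / c)
    target[np.arange(n), labels] += 1.0 - smoothing
    lp = log_softmax(logits, axis=1)
    return (lp * Tensor(target)).sum(axis=1).mean() * -1.0


def focal_loss(logits, labels, gamma: float = 2.0) -> Tensor:
    """Multi-class focal loss -(1-p_t)^gamma * log(p_t), no class weights.

    gamma = 0 recovers plain (unsmoothed) cross-entropy; gamma > 0
    down-weights well-classified samples.
    """
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    logits, labels = _as_logit_batch(logits, labels)
    lp_t = log_softmax(logits, axis=1).gather_rows(labels)
    if gamma == 0.0:
        return lp_t.mean() * -1.0
    p_t = lp_t.exp()
    return ((1.0 - p_t) ** gamma * lp_t).mean() * -1.0


def select_classification_loss(epoch: int, cfg: ClassificationLossConfig) -> str:
    """Which classification loss is active at ``epoch``: cross-entropy
    before the switch epoch, focal from it onward."""
    if not 0 <= epoch < cfg.total_epochs:
        raise ValueError(
            f"epoch {epoch} out of range [0, {cfg.total_epochs})"
        )
    return "cross_entropy" if epoch < cfg.switch_epoch else "focal"


def total_loss(l_mse: float, l_con: float, l_cla: float) -> LossBundle:
    """Unweighted sum of the three components, kept separately for logging."""
    comps = {"l_mse": float(l_mse), "l_con": float(l_con), "l_cla": float(l_cla)}
    bad = [k for k, v in comps.items() if not math.isfinite(v)]
    if bad:
        raise TrainingDivergenceError(
            f"non-finite loss component(s): {', '.join(bad)}"
        )
    return LossBundle(total=sum(comps.values()), **comps)
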