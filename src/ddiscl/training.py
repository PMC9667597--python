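"""Training loop and prediction: profiles -> pair network -> three-level loss.

Defaults follow the published training recipe for the full-size benchmark
runs: learning rate 2e-5, batch size 512, 120 epochs, label smoothing 0.3,
temperature 0.05, switch from cross-entropy to focal loss at epoch 40,
RAdam optimizer. Desk-scale experiments on synthetic data use shorter,
larger-step schedules (see ``toy_train_config``).

Per batch the loop computes the reconstruction MSE (averaged over the two
drugs of each pair), the supervised contrastive loss over the batch CFVs,
and the scheduled classification loss, backpropagates their unweighted sum
jointly, and steps RAdam. All randomness (shuffles, init, dropout) derives
from the run seed; with single-threaded numpy the run is reproducible
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from ._autograd import RAdam, Tensor
from .features import SimilarityProfile
from .losses import (
    ClassificationLossConfig,
    ContrastiveConfig,
    LossBundle,
    TrainingDivergenceError,
    focal_loss,
    mse_loss,
    select_classification_loss,
    smoothed_cross_entropy,
    supervised_contrastive_loss,
    total_loss,
)
from .network import DDIPairNet, NetworkConfig, default_network_config

__all__ = [
    "TrainConfig",
    "TrainingHistory",
    "TrainedModel",
    "train",
    "predict",
    "pair_embeddings",
    "toy_train_config",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 2e-5
    batch_size: int = 512
    epochs: int = 120
    smoothing: float = 0.3
    temperature: float = 0.05
    switch_epoch: int = 40
    focal_gamma: float = 2.0
    optimizer: str = "radam"
    seed: int = 0
    use_scl: bool = True
    use_focal: bool = True
    use_label_smoothing: bool = True
    fusion_mode: str = "multi_scale"

    def __post_init__(self):
        # coerce numeric fields so YAML-sourced strings like "1e-3" are accepted
        for name, cast in (
            ("learning_rate", float), ("smoothing", float), ("temperature", float),
            ("focal_gamma", float), ("batch_size", int), ("epochs", int),
            ("switch_epoch", int), ("seed", int),
        ):
            try:
                object.__setattr__(self, name, cast(getattr(self, name)))
            except (TypeError, ValueError) as err:
                raise ValueError(f"{name} must be numeric: {err}") from err
        if min(self.learning_rate, self.batch_size, self.epochs) <= 0:
            raise ValueError("learning_rate, batch_size and epochs must be positive")
        if self.switch_epoch > self.epochs:
            raise ValueError("switch_epoch must not exceed epochs")
        if self.optimizer != "radam":
            raise ValueError("only the radam optimizer is implemented")

    def classification_cfg(self) -> ClassificationLossConfig:
        return ClassificationLossConfig(
            smoothing=self.smoothing,
            focal_gamma=self.focal_gamma,
            switch_epoch=self.switch_epoch if self.use_focal else self.epochs,
            total_epochs=self.epochs,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def toy_train_config(**overrides) -> TrainConfig:
    """A schedule sized for small synthetic runs: a freshly initialised net
    needs larger steps than the full-size recipe when an epoch is only a
    handful of batches."""
    defaults = dict(
        learning_rate=2e-3, batch_size=32, epochs=30, switch_epoch=10
    )
    defaults.update(overrides)
    return TrainConfig(**defaults)


@dataclass
class HistoryRow:
    epoch: int
    l_mse: float
    l_con: float
    l_cla: float
    total: float
    active_cla_loss: str


@dataclass
class TrainingHistory:
    rows: list[HistoryRow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([asdict(r) for r in self.rows])


@dataclass
class TrainedModel:
    """A fitted network plus everything needed to reuse it: the two configs
    and the feature-type order its profiles were built with."""

    net: DDIPairNet
    net_cfg: NetworkConfig
    train_cfg: TrainConfig
    feature_types: list[str]

    def save(self, path) -> None:
        import json
        import os

        os.makedirs(os.path.dirname(str(path)) or ".", exist_ok=True)
        meta = {
            "network": self.net_cfg.to_dict(),
            "training": self.train_cfg.to_dict(),
            "feature_types": self.feature_types,
        }
        arrays = self.net.state_arrays()
        np.savez(str(path), __meta__=json.dumps(meta), **arrays)

    @staticmethod
    def load(path) -> "TrainedModel":
        import json

        with np.load(str(path), allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            arrays = {k: data[k] for k in data.files if k != "__meta__"}
        net_cfg = NetworkConfig(**meta["network"])
        train_cfg = TrainConfig(**meta["training"])
        net = DDIPairNet(net_cfg, fusion_mode=train_cfg.fusion_mode)
        net.load_state_arrays(arrays)
        return TrainedModel(
            net=net, net_cfg=net_cfg, train_cfg=train_cfg,
            feature_types=meta["feature_types"],
        )


def _gather_pairs(profiles: SimilarityProfile, records):
    a_ids = [r[0] for r in records]
    b_ids = [r[1] for r in records]
    return profiles.vectors(a_ids), profiles.vectors(b_ids)


def train(
    profiles: SimilarityProfile,
    records: list[tuple[str, str, int]],
    cfg: TrainConfig,
    net_cfg: NetworkConfig | None = None,
    n_classes: int | None = None,
) -> tuple[TrainedModel, TrainingHistory]:
    """Fit the pair network on (drugA, drugB, label) records.

    ``net_cfg`` defaults to :func:`default_network_config` for the profile
    geometry; ``n_classes`` is then required (it cannot always be inferred
    from the training labels when a fold lacks a class).
    """
    if not records:
        raise ValueError("empty training set")
    labels_all = np.array([r[2] for r in records], dtype=np.intp)
    if net_cfg is None:
        if n_classes is None:
            n_classes = int(labels_all.max()) + 1
        net_cfg = default_network_config(
            profiles.fea_dim, n_classes,
            n_feature_types=len(profiles.feature_types),
            seed=cfg.seed,
        )
    if labels_all.max() >= net_cfg.n_classes or labels_all.min() < 0:
        raise ValueError("training labels exceed configured class count")

    work = list(records)
    if net_cfg.symmetrize_pairs:
        work = work + [(b, a, y) for a, b, y in records]
    xa_all, xb_all = _gather_pairs(profiles, work)
    y_all = np.array([r[2] for r in work], dtype=np.intp)

    net = DDIPairNet(net_cfg, fusion_mode=cfg.fusion_mode)
    net.train(True)
    opt = RAdam(net.parameters(), lr=cfg.learning_rate)
    cla_cfg = cfg.classification_cfg()
    scl_cfg = ContrastiveConfig(temperature=cfg.temperature)
    shuffle_rng = np.random.default_rng(
        np.random.SeedSequence(cfg.seed).spawn(2)[1]
    )

    history = TrainingHistory()
    n = len(work)
    for epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(n)
        active = select_classification_loss(epoch, cla_cfg)
        sums = np.zeros(3)
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xa, xb, y = xa_all[idx], xb_all[idx], y_all[idx]
            ea, eb, latents, logits = net.forward_pair(xa, xb)
            l_mse = (mse_loss(Tensor(xa), ea.recon)
                     + mse_loss(Tensor(xb), eb.recon)) * 0.5
            if cfg.use_scl and len(idx) >= 2:
                l_con = supervised_contrastive_loss(latents.cfv, y, scl_cfg)
            else:
                l_con = Tensor(0.0)
            if active == "cross_entropy":
                eps = cfg.smoothing if cfg.use_label_smoothing else 0.0
                l_cla = smoothed_cross_entropy(logits, y, smoothing=eps)
            else:
                l_cla = focal_loss(logits, y, gamma=cfg.focal_gamma)
            bundle = total_loss(float(l_mse), float(l_con), float(l_cla))

            loss = l_mse + l_con + l_cla
            opt.zero_grad()
            loss.backward()
            opt.step()
            sums += (bundle.l_mse, bundle.l_con, bundle.l_cla)
            n_batches += 1
        means = sums / n_batches
        history.rows.append(
            HistoryRow(
                epoch=epoch,
                l_mse=float(means[0]),
                l_con=float(means[1]),
                l_cla=float(means[2]),
                total=float(means.sum()),
                active_cla_loss=active,
            )
        )
    model = TrainedModel(
        net=net, net_cfg=net_cfg, train_cfg=cfg,
        feature_types=list(profiles.feature_types),
    )
    return model, history


def predict(
    model: TrainedModel,
    profiles: SimilarityProfile,
    pairs: list[tuple[str, str]],
    batch_size: int = 512,
) -> np.ndarray:
    """Softmax class probabilities for drug pairs, in evaluation mode.

    With ``symmetrize_pairs`` on, the two pair orders are averaged, making
    the prediction order-invariant.
    """
    missing = sorted(
        {d for p in pairs for d in p[:2] if d not in profiles._index}
    )
    if missing:
        raise KeyError(f"pairs reference drugs without profiles: {missing}")
    model.net.eval()
    out = np.empty((len(pairs), model.net_cfg.n_classes))
    for start in range(0, len(pairs), batch_size):
        chunk = pairs[start:start + batch_size]
        xa, xb = _gather_pairs(profiles, chunk)
        probs = model.net.predict_proba(xa, xb)
        if model.net_cfg.symmetrize_pairs:
            probs = 0.5 * (probs + model.net.predict_proba(xb, xa))
        out[start:start + len(chunk)] = probs
    return out


def pair_embeddings(
    model: TrainedModel,
    profiles: SimilarityProfile,
    pairs: list[tuple[str, str]],
    batch_size: int = 512,
) -> np.ndarray:
    """The CFV embeddings of drug pairs in evaluation mode (the vectors the
    contrastive loss shapes)."""
    model.net.eval()
    chunks = []
    for start in range(0, len(pairs), batch_size):
        chunk = pairs[start:start + batch_size]
        xa, xb = _gather_pairs(profiles, chunk)
        _, _, latents, _ = model.net.forward_pair(xa, xb)
        chunks.append(latents.cfv.data.copy())
    return np.concatenate(chunks, axis=0)
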