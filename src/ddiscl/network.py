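"""Drug-pair network: per-drug attention+autoencoder encoder, multi-scale
pair fusion, attention-guided latent reduction to a common feature vector
(CFV), and a two-layer classifier head.

The model consumes per-drug Jaccard similarity profiles (see
:mod:`ddiscl.features`). Each drug is encoded independently:

* the profile is reshaped into ``n_tokens`` equal-width tokens (by default
  one token per feature-type block) and passed through multi-head
  self-attention with a residual connection — flattened, this is ``DA1``;
* a two-layer autoencoder compresses ``DA1`` to ``DA2`` (width ``h1``) and
  ``DA3`` (width ``h2``), and a mirrored decoder reconstructs the profile
  for the reconstruction loss.

For a pair (A, B) the multi-scale fusion concatenates features across
depths — (DA1, DB3), (DA2, DB2), (DA3, DB1) — and projects each through its
own fully connected layer to fused features FD1..FD3. The latent reduction
sub-module concatenates (DA3, DB3, FD1, FD2, FD3), applies multi-head
self-attention treating the five constituent vectors as tokens, and then a
pyramid of halving linear layers (GELU, dropout, batch-norm) producing the
CFV, on which both the supervised contrastive loss and the classifier
operate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from ._autograd import (
    BatchNorm1d,
    Dropout,
    Linear,
    Module,
    MultiHeadSelfAttention,
    Tensor,
    as_tensor,
    concatenate,
    gelu,
    log_softmax,
)

__all__ = [
    "NetworkConfig",
    "EncoderOutput",
    "PairLatents",
    "DDIPairNet",
    "default_network_config",
]

FUSION_MODES = ("multi_scale", "single_scale", "none")


class InvalidConfigError(ValueError):
    """A NetworkConfig violates a shape-divisibility constraint."""


@dataclass
class NetworkConfig:
    """Shape and regularisation settings of the pair network.

    ``fea_dim`` must split into ``n_tokens`` equal tokens and each token
    into ``n_heads`` heads. The latent-reduction attention runs over the
    five width-``h2`` constituents of its input, hence ``f == h2`` and
    ``h2`` divisible by ``reduce_n_heads``; the reduction pyramid halves
    widths ``n_reduce_layers`` times, so ``5*h2`` must be divisible by
    ``2**n_reduce_layers``.
    """

    fea_dim: int
    n_classes: int
    n_tokens: int = 4
    n_heads: int = 4
    h1: int = 0  # 0 -> derived in __post_init__
    h2: int = 0
    f: int = 0
    n_reduce_layers: int = 2
    reduce_n_heads: int = 4
    n_attention_layers: int = 1
    dropout_rate: float = 0.3
    symmetrize_pairs: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.h2 == 0:
            # halving pyramid rounded so all divisibility constraints hold
            base = max(self.reduce_n_heads, 2 ** self.n_reduce_layers)
            self.h2 = max(base, (self.fea_dim // 4 // base) * base)
        if self.h1 == 0:
            self.h1 = 2 * self.h2
        if self.f == 0:
            self.f = self.h2
        self.validate()

    def validate(self) -> None:
        if self.n_classes < 2:
            raise InvalidConfigError("n_classes must be >= 2")
        if self.fea_dim % self.n_tokens != 0:
            raise InvalidConfigError(
                f"fea_dim {self.fea_dim} not divisible by n_tokens {self.n_tokens}"
            )
        d_tok = self.fea_dim // self.n_tokens
        if d_tok % self.n_heads != 0:
            raise InvalidConfigError(
                f"token width {d_tok} not divisible by n_heads {self.n_heads}"
            )
        if not (self.h2 < self.h1 < self.fea_dim):
            raise InvalidConfigError("encoder widths must satisfy h2 < h1 < fea_dim")
        if self.f != self.h2:
            raise InvalidConfigError("fusion width f must equal h2 (reduction tokens)")
        if (5 * self.h2) % (2 ** self.n_reduce_layers) != 0:
            raise InvalidConfigError("5*h2 must be divisible by 2**n_reduce_layers")
        if self.h2 % self.reduce_n_heads != 0:
            raise InvalidConfigError("h2 must be divisible by reduce_n_heads")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise InvalidConfigError("dropout_rate must be in [0, 1)")

    @property
    def cfv_dim(self) -> int:
        return (5 * self.h2) // (2 ** self.n_reduce_layers)

    def to_dict(self) -> dict:
        return asdict(self)


def default_network_config(fea_dim: int, n_classes: int, n_feature_types: int = 4,
                           **overrides) -> NetworkConfig:
    """A valid config for a given profile width: one attention token per
    feature-type block, heads chosen as the largest value <= 4 dividing the
    token width."""
    n_tokens = overrides.pop("n_tokens", n_feature_types)
    d_tok = fea_dim // n_tokens
    n_heads = overrides.pop(
        "n_heads", next(h for h in (4, 3, 2, 1) if d_tok % h == 0)
    )
    return NetworkConfig(
        fea_dim=fea_dim, n_classes=n_classes, n_tokens=n_tokens,
        n_heads=n_heads, **overrides,
    )


@dataclass
class EncoderOutput:
    """Per-drug latents: DA1 (post-attention, width fea_dim), DA2 (width h1),
    DA3 (width h2) and the decoder reconstruction."""

    da1: Tensor
    da2: Tensor
    da3: Tensor
    recon: Tensor


@dataclass
class PairLatents:
    """Fused pair features and the final pair embedding."""

    fd1: Tensor
    fd2: Tensor
    fd3: Tensor
    cfv: Tensor


class DrugEncoder(Module):
    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        d_tok = cfg.fea_dim // cfg.n_tokens
        self.attn_layers = [
            self.add_module(f"attn{i}", MultiHeadSelfAttention(d_tok, cfg.n_heads, rng))
            for i in range(cfg.n_attention_layers)
        ]
        self.enc1 = self.add_module("enc1", Linear(cfg.fea_dim, cfg.h1, rng))
        self.enc2 = self.add_module("enc2", Linear(cfg.h1, cfg.h2, rng))
        self.dec1 = self.add_module("dec1", Linear(cfg.h2, cfg.h1, rng))
        self.dec2 = self.add_module("dec2", Linear(cfg.h1, cfg.fea_dim, rng))

    def __call__(self, x: Tensor) -> EncoderOutput:
        cfg = self.cfg
        if x.ndim != 2 or x.shape[1] != cfg.fea_dim:
            raise ValueError(
                f"expected (batch, {cfg.fea_dim}) input, got {x.shape}"
            )
        b = x.shape[0]
        tokens = x.reshape(b, cfg.n_tokens, cfg.fea_dim // cfg.n_tokens)
        for attn in self.attn_layers:
            tokens = tokens + attn(tokens)  # residual
        da1 = tokens.reshape(b, cfg.fea_dim)
        da2 = gelu(self.enc1(da1))
        da3 = gelu(self.enc2(da2))
        recon = self.dec2(gelu(self.dec1(da3)))
        return EncoderOutput(da1=da1, da2=da2, da3=da3, recon=recon)


class PairFusion(Module):
    """Projects depth-crossed concatenations of the two drugs' latents to a
    common width f. ``multi_scale`` pairs (1,3), (2,2), (3,1); the
    ``single_scale`` ablation pairs (1,1), (2,2), (3,3)."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator, mode: str):
        super().__init__()
        if mode not in ("multi_scale", "single_scale"):
            raise InvalidConfigError(f"unknown fusion mode {mode!r}")
        self.mode = mode
        widths = {
            "multi_scale": (cfg.fea_dim + cfg.h2, cfg.h1 + cfg.h1, cfg.h2 + cfg.fea_dim),
            "single_scale": (2 * cfg.fea_dim, 2 * cfg.h1, 2 * cfg.h2),
        }[mode]
        self.fc = [
            self.add_module(f"fc{i}", Linear(w, cfg.f, rng))
            for i, w in enumerate(widths)
        ]

    def __call__(self, ea: EncoderOutput, eb: EncoderOutput):
        if self.mode == "multi_scale":
            pairs = ((ea.da1, eb.da3), (ea.da2, eb.da2), (ea.da3, eb.da1))
        else:
            pairs = ((ea.da1, eb.da1), (ea.da2, eb.da2), (ea.da3, eb.da3))
        return tuple(
            gelu(fc(concatenate([u, v], axis=-1)))
            for fc, (u, v) in zip(self.fc, pairs)
        )


class LatentReduction(Module):
    """Self-attention over the token stack followed by a halving pyramid of
    (linear, GELU, dropout, batch-norm) layers."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator,
                 dropout_rng: np.random.Generator, n_tokens: int):
        super().__init__()
        self.cfg = cfg
        self.n_tokens = n_tokens
        self.attn = self.add_module(
            "attn", MultiHeadSelfAttention(cfg.h2, cfg.reduce_n_heads, rng)
        )
        width = n_tokens * cfg.h2
        if width % (2 ** cfg.n_reduce_layers) != 0:
            raise InvalidConfigError(
                f"reduction input width {width} not divisible by 2^{cfg.n_reduce_layers}"
            )
        self.layers = []
        for i in range(cfg.n_reduce_layers):
            lin = self.add_module(f"lin{i}", Linear(width, width // 2, rng))
            bn = self.add_module(f"bn{i}", BatchNorm1d(width // 2))
            drop = self.add_module(f"drop{i}", Dropout(cfg.dropout_rate, dropout_rng))
            self.layers.append((lin, drop, bn))
            width //= 2
        self.out_dim = width

    def __call__(self, parts: list[Tensor]) -> Tensor:
        b = parts[0].shape[0]
        stack = concatenate([p.reshape(b, 1, self.cfg.h2) for p in parts], axis=1)
        stack = stack + self.attn(stack)
        x = stack.reshape(b, self.n_tokens * self.cfg.h2)
        for lin, drop, bn in self.layers:
            x = bn(drop(gelu(lin(x))))
        return x


class Classifier(Module):
    """Two fully connected layers; the second has one neuron per DDI type."""

    def __init__(self, cfg: NetworkConfig, in_dim: int, rng: np.random.Generator,
                 dropout_rng: np.random.Generator):
        super().__init__()
        self.fc1 = self.add_module("fc1", Linear(in_dim, in_dim, rng))
        self.drop = self.add_module("drop", Dropout(cfg.dropout_rate, dropout_rng))
        self.bn = self.add_module("bn", BatchNorm1d(in_dim))
        self.fc2 = self.add_module("fc2", Linear(in_dim, cfg.n_classes, rng))

    def __call__(self, cfv: Tensor) -> Tensor:
        return self.fc2(self.bn(self.drop(gelu(self.fc1(cfv)))))


class DDIPairNet(Module):
    """The full pair network. ``forward_pair`` returns everything the three
    losses need: per-drug encoder outputs, pair latents, and class logits."""

    def __init__(self, cfg: NetworkConfig, fusion_mode: str = "multi_scale"):
        super().__init__()
        if fusion_mode not in FUSION_MODES:
            raise InvalidConfigError(f"unknown fusion mode {fusion_mode!r}")
        cfg.validate()
        self.cfg = cfg
        self.fusion_mode = fusion_mode
        rng = np.random.default_rng(cfg.seed)
        # separate stream for dropout masks so init is mask-independent
        self.dropout_rng = np.random.default_rng(
            np.random.SeedSequence(cfg.seed).spawn(1)[0]
        )
        self.encoder = self.add_module("encoder", DrugEncoder(cfg, rng))
        if fusion_mode != "none":
            self.fusion = self.add_module("fusion", PairFusion(cfg, rng, fusion_mode))
            n_tok = 5
        else:
            self.fusion = None
            n_tok = 2
        self.reduce = self.add_module(
            "reduce", LatentReduction(cfg, rng, self.dropout_rng, n_tok)
        )
        self.classifier = self.add_module(
            "classifier", Classifier(cfg, self.reduce.out_dim, rng, self.dropout_rng)
        )

    # ----------------------------------------------------------------- pieces
    def encode_drug(self, x) -> EncoderOutput:
        return self.encoder(as_tensor(x))

    def fuse_pair(self, ea: EncoderOutput, eb: EncoderOutput):
        if self.fusion is None:
            raise InvalidConfigError("fusion disabled (fusion_mode='none')")
        return self.fusion(ea, eb)

    def reduce_latent(self, ea: EncoderOutput, eb: EncoderOutput, fds) -> Tensor:
        parts = [ea.da3, eb.da3, *fds] if fds else [ea.da3, eb.da3]
        return self.reduce(parts)

    def classify(self, cfv: Tensor) -> Tensor:
        return self.classifier(cfv)

    # ------------------------------------------------------------------ whole
    def forward_pair(self, xa, xb):
        xa, xb = as_tensor(xa), as_tensor(xb)
        ea = self.encode_drug(xa)
        eb = self.encode_drug(xb)
        fds = self.fuse_pair(ea, eb) if self.fusion is not None else ()
        cfv = self.reduce_latent(ea, eb, fds)
        logits = self.classify(cfv)
        latents = PairLatents(
            fd1=fds[0] if fds else None,
            fd2=fds[1] if fds else None,
            fd3=fds[2] if fds else None,
            cfv=cfv,
        )
        return ea, eb, latents, logits

    def predict_proba(self, xa, xb) -> np.ndarray:
        """Softmax class probabilities in evaluation mode."""
        was_training = self.training
        self.eval()
        try:
            _, _, _, logits = self.forward_pair(xa, xb)
            probs = np.exp(log_softmax(logits, axis=-1).data)
        finally:
            self.train(was_training)
        return probs
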