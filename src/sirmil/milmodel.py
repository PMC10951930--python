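"""MIL model: encoder, squeeze-excitation, attention pooling, bag classifier.

Two aggregation strategies over a bag of tile embeddings h_1..h_k:

* ``max_pool`` — a single linear layer scores each tile and the bag takes
  the maximum per-tile probability;
* ``gated_attention`` — attention weights
  ``a = softmax_k( w^T (tanh(V h_k) * sigmoid(U h_k)) )`` combine tile
  features into one bag feature ``z = sum_k a_k h_k`` which a linear layer
  turns into the bag probability.

Both are permutation-invariant in the tiles, which is the core MIL symmetry.
Backbones: ``tiny_cnn`` (3 conv blocks + squeeze-excitation + global average
pool, d=64, fast on CPU — the reference encoder for tests and scaled
experiments), and the residual-18 family (``resnet18``, ``se_resnet18``,
d=512) built from the same layer library.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import Module, Parameter, sigmoid

__all__ = [
    "BACKBONES",
    "AGGREGATIONS",
    "AttentionParams",
    "BagOutput",
    "squeeze_excite",
    "gated_attention",
    "max_pool_aggregate",
    "classify_bag",
    "GatedAttention",
    "MILModel",
    "save_checkpoint",
    "load_checkpoint",
]

BACKBONES = ("tiny_cnn", "resnet18", "se_resnet18")
AGGREGATIONS = ("max_pool", "gated_attention")


# ---------------------------------------------------------------------------
# functional ops
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AttentionParams:
    """Gated-attention weights: V, U are (L, d); w is (L,)."""

    V: np.ndarray
    U: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        V, U, w = map(np.asarray, (self.V, self.U, self.w))
        if V.shape != U.shape or w.shape != (V.shape[0],):
            raise ValueError("inconsistent attention parameter shapes")
        if not (np.isfinite(V).all() and np.isfinite(U).all() and np.isfinite(w).all()):
            raise ValueError("attention parameters must be finite")


@dataclass(frozen=True)
class BagOutput:
    """Result of one bag-level inference pass."""

    probability: float
    attention: np.ndarray | None = None          # (k,) for gated attention
    bag_feature: np.ndarray | None = None        # (d,) for gated attention
    per_tile_probabilities: np.ndarray | None = None  # (k,) for max_pool


def squeeze_excite(feature_map: np.ndarray, W1: np.ndarray, W2: np.ndarray) -> np.ndarray:
    """Functional squeeze-excitation on one (C, H, W) feature map.

    ``s = sigmoid(W2 @ relu(W1 @ gap(x)))`` rescales each channel; W1 is
    (C/reduction, C) and W2 is (C, C/reduction).
    """
    x = np.asarray(feature_map, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError("expected a (C, H, W) feature map")
    c = x.shape[0]
    if W1.shape[1] != c or W2.shape[0] != c or W1.shape[0] != W2.shape[1]:
        raise ValueError("squeeze-excitation weight shapes do not match the input")
    g = x.mean(axis=(1, 2))
    s = sigmoid(W2 @ np.maximum(W1 @ g, 0.0))
    return x * s[:, None, None]


def _softmax(scores: np.ndarray) -> np.ndarray:
    e = np.exp(scores - scores.max())
    return e / e.sum()


def gated_attention(H: np.ndarray, params: AttentionParams) -> tuple[np.ndarray, np.ndarray]:
    """Attention weights and bag feature for a (k, d) tile-feature matrix."""
    H = np.asarray(H, dtype=np.float64)
    if H.ndim != 2 or H.shape[0] < 1:
        raise ValueError("H must be a (k, d) matrix with k >= 1")
    if not np.isfinite(H).all():
        raise ValueError("tile features must be finite")
    t = np.tanh(H @ params.V.T)          # (k, L)
    s = sigmoid(H @ params.U.T)          # (k, L)
    scores = (t * s) @ params.w          # (k,)
    a = _softmax(scores)
    z = a @ H
    return a, z


def max_pool_aggregate(per_tile_probabilities: np.ndarray) -> float:
    """One-wins-all over per-tile probabilities."""
    p = np.asarray(per_tile_probabilities, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty probability vector")
    if p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("probabilities must lie in [0, 1]")
    return float(p.max())


def classify_bag(z: np.ndarray, w_c: np.ndarray, b_c: float) -> float:
    """Linear bag classifier: p = sigmoid(w_c . z + b_c)."""
    z = np.asarray(z, dtype=np.float64)
    w_c = np.asarray(w_c, dtype=np.float64)
    if z.shape != w_c.shape:
        raise ValueError("z and w_c must have the same dimension")
    return float(sigmoid(np.array([z @ w_c + b_c]))[0])


# ---------------------------------------------------------------------------
# trainable modules
# ---------------------------------------------------------------------------

class GatedAttention(Module):
    """Trainable gated-attention pooling (no bias terms)."""

    def __init__(self, d: int, L: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(1.0 / d)
        self.V = self.register_parameter("V", Parameter(rng.normal(0, scale, size=(L, d))))
        self.U = self.register_parameter("U", Parameter(rng.normal(0, scale, size=(L, d))))
        self.w = self.register_parameter("w", Parameter(rng.normal(0, np.sqrt(1.0 / L), size=L)))

    def as_params(self) -> AttentionParams:
        return AttentionParams(V=self.V.value, U=self.U.value, w=self.w.value)

    def forward(self, H: np.ndarray):
        t = np.tanh(H @ self.V.value.T)
        s = sigmoid(H @ self.U.value.T)
        scores = (t * s) @ self.w.value
        a = _softmax(scores)
        z = a @ H
        self._cache = (H, t, s, a)
        return a, z

    def backward(self, dz: np.ndarray) -> np.ndarray:
        H, t, s, a = self._cache
        self._cache = None
        da = H @ dz                               # (k,)
        # softmax Jacobian
        de = a * (da - float(a @ da))             # (k,)
        gate = t * s                              # (k, L)
        self.w.grad += de @ gate
        common_v = de[:, None] * (self.w.value[None, :] * s * (1.0 - t**2))  # (k, L)
        common_u = de[:, None] * (self.w.value[None, :] * t * s * (1.0 - s))
        self.V.grad += common_v.T @ H
        self.U.grad += common_u.T @ H
        dH = a[:, None] * dz[None, :] + common_v @ self.V.value + common_u @ self.U.value
        return dH


def _build_tiny_cnn(rng: np.random.Generator, se_reduction: int) -> tuple[Module, int]:
    layers = nn.Sequential(
        nn.Conv2d(3, 16, 3, rng, stride=2, pad=1), nn.BatchNorm2d(16), nn.ReLU(),
        nn.Conv2d(16, 32, 3, rng, stride=2, pad=1), nn.BatchNorm2d(32), nn.ReLU(),
        nn.Conv2d(32, 64, 3, rng, stride=2, pad=1), nn.BatchNorm2d(64), nn.ReLU(),
        nn.SqueezeExcite(64, rng, reduction=se_reduction),
        nn.GlobalAvgPool2d(),
    )
    return layers, 64


def _build_resnet18(rng: np.random.Generator, se: bool, se_reduction: int) -> tuple[Module, int]:
    blocks: list[Module] = [
        nn.Conv2d(3, 64, 7, rng, stride=2, pad=3), nn.BatchNorm2d(64), nn.ReLU(),
        nn.MaxPool2d(3, 2, pad=1),
    ]
    in_ch = 64
    for out_ch, stride in ((64, 1), (128, 2), (256, 2), (512, 2)):
        blocks.append(nn.BasicBlock(in_ch, out_ch, rng, stride=stride, se=se, se_reduction=se_reduction))
        blocks.append(nn.BasicBlock(out_ch, out_ch, rng, stride=1, se=se, se_reduction=se_reduction))
        in_ch = out_ch
    blocks.append(nn.GlobalAvgPool2d())
    return nn.Sequential(*blocks), 512


class MILModel(Module):
    """Encoder + aggregation + bag classifier, trainable end to end.

    ``forward_batch`` runs the encoder over all tiles of a batch of bags in
    one pass and returns bag logits; ``backward_batch`` propagates the loss
    gradient back through aggregation and encoder, accumulating parameter
    gradients.
    """

    def __init__(
        self,
        backbone: str = "tiny_cnn",
        aggregation: str = "gated_attention",
        attention_dim: int = 128,
        se_reduction: int = 16,
        seed: int = 0,
        pretrained: bool = False,
    ):
        super().__init__()
        if backbone not in BACKBONES:
            raise ValueError(f"backbone must be one of {BACKBONES}")
        if aggregation not in AGGREGATIONS:
            raise ValueError(f"aggregation must be one of {AGGREGATIONS}")
        self.backbone = backbone
        self.aggregation = aggregation
        self.attention_dim = attention_dim
        self.se_reduction = se_reduction
        self.seed = seed
        self.pretrained = pretrained
        rng = np.random.default_rng(seed)
        if backbone == "tiny_cnn":
            encoder, d = _build_tiny_cnn(rng, se_reduction)
        else:
            encoder, d = _build_resnet18(rng, se=backbone == "se_resnet18", se_reduction=se_reduction)
        self.encoder = self.add_child("encoder", encoder)
        self.d = d
        if aggregation == "gated_attention":
            self.attention = self.add_child("attention", GatedAttention(d, attention_dim, rng))
        else:
            self.attention = None
        self.w_c = self.register_parameter("w_c", Parameter(rng.normal(0, np.sqrt(1.0 / d), size=d)))
        self.b_c = self.register_parameter("b_c", Parameter(np.zeros(1)))

    # -- parameter groups for the optimizer ---------------------------------
    def encoder_parameters(self) -> list[Parameter]:
        return self.encoder.parameters()

    def head_parameters(self) -> list[Parameter]:
        head = [self.w_c, self.b_c]
        if self.attention is not None:
            head = self.attention.parameters() + head
        return head

    # -- batched forward/backward -------------------------------------------
    def forward_batch(self, bag_arrays: list[np.ndarray]) -> tuple[np.ndarray, dict]:
        """Bag logits for a list of (k_i, 3, H, W) tile stacks."""
        sizes = [b.shape[0] for b in bag_arrays]
        tiles = np.concatenate(bag_arrays, axis=0)
        feats = self.encoder(tiles)                       # (sum k_i, d)
        logits = np.empty(len(bag_arrays))
        cache: dict = {"sizes": sizes, "per_bag": []}
        offset = 0
        for i, k in enumerate(sizes):
            H = feats[offset : offset + k]
            if self.aggregation == "gated_attention":
                a, z = self.attention(H)
                logits[i] = z @ self.w_c.value + self.b_c.value[0]
                cache["per_bag"].append({"a": a, "z": z, "att_cache": self.attention._cache})
            else:
                tl = H @ self.w_c.value + self.b_c.value[0]  # per-tile logits
                j = int(np.argmax(tl))
                logits[i] = tl[j]
                cache["per_bag"].append({"H": H, "argmax": j, "tile_logits": tl})
            offset += k
        return logits, cache

    def backward_batch(self, dlogits: np.ndarray, cache: dict) -> None:
        """Accumulate gradients given d(loss)/d(bag logit)."""
        sizes = cache["sizes"]
        dfeats = np.zeros((sum(sizes), self.d))
        offset = 0
        for i, k in enumerate(sizes):
            info = cache["per_bag"][i]
            g = float(dlogits[i])
            if self.aggregation == "gated_attention":
                z = info["z"]
                self.w_c.grad += g * z
                self.b_c.grad += g
                dz = g * self.w_c.value
                self.attention._cache = info["att_cache"]
                dfeats[offset : offset + k] = self.attention.backward(dz)
            else:
                j = info["argmax"]
                h = info["H"][j]
                self.w_c.grad += g * h
                self.b_c.grad += g
                dfeats[offset + j] = g * self.w_c.value
            offset += k
        self.encoder.backward(dfeats)

    # -- inference ------------------------------------------------------------
    def predict_bag(self, bag_array: np.ndarray) -> BagOutput:
        """Single-bag inference returning probability and diagnostics."""
        was_training = self.training
        self.eval()
        try:
            H = self.encoder(np.asarray(bag_array, dtype=np.float64))
            if self.aggregation == "gated_attention":
                a, z = gated_attention(H, self.attention.as_params())
                p = classify_bag(z, self.w_c.value, float(self.b_c.value[0]))
                return BagOutput(probability=p, attention=a, bag_feature=z)
            tile_p = sigmoid(H @ self.w_c.value + self.b_c.value[0])
            return BagOutput(
                probability=max_pool_aggregate(tile_p),
                per_tile_probabilities=tile_p,
            )
        finally:
            if was_training:
                self.train()

    def config(self) -> dict:
        return {
            "backbone": self.backbone,
            "aggregation": self.aggregation,
            "d": self.d,
            "attention_dim": self.attention_dim,
            "se_reduction": self.se_reduction,
            "seed": self.seed,
            "pretrained": self.pretrained,
        }


def save_checkpoint(model: MILModel, path: str | Path, extra: dict | None = None) -> None:
    """Write weights (npz) plus a JSON sidecar with the model configuration."""
    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    np.savez(path, **model.state_dict())
    sidecar = {"model": model.config()}
    if extra:
        sidecar.update(extra)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))


def load_checkpoint(path: str | Path) -> MILModel:
    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg = sidecar["model"]
    model = MILModel(
        backbone=cfg["backbone"],
        aggregation=cfg["aggregation"],
        attention_dim=cfg["attention_dim"],
        se_reduction=cfg["se_reduction"],
        seed=cfg["seed"],
        pretrained=cfg.get("pretrained", False),
    )
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    model.eval()
    return model
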