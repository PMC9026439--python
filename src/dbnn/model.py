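"""Dual-branch convolutional network for paired two-timepoint images.

Two parallel convolutional branches ingest the pre-treatment image X and
the after-cycle-1 image Y.  Each branch is a VGG-style stack of 3x3
convolutions (conv -> batch-norm -> ReLU) organised in four blocks; a
2x2/stride-2 max-pool follows designated layers, so four pools take a
128x128 input down to 8x8.  At designated *sharing* layers the input to
layer j of each branch is the combination of BOTH branches' previous
feature maps — element-wise sum (FSS) or channel concatenation (FSC) —
so cross-timepoint correlation is exploited while low-level features are
still being extracted.  Each branch then flattens into a fully connected
feature vector, and the two vectors are fused: by concatenation, by sum,
or by the convex weighting  F(Z) = alpha * F(X) + beta * F(Y)  that lets
the later timepoint dominate.  A final linear map and softmax produce
the two class probabilities (index 0 = pCR, index 1 = non-pCR).

The branches have independent parameters (no Siamese weight tying): the
two timepoints are draws from different distributions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn import autograd as ag
from .nn.autograd import Tensor
from .errors import ValidationError, ContractError

#: class ordering used everywhere: probabilities/labels index 0 is pCR.
CLASSES = ("pCR", "non-pCR")

#: per-depth default split of conv layers over the four blocks
DEPTH_LAYOUTS = {8: [2, 2, 2, 2], 9: [2, 2, 3, 2], 10: [2, 2, 3, 3],
                 11: [2, 3, 3, 3], 12: [3, 3, 3, 3]}


def _block_ends(layout: list[int]) -> list[int]:
    ends, c = [], 0
    for n in layout:
        c += n
        ends.append(c)
    return ends


@dataclass
class ModelConfig:
    """Architecture hyper-structure.

    ``sharing_layers`` and ``pool_layers`` are 1-based conv-layer indices.
    For the canonical depth-9 network the sharing set is {2, 4, 6, 9} and
    the pooling set {2, 4, 7, 9}; for other depths both default to the
    last layer of each block.
    """

    depth: int = 9
    block_layout: list[int] | None = None
    channels_per_block: list[int] = field(default_factory=lambda: [64, 128, 256, 512])
    kernel_size: int = 3
    sharing: str = "sum"                       # none | sum | concat
    sharing_layers: set[int] | None = None
    pool_layers: set[int] | None = None
    fc_width: int = 1024
    dropout_rate: float = 0.5
    fusion: str = "weighted"                   # concat | sum | weighted
    alpha: float = 0.2
    beta: float = 0.8
    n_classes: int = 2
    image_size: int = 128
    dtype: str = "float64"

    def __post_init__(self):
        if self.block_layout is None:
            if self.depth not in DEPTH_LAYOUTS:
                raise ValidationError(
                    f"depth={self.depth}: no default block_layout; supply one")
            self.block_layout = list(DEPTH_LAYOUTS[self.depth])
        if sum(self.block_layout) != self.depth:
            raise ValidationError(
                f"block_layout {self.block_layout} sums to {sum(self.block_layout)}"
                f" != depth {self.depth}")
        if len(self.block_layout) != 4 or len(self.channels_per_block) != 4:
            raise ValidationError("block_layout and channels_per_block must have 4 blocks")
        ends = _block_ends(self.block_layout)
        if self.pool_layers is None:
            self.pool_layers = set(ends)
        if self.sharing_layers is None:
            self.sharing_layers = {2, 4, 6, 9} if self.depth == 9 else set(ends)
        self.pool_layers = set(self.pool_layers)
        self.sharing_layers = set(self.sharing_layers)
        valid = set(range(1, self.depth + 1))
        if not self.pool_layers <= valid:
            raise ValidationError(f"pool_layers {self.pool_layers} outside 1..{self.depth}")
        if not self.sharing_layers <= valid:
            raise ValidationError(
                f"sharing_layers {self.sharing_layers} outside 1..{self.depth}")
        if len(self.pool_layers) != 4:
            raise ValidationError("exactly 4 pooling stages are required")
        if self.sharing not in ("none", "sum", "concat"):
            raise ValidationError(f"unknown sharing mode {self.sharing!r}")
        if self.fusion not in ("concat", "sum", "weighted"):
            raise ValidationError(f"unknown fusion mode {self.fusion!r}")
        if self.alpha < 0 or self.beta < 0:
            raise ValidationError("alpha and beta must be non-negative")
        if self.fusion == "weighted" and abs(self.alpha + self.beta - 1.0) > 1e-9:
            raise ValidationError(
                f"weighted fusion requires alpha + beta == 1, got {self.alpha + self.beta}")
        if self.image_size % 16 != 0 or self.image_size < 16:
            raise ValidationError("image_size must be a positive multiple of 16"
                                  " (four 2x2 pools)")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValidationError("dropout_rate must be in [0, 1)")

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["sharing_layers"] = sorted(self.sharing_layers)
        d["pool_layers"] = sorted(self.pool_layers)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for k in ("sharing_layers", "pool_layers"):
            if d.get(k) is not None:
                d[k] = set(d[k])
        return cls(**d)

    @property
    def channel_sequence(self) -> list[int]:
        """Output channels of conv layers 1..depth."""
        seq = []
        for n, ch in zip(self.block_layout, self.channels_per_block):
            seq.extend([ch] * n)
        return seq


@dataclass
class ArchitectureSummary:
    conv_layer_count: int
    pool_count: int
    block_count: int
    per_layer_channels: list[int]
    fused_feature_dim: int
    total_parameter_count: int


class _Branch(nn.Module):
    """One convolutional stack: conv+BN per layer, layer-indexed 1..depth."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator, dtype):
        in_ch = 1
        for i, out_ch in enumerate(cfg.channel_sequence, start=1):
            eff_in = in_ch
            if cfg.sharing == "concat" and i in cfg.sharing_layers:
                eff_in = 2 * in_ch
            setattr(self, f"conv{i}", nn.Conv2d(eff_in, out_ch, rng,
                                                cfg.kernel_size, dtype))
            setattr(self, f"bn{i}", nn.BatchNorm2d(out_ch, dtype))
            in_ch = out_ch
        self.depth = cfg.depth

    def layer(self, i: int) -> tuple[nn.Conv2d, nn.BatchNorm2d]:
        return getattr(self, f"conv{i}"), getattr(self, f"bn{i}")


class DBNNModel(nn.Module):
    """The parameterised dual-branch network; build with :func:`build_model`."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        dtype = np.dtype(config.dtype).type
        rng = np.random.default_rng(seed)
        self.branch_pre = _Branch(config, rng, dtype)
        self.branch_post = _Branch(config, rng, dtype)
        side = config.image_size // 16
        flat = config.channel_sequence[-1] * side * side
        self.fc_pre = nn.Linear(flat, config.fc_width, rng, dtype)
        self.fc_post = nn.Linear(flat, config.fc_width, rng, dtype)
        fused = 2 * config.fc_width if config.fusion == "concat" else config.fc_width
        self.classifier = nn.Linear(fused, config.n_classes, rng, dtype)
        self.seed = seed

    # -- forward ----------------------------------------------------------
    def _check_batch(self, arr: np.ndarray) -> np.ndarray:
        a = np.asarray(arr, dtype=self.config.dtype)
        if a.ndim == 3:
            a = a[:, None, :, :]
        s = self.config.image_size
        if a.ndim != 4 or a.shape[1] != 1 or a.shape[2] != s or a.shape[3] != s:
            raise ContractError(
                f"expected batch of 1x{s}x{s} images, got shape {arr.shape}")
        return a

    def _features(self, pre: np.ndarray, post: np.ndarray, train: bool,
                  rng: np.random.Generator | None) -> tuple[Tensor, Tensor]:
        """Run both conv stacks + fc + dropout; returns (F(X), F(Y))."""
        cfg = self.config
        a: Tensor = Tensor(pre)
        b: Tensor = Tensor(post)
        for i in range(1, cfg.depth + 1):
            if cfg.sharing != "none" and i in cfg.sharing_layers:
                if cfg.sharing == "sum":
                    ia, ib = ag.add(a, b), ag.add(b, a)
                else:
                    ia, ib = ag.concat(a, b, axis=1), ag.concat(b, a, axis=1)
            else:
                ia, ib = a, b
            conv_a, bn_a = self.branch_pre.layer(i)
            conv_b, bn_b = self.branch_post.layer(i)
            a = ag.relu(bn_a(conv_a(ia), train))
            b = ag.relu(bn_b(conv_b(ib), train))
            if i in cfg.pool_layers:
                a, b = ag.maxpool2(a), ag.maxpool2(b)
        n = a.data.shape[0]
        fa = self.fc_pre(ag.reshape(a, (n, -1)))
        fb = self.fc_post(ag.reshape(b, (n, -1)))
        fa = ag.dropout(fa, cfg.dropout_rate, rng, train)
        fb = ag.dropout(fb, cfg.dropout_rate, rng, train)
        return fa, fb

    def fuse(self, fa: Tensor, fb: Tensor) -> Tensor:
        cfg = self.config
        if cfg.fusion == "concat":
            return ag.concat(fa, fb, axis=1)
        if cfg.fusion == "sum":
            return ag.add(fa, fb)
        return ag.add(ag.scale(fa, cfg.alpha), ag.scale(fb, cfg.beta))

    def logits(self, pre, post, train: bool = False,
               rng: np.random.Generator | None = None) -> Tensor:
        pre = self._check_batch(pre)
        post = self._check_batch(post)
        if pre.shape[0] != post.shape[0]:
            raise ContractError("pre and post batches differ in size")
        fa, fb = self._features(pre, post, train, rng)
        return self.classifier(self.fuse(fa, fb))

    def forward(self, pre, post) -> np.ndarray:
        """Eval-mode class probabilities, shape (N, 2), rows sum to 1."""
        return ag.softmax(self.logits(pre, post, train=False).data)

    __call__ = forward

    def branch_features(self, image, branch_id: str,
                        companion_image=None) -> np.ndarray:
        """F(X) (``branch_id='pre'``) or F(Y) (``'post'``), before weighting.

        With sharing enabled the branches are coupled, so the other
        timepoint's image is required.
        """
        if branch_id not in ("pre", "post"):
            raise ValidationError(f"branch_id must be 'pre' or 'post', got {branch_id!r}")
        if self.config.sharing != "none" and companion_image is None:
            raise ContractError(
                "sharing is enabled: branch features depend on the companion image")
        if companion_image is None:
            companion_image = np.zeros_like(np.asarray(image))
        pre, post = (image, companion_image) if branch_id == "pre" \
            else (companion_image, image)
        fa, fb = self._features(self._check_batch(pre), self._check_batch(post),
                                train=False, rng=None)
        return (fa if branch_id == "pre" else fb).data

    # -- introspection ----------------------------------------------------
    def summarize(self) -> ArchitectureSummary:
        return summarize(self)

    # -- checkpointing ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write ``<path>.npz`` (parameters + BN buffers) and ``<path>.json``."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.state_arrays())
        meta = {"model": self.config.to_dict(), "seed": self.seed}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "DBNNModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(ModelConfig.from_dict(meta["model"]), seed=meta.get("seed", 0))
        with np.load(path.with_suffix(".npz")) as st:
            model.load_state_arrays({k: st[k] for k in st.files})
        return model


class SingleBranchCNN(nn.Module):
    """One branch of the dual network with a plain fc + softmax head.

    Used for the single-timepoint baselines: the same backbone, no
    sharing, no fusion.  ``stage`` selects which element of a
    (pre, post) pair the model reads, so it is call-compatible with
    :class:`DBNNModel`.
    """

    def __init__(self, config: ModelConfig, stage: str, seed: int = 0):
        if stage not in ("pre", "post"):
            raise ValidationError("stage must be 'pre' or 'post'")
        cfg_dict = config.to_dict()
        cfg_dict["sharing"] = "none"
        self.config = ModelConfig.from_dict(cfg_dict)
        self.stage = stage
        dtype = np.dtype(self.config.dtype).type
        rng = np.random.default_rng(seed)
        self.branch = _Branch(self.config, rng, dtype)
        side = self.config.image_size // 16
        flat = self.config.channel_sequence[-1] * side * side
        self.fc = nn.Linear(flat, self.config.fc_width, rng, dtype)
        self.classifier = nn.Linear(self.config.fc_width, self.config.n_classes,
                                    rng, dtype)
        self.seed = seed

    def logits(self, pre, post, train: bool = False,
               rng: np.random.Generator | None = None) -> Tensor:
        cfg = self.config
        img = pre if self.stage == "pre" else post
        a = np.asarray(img, dtype=cfg.dtype)
        if a.ndim == 3:
            a = a[:, None, :, :]
        x = Tensor(a)
        for i in range(1, cfg.depth + 1):
            conv, bn = self.branch.layer(i)
            x = ag.relu(bn(conv(x), train))
            if i in cfg.pool_layers:
                x = ag.maxpool2(x)
        f = self.fc(ag.reshape(x, (x.data.shape[0], -1)))
        f = ag.dropout(f, cfg.dropout_rate, rng, train)
        return self.classifier(f)

    def forward(self, pre, post) -> np.ndarray:
        return ag.softmax(self.logits(pre, post, train=False).data)

    __call__ = forward


def build_model(config: ModelConfig, seed: int = 0) -> DBNNModel:
    """Instantiate the dual-branch network with independent He-normal
    branch parameters; deterministic in (config, seed)."""
    return DBNNModel(config, seed=seed)


def summarize(model: DBNNModel | SingleBranchCNN) -> ArchitectureSummary:
    """Architecture inventory derived by traversing the built model."""
    branch = model.branch_pre if isinstance(model, DBNNModel) else model.branch
    channels = []
    i = 1
    while hasattr(branch, f"conv{i}"):
        channels.append(getattr(branch, f"conv{i}").out_ch)
        i += 1
    n_params = sum(p.data.size for p in model.parameters())
    # pool count recovered from the flatten dimension of the built fc layer:
    # side = image_size / 2**pools and fc_in = channels[-1] * side**2
    fc_in = (model.fc_pre if isinstance(model, DBNNModel) else model.fc).in_dim
    side = int(round(np.sqrt(fc_in / channels[-1])))
    pools = int(round(np.log2(model.config.image_size / side)))
    return ArchitectureSummary(
        conv_layer_count=len(channels),
        pool_count=pools,
        block_count=len(set(channels)) if len(set(channels)) == 4
        else len(model.config.block_layout),
        per_layer_channels=channels,
        fused_feature_dim=model.classifier.in_dim,
        total_parameter_count=n_params,
    )
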