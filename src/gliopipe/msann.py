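"""Multi-sequence attention branch (Score 1).

A 3D CNN over the stacked FLAIR/T1CE/T2 channels whose building block
fuses the plain convolutional path with an attention-reweighted path:

    F = Conv(f_x) || [ CAM(Conv(f_x)) (*) SAM(CAM(Conv(f_x))) ]

where ``||`` is channel concatenation, ``(*)`` elementwise (Hadamard)
multiplication, CAM the channel-reweighted tensor and SAM the spatially
reweighted tensor.  The attention internals follow the CBAM pattern in
3D: channel weights come from a shared bottleneck MLP applied to global
max- and average-pooled channel descriptors; spatial weights from a
single convolution over the channelwise max and mean maps.  Both pass
through a sigmoid, so every attention weight lies in (0, 1).

The concatenation doubles the channel count, so deleting the attention
term (``use_attention=False``) halves the block output — the built-in
ablation mirroring an attention-free CNN of the same trunk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from ._training import BranchResult, grade_to_int, heldout_accuracy, stratified_split, train_epochs
from .segmentation import preprocess_input, _study_of

__all__ = [
    "MsaBlockConfig",
    "MsannConfig",
    "ChannelAttention3d",
    "SpatialAttention3d",
    "MsaBlock",
    "MSANN",
    "channel_attention",
    "spatial_attention",
    "msa_block",
    "build_msann",
    "train_msann",
]


@dataclass
class MsaBlockConfig:
    in_channels: int
    conv_channels: int
    kernel: int = 3
    reduction: int = 2
    stride: int = 2  # per-block downsampling keeps 3D memory small

    def __post_init__(self) -> None:
        if self.conv_channels < 1:
            raise ValueError("conv_channels must be >= 1")
        if self.conv_channels % self.reduction:
            raise ValueError(
                f"reduction {self.reduction} must divide conv_channels {self.conv_channels}"
            )


class ChannelAttention3d(nn.Module):
    """One weight per channel from max+avg pooled descriptors through a
    shared bottleneck MLP and a sigmoid."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        hidden = max(1, channels // reduction)
        self.fc1 = nn.Linear(channels, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, channels, rng=rng)

    def weights(self, x: Tensor) -> Tensor:
        """(B, C, D, H, W) -> per-channel weights (B, C) in (0, 1)."""
        mx = x.max(axis=(2, 3, 4))
        av = x.mean(axis=(2, 3, 4))
        h = self.fc2(self.fc1(mx).relu()) + self.fc2(self.fc1(av).relu())
        return h.sigmoid()

    def __call__(self, x: Tensor) -> Tensor:
        """Channel-reweighted tensor CAM(x)."""
        b, c = x.data.shape[:2]
        return x * self.weights(x).reshape(b, c, 1, 1, 1)


class SpatialAttention3d(nn.Module):
    """One weight per voxel from the channelwise max and mean maps through
    a single 3D convolution and a sigmoid."""

    def __init__(self, kernel: int = 3, rng: np.random.Generator | None = None):
        self.conv = nn.Conv3d(2, 1, kernel=kernel, rng=rng or np.random.default_rng(0))

    def weights(self, x: Tensor) -> Tensor:
        """(B, C, D, H, W) -> (B, 1, D, H, W) weights in (0, 1)."""
        mx = x.max(axis=1, keepdims=True)
        av = x.mean(axis=1, keepdims=True)
        return self.conv(nn.concat([mx, av], axis=1)).sigmoid()

    def __call__(self, x: Tensor) -> Tensor:
        """Spatially reweighted tensor SAM(x)."""
        return x * self.weights(x)


class MsaBlock(nn.Module):
    """Conv trunk concatenated with its serially attention-weighted copy;
    output channels = 2 x conv_channels (or conv_channels without attention)."""

    def __init__(self, config: MsaBlockConfig, rng: np.random.Generator | None = None,
                 use_attention: bool = True):
        rng = rng or np.random.default_rng(0)
        self.config = config
        self.use_attention = use_attention
        self.conv = nn.Conv3d(config.in_channels, config.conv_channels, kernel=config.kernel,
                              stride=config.stride, rng=rng)
        self.cam = ChannelAttention3d(config.conv_channels, config.reduction, rng=rng)
        self.sam = SpatialAttention3d(kernel=config.kernel, rng=rng)

    @property
    def out_channels(self) -> int:
        return (2 if self.use_attention else 1) * self.config.conv_channels

    def __call__(self, x: Tensor, identity_attention: bool = False) -> Tensor:
        y = self.conv(x).relu()
        if not self.use_attention:
            return y
        if identity_attention:
            return nn.concat([y, y], axis=1)
        b, c = y.data.shape[:2]
        yc = y * self.cam.weights(y).reshape(b, c, 1, 1, 1)
        att = yc * self.sam.weights(yc)
        return nn.concat([y, att], axis=1)


# functional wrappers matching the operation-level surface


def channel_attention(features: Tensor | np.ndarray, cam: ChannelAttention3d) -> np.ndarray:
    """Per-channel attention weights in (0, 1), shape (B, C)."""
    x = features if isinstance(features, Tensor) else Tensor(features)
    return cam.weights(x).data


def spatial_attention(features: Tensor | np.ndarray, sam: SpatialAttention3d) -> np.ndarray:
    """Per-voxel attention weights in (0, 1), shape (B, 1, D, H, W)."""
    x = features if isinstance(features, Tensor) else Tensor(features)
    return sam.weights(x).data


def msa_block(features: Tensor | np.ndarray, block: MsaBlock, identity_attention: bool = False) -> np.ndarray:
    x = features if isinstance(features, Tensor) else Tensor(features)
    return block(x, identity_attention=identity_attention).data


@dataclass
class MsannConfig:
    in_channels: int = 3
    channels: tuple[int, ...] = (8, 16)  # conv channels per block
    kernel: int = 3
    reduction: int = 2
    pool_in: int = 4  # input average-pooling factor (64^3 -> 16^3)
    use_attention: bool = True
    n_classes: int = 2
    lr: float = 5e-4
    epochs: int = 30
    batch_size: int = 2
    test_fraction: float = 0.4
    seed: int = 0


class MSANN(nn.Module):
    """Stacked attention blocks, global average pooling, linear head."""

    def __init__(self, config: MsannConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(config.seed)
        self.config = config
        self.blocks: list[MsaBlock] = []
        c_in = config.in_channels
        for c in config.channels:
            block = MsaBlock(
                MsaBlockConfig(c_in, c, kernel=config.kernel, reduction=config.reduction),
                rng=rng,
                use_attention=config.use_attention,
            )
            self.blocks.append(block)
            c_in = block.out_channels
        self.head = nn.Linear(c_in, config.n_classes, rng=rng)

    def forward_logits(self, x: Tensor) -> Tensor:
        h = nn.avg_pool3d(x, self.config.pool_in) if self.config.pool_in > 1 else x
        for block in self.blocks:
            h = block(h)
        h = h.mean(axis=(2, 3, 4))
        return self.head(h)

    def score(self, x: np.ndarray) -> np.ndarray:
        """GBM probability per study for a batched (N, C, D, H, W) input."""
        logits = self.forward_logits(Tensor(x))
        return nn.softmax(logits, axis=1).data[:, 1]


def build_msann(config: MsannConfig | None = None) -> MSANN:
    config = config or MsannConfig()
    return MSANN(config, rng=np.random.default_rng(config.seed))


def train_msann(cohort, config: MsannConfig | None = None, split=None) -> BranchResult:
    """Train the attention branch; Score 1 = GBM probability per study.

    ``split`` optionally fixes the (train_idx, test_idx) study split so
    several branches can share one held-out set.
    """
    config = config or MsannConfig()
    studies = [_study_of(s) for s in cohort]
    if any(s.grade is None for s in studies):
        missing = [s.study_id for s in studies if s.grade is None]
        raise ValueError(f"unlabeled studies in training set: {missing}")
    rng = np.random.default_rng(config.seed)

    X = np.stack([preprocess_input(s) for s in studies])
    y = np.array([grade_to_int(s.grade) for s in studies])
    if split is None:
        train_idx, test_idx = stratified_split(y, config.test_fraction, rng)
    else:
        train_idx, test_idx = np.asarray(split[0]), np.asarray(split[1])

    model = build_msann(config)
    losses = train_epochs(
        model, model.forward_logits, X[train_idx], y[train_idx],
        epochs=config.epochs, lr=config.lr, batch_size=config.batch_size, rng=rng,
    )
    probs = model.score(X)
    scores = {s.study_id: float(p) for s, p in zip(studies, probs)}
    grades = {s.study_id: s.grade for s in studies}
    heldout_ids = [studies[i].study_id for i in test_idx]
    return BranchResult(
        name="score1",
        model=model,
        scores=scores,
        train_ids=[studies[i].study_id for i in train_idx],
        heldout_ids=heldout_ids,
        heldout_accuracy=heldout_accuracy(scores, grades, heldout_ids),
        losses=losses,
    )
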