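"""3D U-Net lesion segmentation with a combined soft-Dice + cross-entropy loss.

The segmenter maps a stacked FLAIR/T1CE/T2 tensor to a 4-class label map
(background, NCR/NET, ED, ET).  Training minimizes

    L = 1 - (2 * sum_i sum_c y_ic p_ic + eps) / (sum_i sum_c (y_ic + p_ic) + eps)
        - (1/N) * sum_i sum_c y_ic log(p_ic)

where ``y_ic`` is the one-hot ground truth, ``p_ic`` the predicted class
probability at voxel ``i`` and ``eps`` a small stabilizer.  Class
probabilities come from a softmax head, which keeps the per-voxel class
distribution well-defined for the multi-class Dice term.  Segmentation
quality is reported as the Dice similarity coefficient

    DSC = 2 TP / (2 TP + FP + FN)

per composite region (ET, TC, WT).  Long volumes are split along z into
fixed-depth chunks for training, mirroring sub-volume training of large
grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .nn import Tensor
from .volume_io import (
    LABEL_ED,
    LABEL_ET,
    LABEL_NCR_NET,
    SEQUENCES,
    LesionLabelMap,
    MultiSequenceStudy,
    RegionMask,
    derive_mask,
    zscore_normalize,
)

__all__ = ["SegConfig", "UNet3D", "dice_ce_loss", "dsc", "build_unet", "train_segmentation", "predict_labels"]

#: network class index -> BraTS label
CLASS_TO_LABEL = np.array([0, LABEL_NCR_NET, LABEL_ED, LABEL_ET], dtype=np.int16)
LABEL_TO_CLASS = {0: 0, LABEL_NCR_NET: 1, LABEL_ED: 2, LABEL_ET: 3}

#: probability floor inside the log: keeps the cross-entropy finite when a
#: predicted probability underflows to 0 at a hot class
PROB_FLOOR = 1e-7


@dataclass
class SegConfig:
    in_channels: int = 3
    n_classes: int = 4  # background + NCR/NET + ED + ET
    depth: int = 2
    base_filters: int = 8
    epsilon: float = 1e-5
    lr: float = 15e-4
    epochs: int = 10
    batch_size: int = 2
    chunk_z: int = 32
    holdout_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")

    @classmethod
    def desk(cls, **overrides) -> "SegConfig":
        """Desk-scale preset: shallow net, few epochs, higher learning
        rate — sized for small synthetic cohorts on one CPU."""
        kwargs = dict(depth=2, base_filters=8, epochs=12, lr=3e-3, chunk_z=16)
        kwargs.update(overrides)
        return cls(**kwargs)


def dice_ce_loss(probs, onehot, epsilon: float = 1e-5):
    """Combined soft-Dice + cross-entropy loss.

    ``probs`` and ``onehot`` have identical shapes with the class axis
    first after batch, e.g. (C, D, H, W) or (B, C, ...).  Accepts plain
    arrays (returns a float) or autodiff tensors (returns a scalar
    tensor).  The Dice term sums over all classes including background;
    N in the cross-entropy term is the voxel count.
    """
    is_tensor = isinstance(probs, Tensor)
    p = probs if is_tensor else Tensor(np.asarray(probs, dtype=np.float64))
    y_arr = onehot.data if isinstance(onehot, Tensor) else np.asarray(onehot, dtype=np.float64)
    if p.data.shape != y_arr.shape:
        raise ValueError(f"shape mismatch: probs {p.data.shape} vs onehot {y_arr.shape}")
    y = Tensor(y_arr)
    n_classes = y_arr.shape[0] if y_arr.ndim == 4 else y_arr.shape[1]
    n_voxels = y_arr.size // n_classes

    intersect = (y * p).sum()
    total = (y + p).sum()
    dice = 1.0 - (2.0 * intersect + epsilon) / (total + epsilon)
    ce = -(y * p.log(floor=PROB_FLOOR)).sum() * (1.0 / n_voxels)
    loss = dice + ce
    return loss if is_tensor else float(loss.data)


def dsc(pred_mask: RegionMask | np.ndarray, true_mask: RegionMask | np.ndarray) -> float:
    """Dice similarity coefficient 2TP/(2TP+FP+FN).

    Two empty masks are in perfect agreement and score 1.0.
    """
    a = pred_mask.data if isinstance(pred_mask, RegionMask) else np.asarray(pred_mask, dtype=bool)
    b = true_mask.data if isinstance(true_mask, RegionMask) else np.asarray(true_mask, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    tp = int(np.count_nonzero(a & b))
    denom = 2 * tp + int(np.count_nonzero(a & ~b)) + int(np.count_nonzero(~a & b))
    if denom == 0:
        return 1.0
    return 2.0 * tp / denom


class UNet3D(nn.Module):
    """Encoder-decoder with skip connections and a softmax class head."""

    def __init__(self, config: SegConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(config.seed)
        self.config = config
        c_in = config.in_channels
        self.enc: list[list[nn.Conv3d]] = []
        for level in range(config.depth):
            c_out = config.base_filters * 2**level
            self.enc.append([nn.Conv3d(c_in, c_out, rng=rng), nn.Conv3d(c_out, c_out, rng=rng)])
            c_in = c_out
        c_bot = config.base_filters * 2**config.depth
        self.bottleneck = [nn.Conv3d(c_in, c_bot, rng=rng), nn.Conv3d(c_bot, c_bot, rng=rng)]
        self.dec: list[list[nn.Conv3d]] = []
        c_up = c_bot
        for level in reversed(range(config.depth)):
            c_skip = config.base_filters * 2**level
            self.dec.append([nn.Conv3d(c_up + c_skip, c_skip, rng=rng), nn.Conv3d(c_skip, c_skip, rng=rng)])
            c_up = c_skip
        self.head = nn.Conv3d(c_up, config.n_classes, kernel=1, padding=0, rng=rng)

    def _check_shape(self, spatial: tuple[int, ...]) -> None:
        div = 2**self.config.depth
        bad = [s for s in spatial if s % div]
        if bad:
            need = [int(np.ceil(s / div) * div) for s in spatial]
            raise ValueError(
                f"input spatial shape {spatial} not divisible by 2^depth={div}; "
                f"pad to {tuple(need)}"
            )

    @staticmethod
    def _act(h: Tensor) -> Tensor:
        # instance norm + leaky ReLU: keeps gradients alive despite the
        # heavy background/lesion class imbalance
        return nn.instance_norm3d(h).leaky_relu(0.01)

    def forward_logits(self, x: Tensor) -> Tensor:
        self._check_shape(x.data.shape[2:])
        skips = []
        h = x
        for conv1, conv2 in self.enc:
            h = self._act(conv2(self._act(conv1(h))))
            skips.append(h)
            h = nn.avg_pool3d(h, 2)
        h = self._act(self.bottleneck[0](h))
        h = self._act(self.bottleneck[1](h))
        for (conv1, conv2), skip in zip(self.dec, reversed(skips)):
            h = nn.upsample_nearest3d(h, 2)
            h = nn.concat([h, skip], axis=1)
            h = self._act(conv2(self._act(conv1(h))))
        return self.head(h)

    def forward_probs(self, x: Tensor) -> Tensor:
        return nn.softmax(self.forward_logits(x), axis=1)


def build_unet(config: SegConfig) -> UNet3D:
    """Construct a U-Net; identical seeds give identical initial parameters."""
    return UNet3D(config, rng=np.random.default_rng(config.seed))


def _study_of(item) -> MultiSequenceStudy:
    return item.study if hasattr(item, "study") else item


def preprocess_input(study: MultiSequenceStudy) -> np.ndarray:
    """Z-scored FLAIR/T1CE/T2 stack, channels first: (3, D, H, W)."""
    return np.stack([zscore_normalize(study.sequences[s]).data for s in SEQUENCES])


def _onehot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    classes = np.zeros_like(labels, dtype=np.int64)
    for lab, cls in LABEL_TO_CLASS.items():
        classes[labels == lab] = cls
    eye = np.eye(n_classes)
    return np.moveaxis(eye[classes], -1, 0)  # (C, D, H, W)


def _chunks(x: np.ndarray, y: np.ndarray, chunk_z: int):
    """Split (C,D,H,W) input and (C,D,H,W) one-hot target along z (axis 1)."""
    depth = x.shape[1]
    n = int(np.ceil(depth / chunk_z))
    out = []
    for i in range(n):
        sl = slice(i * chunk_z, min((i + 1) * chunk_z, depth))
        out.append((x[:, sl], y[:, sl]))
    return out


@dataclass
class SegResult:
    model: UNet3D
    losses: list[float]
    dsc_report: pd.DataFrame
    train_ids: list[str] = field(default_factory=list)
    heldout_ids: list[str] = field(default_factory=list)


def predict_labels(model: UNet3D, study: MultiSequenceStudy) -> LesionLabelMap:
    """Segment one study: softmax argmax mapped back to BraTS labels."""
    x = preprocess_input(study)[None]
    probs = model.forward_probs(Tensor(x)).data[0]
    classes = probs.argmax(axis=0)
    return LesionLabelMap(CLASS_TO_LABEL[classes], spacing=study.sequences[SEQUENCES[0]].spacing)


def train_segmentation(cohort, config: SegConfig) -> SegResult:
    """Train the U-Net on z-chunks and report held-out DSC per region.

    The cohort is split study-wise (the last ``holdout_fraction`` after a
    seeded shuffle is held out).  The loss trace is the mean chunk loss
    per epoch; the report carries mean and sd of ET/TC/WT Dice over the
    held-out studies.
    """
    studies = [_study_of(s) for s in cohort]
    if not studies:
        raise ValueError("empty cohort")
    if any(s.labels is None for s in studies):
        raise ValueError("all studies need label maps for segmentation training")
    rng = np.random.default_rng(config.seed)

    order = rng.permutation(len(studies))
    n_hold = max(1, int(round(config.holdout_fraction * len(studies)))) if len(studies) > 1 else 0
    hold_idx = order[:n_hold]
    train_idx = order[n_hold:] if n_hold else order

    samples = []
    for i in train_idx:
        x = preprocess_input(studies[i])
        y = _onehot(studies[i].labels.data, config.n_classes)
        samples.extend(_chunks(x, y, config.chunk_z))

    model = build_unet(config)
    opt = nn.Adam(model.parameters(), lr=config.lr)
    losses: list[float] = []
    for _epoch in range(config.epochs):
        perm = rng.permutation(len(samples))
        epoch_loss = 0.0
        for start in range(0, len(perm), config.batch_size):
            batch = [samples[j] for j in perm[start : start + config.batch_size]]
            xb = Tensor(np.stack([b[0] for b in batch]))
            yb = np.stack([b[1] for b in batch])
            probs = model.forward_probs(xb)
            loss = dice_ce_loss(probs, Tensor(yb), epsilon=config.epsilon)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(batch)
        losses.append(epoch_loss / len(samples))

    eval_idx = hold_idx if n_hold else train_idx
    rows = []
    for i in eval_idx:
        pred = predict_labels(model, studies[i])
        for region in ("ET", "TC", "WT"):
            rows.append(
                {
                    "study_id": studies[i].study_id,
                    "region": region,
                    "dsc": dsc(derive_mask(pred, region), derive_mask(studies[i].labels, region)),
                }
            )
    per_region = (
        pd.DataFrame(rows).groupby("region")["dsc"].agg(["mean", "std"]).reindex(["ET", "TC", "WT"])
    )
    return SegResult(
        model=model,
        losses=losses,
        dsc_report=per_region,
        train_ids=[studies[i].study_id for i in train_idx],
        heldout_ids=[studies[i].study_id for i in hold_idx],
    )
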