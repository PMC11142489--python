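"""Curriculum-learning branch (Score 2).

Training proceeds in two rounds on one shared convolutional trunk:

* **Phase 1 (pretext task)** — the network learns to say which MRI
  sequence (FLAIR / T1CE / T2) a single-sequence input comes from.  This
  forces the trunk to encode sequence-specific contrast before it ever
  sees a grading label.  The trunk state with the best validation
  accuracy is checkpointed.
* **Phase 2 (target task)** — the best phase-1 trunk is transferred to
  GBM vs non-GBM classification.  Each sequence's input intensities are
  multiplied by a per-voxel lesion weight field ``omega_mask`` that
  up-weights (default x1.5) the lesion compartments a radiologist
  scrutinizes on that sequence: ED and ET on FLAIR, ET and NCR/NET on
  T1CE, and all three lesion regions on T2; everything else (including
  background) keeps weight 1.

The phase switch happens exactly at ``phase1_epochs``; the remaining
``total_epochs - phase1_epochs`` epochs belong to phase 2.  The default
50/180 split of the reference schedule is preserved proportionally when
scaled down for desk-size runs.

``omega_mask`` is applied to the input volume per sequence — the
earliest point "in the network".  ``weight_features=True`` instead
applies the (pooled) weight field to the trunk's first feature map, the
alternative reading in which a flattened mask vector reweights internal
features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np

from . import nn
from .nn import Tensor
from ._training import BranchResult, grade_to_int, heldout_accuracy, stratified_split, train_epochs
from .segmentation import _study_of
from .volume_io import (
    REGIONS,
    SEQUENCES,
    VALID_LABELS,
    LesionLabelMap,
    MultiSequenceStudy,
)

__all__ = [
    "CurriculumSchedule",
    "MaskWeightTable",
    "DEFAULT_MASK_WEIGHTS",
    "ClnnConfig",
    "ClnnTrunk",
    "build_mask_weights",
    "phase1_train",
    "phase2_train",
    "train_clnn",
]

#: sequence -> region -> weight; regions not listed (and background) get 1.
DEFAULT_MASK_WEIGHTS: dict[str, dict[str, float]] = {
    "FLAIR": {"ED": 1.5, "ET": 1.5},
    "T1CE": {"ET": 1.5, "NCR/NET": 1.5},
    "T2": {"NCR/NET": 1.5, "ET": 1.5, "ED": 1.5},
}


@dataclass
class MaskWeightTable:
    weights: dict[str, dict[str, float]] = dataclass_field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MASK_WEIGHTS.items()}
    )

    def __post_init__(self) -> None:
        for seq, table in self.weights.items():
            if seq not in SEQUENCES:
                raise ValueError(f"unknown sequence {seq!r}")
            for region, w in table.items():
                if region not in ("ET", "NCR/NET", "ED"):
                    raise ValueError(f"unknown region {region!r} in mask weight table")
                if w < 1:
                    raise ValueError(f"mask weights must be >= 1, got {region}={w}")


@dataclass
class CurriculumSchedule:
    phase1_epochs: int = 50
    total_epochs: int = 180

    def __post_init__(self) -> None:
        if not (0 < self.phase1_epochs < self.total_epochs):
            raise ValueError("need 0 < phase1_epochs < total_epochs")

    def scaled(self, total: int) -> "CurriculumSchedule":
        """Scale the schedule down preserving the phase-1/total proportion."""
        p1 = max(1, int(round(total * self.phase1_epochs / self.total_epochs)))
        return CurriculumSchedule(phase1_epochs=min(p1, total - 1), total_epochs=total)


def build_mask_weights(
    labels: LesionLabelMap, sequence: str, table: MaskWeightTable | None = None
) -> np.ndarray:
    """Per-voxel weight field omega_mask for one sequence.

    A voxel's weight is the table entry for its lesion region on that
    sequence; background and unlisted regions get 1.
    """
    if sequence not in SEQUENCES:
        raise ValueError(f"unknown sequence {sequence!r}; valid: {SEQUENCES}")
    table = table or MaskWeightTable()
    data = labels.data
    present = set(np.unique(data).tolist())
    if not present <= VALID_LABELS:
        raise ValueError(f"unknown labels {sorted(present - VALID_LABELS)} in label map")
    weights = np.ones(data.shape, dtype=np.float64)
    for region, w in table.weights[sequence].items():
        for lab in REGIONS[region]:
            weights[data == lab] = w
    return weights


@dataclass
class ClnnConfig:
    channels: tuple[int, ...] = (8, 16)
    kernel: int = 3
    pool_in: int = 4
    schedule: CurriculumSchedule = dataclass_field(default_factory=CurriculumSchedule)
    lr: float = 2e-3
    batch_size: int = 2
    test_fraction: float = 0.4
    weight_features: bool = False  # apply omega_mask to the first feature map instead
    seed: int = 0


class ClnnTrunk(nn.Module):
    """Shared trunk with exchangeable linear heads for the two phases."""

    def __init__(self, config: ClnnConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(config.seed)
        self.config = config
        self.convs: list[nn.Conv3d] = []
        c_in = 3
        for c in config.channels:
            self.convs.append(nn.Conv3d(c_in, c, kernel=config.kernel, stride=2, rng=rng))
            c_in = c
        self.head_seq = nn.Linear(2 * c_in, len(SEQUENCES), rng=rng)
        self.head_grade = nn.Linear(2 * c_in, 2, rng=rng)

    def trunk_parameters(self) -> list[nn.Tensor]:
        return [p for conv in self.convs for p in conv.parameters()]

    def features(self, x: Tensor, feature_weights: np.ndarray | None = None) -> Tensor:
        h = nn.avg_pool3d(x, self.config.pool_in) if self.config.pool_in > 1 else x
        for i, conv in enumerate(self.convs):
            h = conv(h).relu()
            if i == 0 and feature_weights is not None:
                h = h * Tensor(feature_weights)
        # avg + max global descriptors: max keeps small-lesion evidence
        # that spatial averaging dilutes
        return nn.concat([h.mean(axis=(2, 3, 4)), h.max(axis=(2, 3, 4))], axis=1)

    def forward_seq(self, x: Tensor) -> Tensor:
        return self.head_seq(self.features(x))

    def forward_grade(self, x: Tensor, feature_weights: np.ndarray | None = None) -> Tensor:
        return self.head_grade(self.features(x, feature_weights))

    def trunk_state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.trunk_parameters()]

    def load_trunk_state(self, state: list[np.ndarray]) -> None:
        for p, arr in zip(self.trunk_parameters(), state):
            p.data = arr.copy()


def _joint_normalized(study: MultiSequenceStudy) -> dict[str, np.ndarray]:
    """Z-score each sequence with brain statistics pooled over all three
    sequences of the study.

    Per-volume z-scoring would erase exactly the between-sequence
    intensity statistics the phase-1 pretext task discriminates on;
    pooling the normalization support across sequences standardizes the
    study's scale while preserving relative sequence contrast.
    Background (zero) voxels stay zero.
    """
    support_vals = np.concatenate(
        [study.sequences[s].data[study.sequences[s].data != 0] for s in SEQUENCES]
    )
    if support_vals.size < 2 or support_vals.std() == 0:
        raise ValueError(f"study {study.study_id}: degenerate intensity support")
    mu, sd = float(support_vals.mean()), float(support_vals.std())
    out = {}
    for s in SEQUENCES:
        x = study.sequences[s].data
        z = np.where(x != 0, (x - mu) / sd, 0.0)
        out[s] = z
    return out


def _phase1_samples(studies: list[MultiSequenceStudy]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Each study contributes three single-sequence samples (replicated to
    the trunk's 3-channel width) labeled by sequence identity."""
    X, y, study_idx = [], [], []
    for i, s in enumerate(studies):
        normed = _joint_normalized(s)
        for k, seq in enumerate(SEQUENCES):
            X.append(np.repeat(normed[seq][None], 3, axis=0))
            y.append(k)
            study_idx.append(i)
    return np.stack(X), np.array(y), np.array(study_idx)


@dataclass
class Phase1Result:
    model: ClnnTrunk
    best_trunk_state: list[np.ndarray]
    best_epoch: int
    accuracy: float  # held-out sequence-classification accuracy at the best epoch
    losses: list[float]
    heldout_study_ids: list[str]


def phase1_train(cohort, config: ClnnConfig | None = None, split=None) -> Phase1Result:
    """Round 1: sequence-identity pretext task with best-epoch checkpointing.

    The held-out split is by study (all three sequence samples of a study
    stay on one side); ``split`` optionally fixes it as (train, heldout)
    study indices.  A single-study cohort trains but can only report
    training accuracy, with a warning.
    """
    config = config or ClnnConfig()
    studies = [_study_of(s) for s in cohort]
    if not studies:
        raise ValueError("empty cohort")
    rng = np.random.default_rng(config.seed)

    X, y, study_idx = _phase1_samples(studies)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 sequence classes for the pretext task")

    n_studies = len(studies)
    degenerate = n_studies < 2
    if degenerate:
        warnings.warn("single-study cohort: phase-1 reports training accuracy only")
        train_studies = val_studies = np.array([0])
    elif split is not None:
        train_studies, val_studies = np.asarray(split[0]), np.asarray(split[1])
    else:
        order = rng.permutation(n_studies)
        n_val = max(1, int(round(config.test_fraction * n_studies)))
        val_studies, train_studies = order[:n_val], order[n_val:]
    train_mask = np.isin(study_idx, train_studies)
    val_mask = np.isin(study_idx, val_studies)

    model = ClnnTrunk(config, rng=np.random.default_rng(config.seed))
    sched = config.schedule
    best = {"acc": -1.0, "epoch": -1, "state": model.trunk_state()}

    def checkpoint(epoch: int) -> None:
        pred = model.forward_seq(Tensor(X[val_mask])).data.argmax(axis=1)
        acc = float((pred == y[val_mask]).mean())
        if acc > best["acc"]:
            best.update(acc=acc, epoch=epoch, state=model.trunk_state())

    losses = train_epochs(
        model, model.forward_seq, X[train_mask], y[train_mask],
        epochs=sched.phase1_epochs, lr=config.lr, batch_size=config.batch_size,
        rng=rng, callback=checkpoint,
    )
    return Phase1Result(
        model=model,
        best_trunk_state=best["state"],
        best_epoch=int(best["epoch"]),
        accuracy=float(best["acc"]),
        losses=losses,
        heldout_study_ids=[studies[i].study_id for i in val_studies],
    )


def _phase2_input(study: MultiSequenceStudy, table: MaskWeightTable, weight_input: bool) -> np.ndarray:
    if study.labels is None:
        raise ValueError(f"study {study.study_id}: missing label map, omega_mask undefined")
    normed = _joint_normalized(study)  # same normalization as phase 1: transfer-friendly
    chans = []
    for seq in SEQUENCES:
        vol = normed[seq]
        if weight_input:
            vol = vol * build_mask_weights(study.labels, seq, table)
        chans.append(vol)
    return np.stack(chans)


def _pooled_feature_weights(study: MultiSequenceStudy, table: MaskWeightTable, factor: int) -> np.ndarray:
    """omega_mask averaged over sequences and pooled to the first feature
    map's resolution (the flattened-mask-vector reading)."""
    w = np.mean(
        [build_mask_weights(study.labels, seq, table) for seq in SEQUENCES], axis=0
    )
    f = factor
    d, h, ww = w.shape
    w = w.reshape(d // f, f, h // f, f, ww // f, f).mean(axis=(1, 3, 5))
    return w[None]  # broadcast over channels


def phase2_train(
    phase1: Phase1Result,
    cohort,
    config: ClnnConfig | None = None,
    table: MaskWeightTable | None = None,
    split=None,
) -> BranchResult:
    """Round 2: transfer the best phase-1 trunk to GBM / non-GBM grading.

    Score 2 is the GBM probability per study.  The trunk starts from the
    phase-1 best checkpoint (bitwise) and is fine-tuned together with the
    grading head for ``total_epochs - phase1_epochs`` epochs.
    """
    config = config or ClnnConfig()
    table = table or MaskWeightTable()
    studies = [_study_of(s) for s in cohort]
    if any(s.grade is None for s in studies):
        raise ValueError("phase-2 training requires grade labels on every study")
    rng = np.random.default_rng(config.seed + 1)

    model = phase1.model
    model.load_trunk_state(phase1.best_trunk_state)
    phase2_init_state = model.trunk_state()

    weight_input = not config.weight_features
    X = np.stack([_phase2_input(s, table, weight_input) for s in studies])
    fw = None
    if config.weight_features:
        pool = config.pool_in * 2  # input pooling then the first stride-2 conv
        fw = np.stack([_pooled_feature_weights(s, table, pool) for s in studies])
    y = np.array([grade_to_int(s.grade) for s in studies])
    if split is None:
        train_idx, test_idx = stratified_split(y, config.test_fraction, rng)
    else:
        train_idx, test_idx = np.asarray(split[0]), np.asarray(split[1])

    sched = config.schedule
    n_epochs = sched.total_epochs - sched.phase1_epochs

    if fw is None:
        forward = model.forward_grade
        losses = train_epochs(
            model, forward, X[train_idx], y[train_idx],
            epochs=n_epochs, lr=config.lr, batch_size=config.batch_size, rng=rng,
        )
        probs = nn.softmax(model.forward_grade(Tensor(X)), axis=1).data[:, 1]
    else:
        # feature-weighted variant: batch the weights alongside the inputs
        opt = nn.Adam(model.parameters(), lr=config.lr)
        losses = []
        idx = np.asarray(train_idx)
        for _epoch in range(n_epochs):
            perm = rng.permutation(len(idx))
            total = 0.0
            for start in range(0, len(idx), config.batch_size):
                sel = idx[perm[start : start + config.batch_size]]
                logits = model.forward_grade(Tensor(X[sel]), feature_weights=fw[sel])
                loss = nn.cross_entropy_logits(logits, y[sel])
                opt.zero_grad()
                loss.backward()
                opt.step()
                total += float(loss.data) * len(sel)
            losses.append(total / len(idx))
        probs = nn.softmax(model.forward_grade(Tensor(X), feature_weights=fw), axis=1).data[:, 1]

    scores = {s.study_id: float(p) for s, p in zip(studies, probs)}
    grades = {s.study_id: s.grade for s in studies}
    heldout_ids = [studies[i].study_id for i in test_idx]
    return BranchResult(
        name="score2",
        model=model,
        scores=scores,
        train_ids=[studies[i].study_id for i in train_idx],
        heldout_ids=heldout_ids,
        heldout_accuracy=heldout_accuracy(scores, grades, heldout_ids),
        losses=losses,
        extra={
            "phase1_accuracy": phase1.accuracy,
            "phase1_best_epoch": phase1.best_epoch,
            "phase2_init_trunk_state": phase2_init_state,
        },
    )


def train_clnn(cohort, config: ClnnConfig | None = None, table: MaskWeightTable | None = None,
               split=None) -> BranchResult:
    """Full two-round curriculum: pretext phase then grading phase."""
    config = config or ClnnConfig()
    phase1 = phase1_train(cohort, config, split=split)
    return phase2_train(phase1, cohort, config, table, split=split)


def curriculum_vs_direct(cohort, config: ClnnConfig | None = None,
                         table: MaskWeightTable | None = None, split=None) -> dict[str, BranchResult]:
    """Train the grading task with and without the pretext round.

    The direct variant starts the same trunk from its random
    initialization and trains on the grading task for the full epoch
    budget; the curriculum variant spends the phase-1 share on the
    sequence pretext first.  Comparing the two mirrors the question the
    curriculum is meant to answer: does the pretext round reach the
    grading plateau at least as fast?
    """
    config = config or ClnnConfig()
    curriculum = train_clnn(cohort, config, table, split=split)

    model = ClnnTrunk(config, rng=np.random.default_rng(config.seed))
    direct_phase1 = Phase1Result(
        model=model,
        best_trunk_state=model.trunk_state(),  # random init: no pretext round
        best_epoch=-1,
        accuracy=float("nan"),
        losses=[],
        heldout_study_ids=[],
    )
    direct = phase2_train(direct_phase1, cohort, config, table, split=split)
    direct.name = "direct"
    return {"curriculum": curriculum, "direct": direct}
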