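"""Shared plumbing for the two deep classification branches."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .nn import Tensor

GRADES = ("nonGBM", "GBM")  # index = class id; GBM is the positive class


def grade_to_int(grade: str) -> int:
    return GRADES.index(grade)


def stratified_split(labels: np.ndarray, test_fraction: float, rng: np.random.Generator):
    """Per-class shuffled split; returns (train_idx, test_idx)."""
    train, test = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        n_test = int(round(test_fraction * len(idx)))
        test.extend(idx[:n_test])
        train.extend(idx[n_test:])
    return np.sort(np.asarray(train, dtype=int)), np.sort(np.asarray(test, dtype=int))


def train_epochs(model, forward, X: np.ndarray, y: np.ndarray, *, epochs: int, lr: float,
                 batch_size: int, rng: np.random.Generator,
                 callback=None) -> list[float]:
    """Generic minibatch Adam training with cross-entropy on logits.

    ``forward`` maps a batched input tensor to logits.  ``callback`` is
    invoked after every epoch with the epoch index (e.g. to checkpoint).
    Returns per-epoch mean losses.
    """
    opt = nn.Adam(model.parameters(), lr=lr)
    losses = []
    n = len(X)
    for epoch in range(epochs):
        perm = rng.permutation(n)
        total = 0.0
        for start in range(0, n, batch_size):
            sel = perm[start : start + batch_size]
            logits = forward(Tensor(X[sel]))
            loss = nn.cross_entropy_logits(logits, y[sel])
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(sel)
        losses.append(total / n)
        if callback is not None:
            callback(epoch)
    return losses


@dataclass
class BranchResult:
    """Outcome of training one scoring branch.

    ``scores`` maps study_id -> GBM probability for every study in the
    cohort; ``heldout_accuracy`` is computed on the held-out split only.
    """

    name: str
    model: object
    scores: dict[str, float]
    train_ids: list[str]
    heldout_ids: list[str]
    heldout_accuracy: float
    losses: list[float] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"study_id": list(self.scores), self.name: list(self.scores.values())}
        ).set_index("study_id")


def heldout_accuracy(scores: dict[str, float], grades: dict[str, str], heldout_ids) -> float:
    hits = [
        (scores[sid] >= 0.5) == (grades[sid] == "GBM")
        for sid in heldout_ids
    ]
    return float(np.mean(hits)) if hits else float("nan")
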