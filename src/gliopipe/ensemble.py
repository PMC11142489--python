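"""Score fusion, evaluation metrics, permutation tests and the
end-to-end pipeline orchestrator.

The four branch scores — attention network (Score 1), curriculum network
(Score 2), radiomics forests (Score 3), volumetric diagnostic features
(Score 4) — are each the probability assigned to the GBM class.  The
final call averages the available scores (soft voting) and thresholds at
0.5: GBM iff the mean score is at least the threshold.  Performance is
summarized by

    Accuracy  = (TP + TN) / (TP + TN + FP + FN)
    Recall    = TP / (TP + FN)
    Precision = TP / (TP + FP)

with GBM as the positive class.  Method pairs are compared with a paired
permutation test whose statistic is the accuracy difference; the null
randomly swaps the two methods' predictions per study.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._training import BranchResult, grade_to_int, stratified_split
from .clnn import ClnnConfig, phase1_train, phase2_train
from .diag import train_diag_model
from .msann import MsannConfig, train_msann
from .radiomics import RadiomicsConfig, train_radiomics
from .segmentation import SegConfig, _study_of, predict_labels, train_segmentation
from .volume_io import MultiSequenceStudy

__all__ = [
    "ScoreSet",
    "ClassificationReport",
    "PipelineConfig",
    "PipelineResult",
    "fuse_scores",
    "classification_report",
    "permutation_test",
    "run_pipeline",
    "ablation_reports",
]

BRANCHES = ("score1", "score2", "score3", "score4")


@dataclass
class ScoreSet:
    """Per-study branch scores and the fused call."""

    study_id: str
    score1: float | None = None
    score2: float | None = None
    score3: float | None = None
    score4: float | None = None
    threshold: float = 0.5
    fused: float = field(init=False)
    call: str = field(init=False)

    def __post_init__(self) -> None:
        present = [s for s in (self.score1, self.score2, self.score3, self.score4) if s is not None]
        if not present:
            raise ValueError(f"study {self.study_id}: no scores present")
        self.fused = float(np.mean(present))
        self.call = "GBM" if self.fused >= self.threshold else "nonGBM"


def fuse_scores(scores, threshold: float = 0.5) -> tuple[float, str]:
    """Arithmetic mean of the present scores and the resulting call.

    ``scores`` is a mapping branch -> probability (absent / None entries
    are ablated branches) or an iterable of probabilities.
    """
    if isinstance(scores, dict):
        vals = [v for v in scores.values() if v is not None]
    else:
        vals = [v for v in scores if v is not None]
    if not vals:
        raise ValueError("no scores present")
    fused = float(np.mean(vals))
    return fused, ("GBM" if fused >= threshold else "nonGBM")


def _as_binary(labels) -> np.ndarray:
    out = []
    for v in labels:
        if isinstance(v, str):
            try:
                out.append(grade_to_int(v))
            except ValueError as exc:
                raise ValueError(f"unknown label {v!r}") from exc
        elif v in (0, 1):
            out.append(int(v))
        else:
            raise ValueError(f"unknown label {v!r}")
    return np.asarray(out, dtype=int)


@dataclass
class ClassificationReport:
    TP: int
    TN: int
    FP: int
    FN: int
    accuracy: float
    recall: float | None  # None when TP+FN == 0 (flagged undefined)
    precision: float | None  # None when TP+FP == 0

    def as_dict(self) -> dict:
        return {
            "TP": self.TP, "TN": self.TN, "FP": self.FP, "FN": self.FN,
            "accuracy": self.accuracy, "recall": self.recall, "precision": self.precision,
        }


def classification_report(calls, truths) -> ClassificationReport:
    """Contingency counts and accuracy/recall/precision, GBM positive.

    Zero-denominator ratios are reported as ``None`` rather than NaN.
    """
    pred = _as_binary(calls)
    true = _as_binary(truths)
    if len(pred) != len(true):
        raise ValueError(f"length mismatch: {len(pred)} calls vs {len(true)} truths")
    tp = int(np.sum((pred == 1) & (true == 1)))
    tn = int(np.sum((pred == 0) & (true == 0)))
    fp = int(np.sum((pred == 1) & (true == 0)))
    fn = int(np.sum((pred == 0) & (true == 1)))
    accuracy = (tp + tn) / len(pred)
    recall = tp / (tp + fn) if (tp + fn) else None
    precision = tp / (tp + fp) if (tp + fp) else None
    return ClassificationReport(TP=tp, TN=tn, FP=fp, FN=fn,
                                accuracy=accuracy, recall=recall, precision=precision)


def permutation_test(calls_a, calls_b, truths, n_perm: int = 1000, seed: int = 0,
                     randomized: bool = False) -> float:
    """Paired permutation test on the accuracy difference of two methods.

    The null hypothesis exchanges the two methods' predictions per study
    with probability 1/2.  By default returns the two-sided p-value with
    the usual +1 smoothing — conservative (super-uniform) because the
    accuracy-difference statistic is discrete, and lying in (0, 1].
    ``randomized=True`` breaks ties uniformly at random instead, which
    makes the null p-value distribution exactly uniform (useful for
    calibration studies); it remains a valid p-value.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    a = _as_binary(calls_a)
    b = _as_binary(calls_b)
    t = _as_binary(truths)
    if not (len(a) == len(b) == len(t)):
        raise ValueError("calls_a, calls_b and truths must have equal length")
    d = (a == t).astype(float) - (b == t).astype(float)  # per-study accuracy contribution
    t_obs = abs(d.mean())
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, len(d)))
    t_null = np.abs((signs * d).mean(axis=1))
    n_greater = int(np.sum(t_null > t_obs + 1e-12))
    n_ties = int(np.sum(np.abs(t_null - t_obs) <= 1e-12))
    if randomized:
        u = float(rng.uniform())
        return float((n_greater + u * (n_ties + 1)) / (n_perm + 1))
    return float((1 + n_greater + n_ties) / (n_perm + 1))


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class PipelineConfig:
    """End-to-end run configuration (all branch seeds derive from ``seed``)."""

    seed: int = 0
    test_fraction: float = 0.4
    threshold: float = 0.5
    use_unet_masks: bool = False  # else ground-truth label maps feed the branches
    branches: tuple[str, ...] = BRANCHES
    seg: SegConfig = field(default_factory=SegConfig)
    msann: MsannConfig = field(default_factory=MsannConfig)
    clnn: ClnnConfig = field(default_factory=ClnnConfig)
    radiomics: RadiomicsConfig = field(default_factory=RadiomicsConfig)
    diag_N: float = 1.0

    def as_json(self) -> str:
        def default(o):
            if hasattr(o, "__dict__"):
                return {k: v for k, v in vars(o).items() if not k.startswith("_")}
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            return str(o)

        return json.dumps(vars(self), default=default, indent=1, sort_keys=True)


@dataclass
class PipelineResult:
    scores: pd.DataFrame  # per study: score1..4, fused, call, grade, split
    report: ClassificationReport  # fused performance on the held-out studies
    branch_results: dict[str, BranchResult]
    branch_reports: dict[str, ClassificationReport]
    seg_result: object | None = None
    config: PipelineConfig | None = None


def _with_labels(study: MultiSequenceStudy, labels) -> MultiSequenceStudy:
    return MultiSequenceStudy(study.study_id, study.sequences, labels=labels,
                              grade=study.grade, meta=study.meta)


def run_pipeline(cohort, config: PipelineConfig | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run segmentation (or use ground-truth masks) and all four scoring
    branches on a shared train/held-out split, fuse, and report.

    Branch failures surface as exceptions prefixed with the stage name.
    With ``out_dir`` set, writes ``scores.csv``, ``report.csv``,
    ``ablation/<branch>.csv`` and the resolved config JSON.
    """
    config = config or PipelineConfig()
    studies = [_study_of(s) for s in cohort]
    if any(s.grade is None for s in studies):
        raise ValueError("pipeline requires graded studies")
    y = np.array([grade_to_int(s.grade) for s in studies])
    rng = np.random.default_rng(config.seed)
    split = stratified_split(y, config.test_fraction, rng)

    seg_result = None
    if config.use_unet_masks:
        try:
            seg_result = train_segmentation(studies, config.seg)
            studies = [_with_labels(s, predict_labels(seg_result.model, s)) for s in studies]
        except Exception as exc:  # noqa: BLE001 - stage attribution
            raise RuntimeError(f"segmentation stage failed: {exc}") from exc

    branch_results: dict[str, BranchResult] = {}
    stages = {
        "score1": lambda: train_msann(studies, config.msann, split=split),
        "score2": lambda: _run_clnn(studies, config.clnn, split),
        "score3": lambda: train_radiomics(studies, config.radiomics, split=split),
        "score4": lambda: train_diag_model(studies, N=config.diag_N, seed=config.seed, split=split),
    }
    for branch in config.branches:
        try:
            branch_results[branch] = stages[branch]()
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"branch {branch} failed: {exc}") from exc

    ids = [s.study_id for s in studies]
    grades = {s.study_id: s.grade for s in studies}
    heldout = set(ids[i] for i in split[1])
    rows = []
    for sid in ids:
        kwargs = {b: branch_results[b].scores[sid] for b in config.branches}
        ss = ScoreSet(study_id=sid, threshold=config.threshold, **kwargs)
        rows.append({
            "study_id": sid,
            **{b: kwargs.get(b) for b in BRANCHES},
            "fused": ss.fused,
            "call": ss.call,
            "grade": grades[sid],
            "split": "heldout" if sid in heldout else "train",
        })
    scores_df = pd.DataFrame(rows).set_index("study_id")

    held = scores_df[scores_df["split"] == "heldout"]
    report = classification_report(held["call"], held["grade"])
    branch_reports = {
        b: classification_report((held[b] >= config.threshold).map({True: "GBM", False: "nonGBM"}),
                                 held["grade"])
        for b in config.branches
    }

    result = PipelineResult(scores=scores_df, report=report, branch_results=branch_results,
                            branch_reports=branch_reports, seg_result=seg_result, config=config)
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _run_clnn(studies, config: ClnnConfig, split) -> BranchResult:
    phase1 = phase1_train(studies, config, split=split)
    return phase2_train(phase1, studies, config, split=split)


def ablation_reports(result: PipelineResult, threshold: float = 0.5) -> dict[str, ClassificationReport]:
    """Drop one branch at a time and re-fuse the remaining scores on the
    held-out studies (the branch-contribution harness)."""
    held = result.scores[result.scores["split"] == "heldout"]
    present = [b for b in BRANCHES if held[b].notna().all()]
    out = {}
    for dropped in present:
        kept = [b for b in present if b != dropped]
        calls = [fuse_scores({b: row[b] for b in kept}, threshold)[1] for _, row in held.iterrows()]
        out[dropped] = classification_report(calls, held["grade"])
    return out


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.scores.to_csv(out_dir / "scores.csv", float_format="%.10g")
    rows = [{"method": "fused", **result.report.as_dict()}]
    for b, rep in result.branch_reports.items():
        rows.append({"method": b, **rep.as_dict()})
    pd.DataFrame(rows).to_csv(out_dir / "report.csv", index=False, float_format="%.10g")
    abl = ablation_reports(result, result.config.threshold if result.config else 0.5)
    abl_dir = out_dir / "ablation"
    abl_dir.mkdir(exist_ok=True)
    for dropped, rep in abl.items():
        pd.DataFrame([{"dropped": dropped, **rep.as_dict()}]).to_csv(
            abl_dir / f"without_{dropped}.csv", index=False, float_format="%.10g"
        )
    if result.config is not None:
        (out_dir / "config.json").write_text(result.config.as_json())
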