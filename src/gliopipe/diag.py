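"""Hand-crafted volumetric diagnostic features (Score 4).

From the lesion label map alone, four scalar features capture the
radiological rules separating glioblastoma from lower grades — GBM tends
to show an extensive enhancing region with central necrosis and
substantial surrounding edema, while grades I-III show limited
enhancement relative to the tumor bulk:

    F3 = (V_ET + N) / (V_ET + V_NCR/NET + N)    enhancement share of the core
    F4 = (V_ET + N) / (V_ET + V_ED + N)         enhancement vs edema extent
    F1 = ln(V_ET + N) - ln(V_ET + V_NCR/NET + N) = ln(F3)
    F2 = ln(V_ET + N) - ln(V_ET + V_ED + N)      = ln(F4)

``V_x`` are compartment volumes (voxel counts by default; ratios are
unit-invariant under shared spacing) and ``N > 0`` is a small constant
guarding the ratios and logs when compartments are empty (default: one
voxel).  F1 = ln(F3) and F2 = ln(F4) hold as algebraic identities.

The features are screened statistically (Pearson correlation against the
binary grade and Welch's t-test between grades) and scored with a
ridge-regularized logistic regression whose GBM-class probability is
Score 4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from ._training import BranchResult, grade_to_int, heldout_accuracy, stratified_split
from .segmentation import _study_of
from .volume_io import LABEL_ED, LABEL_ET, LABEL_NCR_NET, LesionLabelMap

__all__ = [
    "DiagFeatures",
    "FEATURE_NAMES",
    "compute_diag_features",
    "diag_feature_frame",
    "feature_stats",
    "train_diag_model",
]

FEATURE_NAMES = ("F1", "F2", "F3", "F4")


@dataclass
class DiagFeatures:
    F1: float
    F2: float
    F3: float
    F4: float
    V_ET: float
    V_NCR_NET: float
    V_ED: float
    N: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in FEATURE_NAMES + ("V_ET", "V_NCR_NET", "V_ED")}


def compute_diag_features(
    labels: LesionLabelMap | np.ndarray, N: float = 1.0, use_mm3: bool = False
) -> DiagFeatures:
    """Volume-ratio diagnostic features from a lesion label map.

    ``N`` must be positive — its entire role is keeping denominators and
    logs defined when compartments are empty.  With ``use_mm3`` volumes
    are in mm^3 (for mixed-spacing cohorts); default is voxel counts.
    """
    if N <= 0:
        raise ValueError(f"N must be > 0 (it guards the ratios and logs), got {N}")
    if isinstance(labels, LesionLabelMap):
        data = labels.data
        scale = float(np.prod(labels.spacing)) if use_mm3 else 1.0
    else:
        data = np.asarray(labels)
        scale = 1.0
    v_et = float(np.count_nonzero(data == LABEL_ET)) * scale
    v_ncr = float(np.count_nonzero(data == LABEL_NCR_NET)) * scale
    v_ed = float(np.count_nonzero(data == LABEL_ED)) * scale
    f3 = (v_et + N) / (v_et + v_ncr + N)
    f4 = (v_et + N) / (v_et + v_ed + N)
    f1 = np.log(v_et + N) - np.log(v_et + v_ncr + N)
    f2 = np.log(v_et + N) - np.log(v_et + v_ed + N)
    return DiagFeatures(F1=float(f1), F2=float(f2), F3=float(f3), F4=float(f4),
                        V_ET=v_et, V_NCR_NET=v_ncr, V_ED=v_ed, N=float(N))


def diag_feature_frame(cohort, N: float = 1.0) -> pd.DataFrame:
    """Per-study feature table (index study_id; F1..F4, volumes, grade)."""
    rows = {}
    grades = {}
    for item in cohort:
        s = _study_of(item)
        if s.labels is None:
            raise ValueError(f"study {s.study_id}: no label map")
        rows[s.study_id] = compute_diag_features(s.labels, N=N).as_dict()
        grades[s.study_id] = s.grade
    df = pd.DataFrame.from_dict(rows, orient="index")
    df["grade"] = pd.Series(grades)
    return df


def feature_stats(features: pd.DataFrame, grades: pd.Series | None = None) -> pd.DataFrame:
    """Pearson correlation with grade and Welch's t-test per feature.

    ``features`` holds one row per study; ``grades`` the matching "GBM" /
    "nonGBM" labels (taken from a ``grade`` column if present).  A
    zero-variance feature gets ``constant=True`` with NaN statistics
    (flagged, not propagated silently).
    """
    if grades is None:
        if "grade" not in features.columns:
            raise ValueError("grades not given and no 'grade' column present")
        grades = features["grade"]
    y = np.array([grade_to_int(g) for g in grades])
    if min(np.bincount(y, minlength=2)) < 3:
        raise ValueError("need at least 3 studies per class")
    rows = []
    for name in FEATURE_NAMES:
        x = features[name].to_numpy(dtype=float)
        constant = float(np.std(x)) == 0.0
        if constant:
            rows.append({"feature": name, "pearson_r": np.nan, "t_stat": np.nan,
                         "p_value": np.nan, "constant": True})
            continue
        r, _ = stats.pearsonr(x, y)
        t, p = stats.ttest_ind(x[y == 1], x[y == 0], equal_var=False)
        rows.append({"feature": name, "pearson_r": float(r), "t_stat": float(t),
                     "p_value": float(p), "constant": False})
    return pd.DataFrame(rows).set_index("feature")


def train_diag_model(cohort, N: float = 1.0, C: float = 10.0,
                     test_fraction: float = 0.4, seed: int = 0, split=None) -> BranchResult:
    """Ridge-regularized logistic regression on F1..F4; Score 4 = P(GBM).

    The small L2 penalty (inverse strength ``C``) keeps the fit defined
    under perfect separation, which clean phantom cohorts readily produce.
    ``split`` optionally fixes the (train_idx, test_idx) study split.
    """
    df = diag_feature_frame(cohort, N=N)
    y = np.array([grade_to_int(g) for g in df["grade"]])
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    if split is None:
        train_idx, test_idx = stratified_split(y, test_fraction, rng)
    else:
        train_idx, test_idx = np.asarray(split[0]), np.asarray(split[1])

    X = df[list(FEATURE_NAMES)].to_numpy()
    model = LogisticRegression(C=C, max_iter=5000, tol=1e-8)
    model.fit(X[train_idx], y[train_idx])
    gbm_col = int(np.flatnonzero(model.classes_ == 1)[0])
    probs = model.predict_proba(X)[:, gbm_col]

    ids = list(df.index)
    scores = {sid: float(p) for sid, p in zip(ids, probs)}
    grades = dict(zip(ids, df["grade"]))
    heldout_ids = [ids[i] for i in test_idx]
    return BranchResult(
        name="score4",
        model=model,
        scores=scores,
        train_ids=[ids[i] for i in train_idx],
        heldout_ids=heldout_ids,
        heldout_accuracy=heldout_accuracy(scores, grades, heldout_ids),
        extra={"coefficients": dict(zip(FEATURE_NAMES, model.coef_[0])),
               "intercept": float(model.intercept_[0]),
               "features": df},
    )
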