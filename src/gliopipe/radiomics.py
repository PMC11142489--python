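"""Radiomics branch (Score 3): filtered images x feature families x
sequence-mask combinations, fused through per-combination random forests.

Six combinations are extracted per study — each of FLAIR/T1CE/T2 against
the TC and WT masks.  Every combination yields, per filtered image
(original, Laplacian-of-Gaussian at each sigma, the eight level-1
stationary-wavelet sub-bands, and a squared-intensity transform):

* first-order statistics over the masked voxels: mean, standard
  deviation (population), skewness, kurtosis (Pearson, normal = 3),
  energy, and entropy over bin-width-discretized gray levels;
* gray-level co-occurrence (GLCM) texture: joint energy, entropy,
  contrast, correlation, homogeneity — from a symmetric, normalized
  co-occurrence matrix aggregated over the 13 unique 3D unit offsets,
  restricted to within-mask pairs;

plus, once per combination, shape descriptors of the mask itself:
volume (mm^3), surface area (mm^2, exposed-face counting) and maximum
3D diameter (mm, largest pairwise distance between surface voxel
centers).

Intensities are normalized z-score-times-100 over the brain support
before discretization, so the default bin width of 25 yields a few tens
of gray levels.  One random forest is trained per combination; Score 3
is the (by default uniform) weighted mean of the six per-combination
GBM probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pywt
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from ._training import BranchResult, grade_to_int, heldout_accuracy, stratified_split
from .segmentation import _study_of
from .volume_io import (
    SEQUENCES,
    MultiSequenceStudy,
    RegionMask,
    VolumeGrid,
    derive_mask,
    zscore_normalize,
)

__all__ = [
    "RadiomicsConfig",
    "OFFSETS_13",
    "discretize",
    "first_order_features",
    "glcm_features",
    "shape_features",
    "apply_filters",
    "extract_combination",
    "extract_features",
    "train_radiomics",
    "tc_wt_permutation_pvalues",
]

#: the 13 unique 3D direction vectors at Chebyshev distance 1
OFFSETS_13: tuple[tuple[int, int, int], ...] = (
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

DEFAULT_COMBINATIONS: tuple[tuple[str, str], ...] = tuple(
    (seq, region) for seq in SEQUENCES for region in ("TC", "WT")
)

FIRST_ORDER_NAMES = ("mean", "sd", "skewness", "kurtosis", "energy", "entropy")
GLCM_NAMES = ("glcm_energy", "glcm_entropy", "glcm_contrast", "glcm_correlation", "glcm_homogeneity")
SHAPE_NAMES = ("volume_mm3", "surface_mm2", "max_diameter_mm")


@dataclass
class RadiomicsConfig:
    bin_width: float = 25.0
    normalize: bool = True
    normalize_scale: float = 100.0
    log_sigmas: tuple[float, ...] = (1.0, 3.0)  # mm
    wavelet: str = "haar"
    combinations: tuple[tuple[str, str], ...] = DEFAULT_COMBINATIONS
    rf_trees: int = 100
    combination_weights: Mapping[tuple[str, str], float] | None = None  # None = uniform
    test_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if not self.combinations:
            raise ValueError("combinations must be non-empty")


# ---------------------------------------------------------------------------
# primitive feature operations (each has a brute-force oracle in the tests)


def _mask_array(mask) -> np.ndarray:
    return mask.data if isinstance(mask, RegionMask) else np.asarray(mask, dtype=bool)


def _vol_array(vol) -> np.ndarray:
    return vol.data if isinstance(vol, VolumeGrid) else np.asarray(vol, dtype=np.float64)


def discretize(vol, mask, bin_width: float) -> tuple[np.ndarray, int]:
    """Gray-level discretization inside the mask.

    level(v) = floor((x_v - min_masked) / bin_width) + 1; voxels outside
    the mask get level 0.  Returns the level field and the highest level.
    """
    x = _vol_array(vol)
    m = _mask_array(mask)
    if not m.any():
        raise ValueError("empty mask")
    levels = np.zeros(x.shape, dtype=np.int64)
    vals = x[m]
    levels[m] = np.floor((vals - vals.min()) / bin_width).astype(np.int64) + 1
    return levels, int(levels.max())


def first_order_features(vol, mask, bin_width: float = 25.0) -> dict[str, float]:
    """Gray-level distribution statistics over the masked voxels."""
    x = _vol_array(vol)
    m = _mask_array(mask)
    n = int(np.count_nonzero(m))
    if n < 2:
        raise ValueError(f"mask has {n} voxels; dispersion statistics need at least 2")
    v = x[m]
    mu = float(v.mean())
    sd = float(v.std())  # population
    if sd > 0:
        skew = float(((v - mu) ** 3).mean() / sd**3)
        kurt = float(((v - mu) ** 4).mean() / sd**4)
    else:
        skew, kurt = 0.0, 0.0
    levels, _ = discretize(x, m, bin_width)
    counts = np.bincount(levels[m])[1:]
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    return {
        "mean": mu,
        "sd": sd,
        "skewness": skew,
        "kurtosis": kurt,
        "energy": float((v**2).sum()),
        "entropy": entropy,
    }


def glcm_matrix(
    levels: np.ndarray, mask, offsets: Sequence[tuple[int, int, int]] = OFFSETS_13
) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix over within-mask pairs,
    summed over the given offsets before normalization.  Index 0 of the
    returned matrix corresponds to gray level 1."""
    m = _mask_array(mask)
    lmax = int(levels[m].max()) if m.any() else 0
    if lmax < 1:
        raise ValueError("no gray levels inside the mask")
    counts = np.zeros((lmax, lmax), dtype=np.float64)
    for off in offsets:
        src = tuple(slice(max(0, -o), levels.shape[a] - max(0, o)) for a, o in enumerate(off))
        dst = tuple(slice(max(0, o), levels.shape[a] + min(0, o)) for a, o in enumerate(off))
        valid = m[src] & m[dst]
        if not valid.any():
            continue
        a = levels[src][valid] - 1
        b = levels[dst][valid] - 1
        np.add.at(counts, (a, b), 1.0)
        np.add.at(counts, (b, a), 1.0)  # symmetrize
    total = counts.sum()
    if total == 0:
        raise ValueError("no co-occurring voxel pairs inside the mask")
    return counts / total


def glcm_features(
    levels: np.ndarray, mask, offsets: Sequence[tuple[int, int, int]] = OFFSETS_13
) -> dict[str, float]:
    """Haralick-style texture statistics of the aggregated GLCM."""
    p = glcm_matrix(levels, mask, offsets)
    L = p.shape[0]
    i = np.arange(1, L + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu_x = float((i * px).sum())
    sd_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    nz = p[p > 0]
    if sd_x > 0:  # symmetric matrix: marginals coincide
        corr = float((p * (ii - mu_x) * (jj - mu_x)).sum() / sd_x**2)
    else:
        corr = 1.0
    return {
        "glcm_energy": float((p**2).sum()),
        "glcm_entropy": float(-(nz * np.log2(nz)).sum()),
        "glcm_contrast": float((p * (ii - jj) ** 2).sum()),
        "glcm_correlation": corr,
        "glcm_homogeneity": float((p / (1.0 + np.abs(ii - jj))).sum()),
    }


def shape_features(mask, spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> dict[str, float]:
    """Volume, exposed-face surface area and maximum 3D diameter of a mask."""
    m = _mask_array(mask)
    if not m.any():
        raise ValueError("empty mask")
    sx, sy, sz = (float(s) for s in spacing)
    voxel_vol = sx * sy * sz
    volume = float(np.count_nonzero(m)) * voxel_vol

    face_areas = (sy * sz, sx * sz, sx * sy)
    surface = 0.0
    for axis, area in enumerate(face_areas):
        padded = np.pad(m, [(1, 1) if a == axis else (0, 0) for a in range(3)])
        diff = np.diff(padded.astype(np.int8), axis=axis)
        surface += float(np.abs(diff).sum()) * area

    eroded = ndimage.binary_erosion(m)
    boundary = m & ~eroded
    coords = np.argwhere(boundary).astype(np.float64) * np.array([sx, sy, sz])
    max_d = 0.0
    for start in range(0, len(coords), 512):  # chunked pairwise max, exact
        block = coords[start : start + 512]
        d2 = ((block[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
        max_d = max(max_d, float(d2.max()))
    return {
        "volume_mm3": volume,
        "surface_mm2": surface,
        "max_diameter_mm": float(np.sqrt(max_d)),
    }


# ---------------------------------------------------------------------------
# image filters


def square_filter(x: np.ndarray, rescale: bool = True) -> np.ndarray:
    """Elementwise square; by default rescaled linearly back onto the
    original intensity range so discretization bin semantics stay stable."""
    y = np.square(x)
    if not rescale:
        return y
    lo, hi = float(x.min()), float(x.max())
    ylo, yhi = float(y.min()), float(y.max())
    if yhi == ylo:
        return np.full_like(y, lo)
    return lo + (y - ylo) * (hi - lo) / (yhi - ylo)


def _swt_subbands(x: np.ndarray, wavelet: str) -> dict[str, np.ndarray]:
    """Level-1 stationary 3D wavelet sub-bands at full resolution.

    Odd axes are edge-padded to even length and cropped back.  Band names
    use L (approximation) / H (detail) per axis, e.g. 'LLL', 'LLH'.
    """
    pads = [(0, s % 2) for s in x.shape]
    xp = np.pad(x, pads, mode="edge")
    coeffs = pywt.swtn(xp, wavelet, level=1)[0]
    crop = tuple(slice(0, s) for s in x.shape)
    out = {}
    for key, band in coeffs.items():
        name = key.replace("a", "L").replace("d", "H").upper()
        out[name] = band[crop]
    return out


def apply_filters(vol, config: RadiomicsConfig | None = None,
                  spacing: tuple[float, float, float] | None = None) -> dict[str, np.ndarray]:
    """All filtered versions of a volume: original, LoG per sigma, the
    eight wavelet sub-bands and the squared image."""
    config = config or RadiomicsConfig()
    if isinstance(vol, VolumeGrid):
        x = vol.data
        spacing = vol.spacing
    else:
        x = np.asarray(vol, dtype=np.float64)
        spacing = spacing or (1.0, 1.0, 1.0)
    out: dict[str, np.ndarray] = {"original": x}
    for sigma in config.log_sigmas:
        sig_vox = [sigma / s for s in spacing]
        smoothed = ndimage.gaussian_filter(x, sigma=sig_vox)
        # spacing-aware discrete Laplacian of the smoothed image: exactly
        # zero on constants (the normalized Gaussian preserves them)
        log = np.zeros_like(smoothed)
        for axis, sp in enumerate(spacing):
            log += np.gradient(np.gradient(smoothed, sp, axis=axis), sp, axis=axis)
        out[f"log-sigma-{sigma:g}mm"] = log
    for name, band in _swt_subbands(x, config.wavelet).items():
        out[f"wavelet-{name}"] = band
    out["square"] = square_filter(x)
    return out


# ---------------------------------------------------------------------------
# per-study extraction


def _normalized_volume(study: MultiSequenceStudy, sequence: str, config: RadiomicsConfig) -> VolumeGrid:
    vol = study.sequences[sequence]
    if not config.normalize:
        return vol
    z = zscore_normalize(vol)
    z.data *= config.normalize_scale
    return z


def extract_combination(
    study: MultiSequenceStudy, sequence: str, mask_region: str, config: RadiomicsConfig | None = None
) -> pd.Series:
    """Full feature vector for one sequence x mask combination.

    Deterministic name/order: shape features first, then per filtered
    image the first-order and GLCM families.  Raises ``ValueError`` on an
    empty mask (callers flag and exclude the study).
    """
    config = config or RadiomicsConfig()
    if study.labels is None:
        raise ValueError(f"study {study.study_id}: no label map, cannot derive {mask_region}")
    mask = derive_mask(study.labels, mask_region)
    if not mask.data.any():
        raise ValueError(f"study {study.study_id}: empty {mask_region} mask")
    vol = _normalized_volume(study, sequence, config)
    prefix = f"{sequence}|{mask_region}"
    feats: dict[str, float] = {}
    for name, value in shape_features(mask, vol.spacing).items():
        feats[f"{prefix}|shape|{name}"] = value
    for filt, img in apply_filters(vol, config).items():
        fo = first_order_features(img, mask, bin_width=config.bin_width)
        for name, value in fo.items():
            feats[f"{prefix}|{filt}|{name}"] = value
        levels, _ = discretize(img, mask, config.bin_width)
        for name, value in glcm_features(levels, mask).items():
            feats[f"{prefix}|{filt}|{name}"] = value
    return pd.Series(feats, name=study.study_id)


def extract_features(cohort, config: RadiomicsConfig | None = None) -> dict[tuple[str, str], pd.DataFrame]:
    """Feature matrix per combination (rows = studies, columns = features)."""
    config = config or RadiomicsConfig()
    studies = [_study_of(s) for s in cohort]
    out: dict[tuple[str, str], pd.DataFrame] = {}
    for seq, region in config.combinations:
        rows = [extract_combination(s, seq, region, config) for s in studies]
        out[(seq, region)] = pd.DataFrame(rows)
    return out


# ---------------------------------------------------------------------------
# training


def train_radiomics(cohort, config: RadiomicsConfig | None = None, split=None) -> BranchResult:
    """One random forest per combination; Score 3 fuses their GBM
    probabilities by (default uniform) weighted mean.

    ``split`` optionally fixes the (train_idx, test_idx) study split.
    """
    config = config or RadiomicsConfig()
    studies = [_study_of(s) for s in cohort]
    if any(s.grade is None for s in studies):
        raise ValueError("radiomics training requires grade labels")
    y = np.array([grade_to_int(s.grade) for s in studies])
    if len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
        raise ValueError("need at least 2 studies per class")
    rng = np.random.default_rng(config.seed)
    if split is None:
        train_idx, test_idx = stratified_split(y, config.test_fraction, rng)
    else:
        train_idx, test_idx = np.asarray(split[0]), np.asarray(split[1])

    features = extract_features(studies, config)
    weights = {
        combo: (1.0 if config.combination_weights is None else config.combination_weights[combo])
        for combo in config.combinations
    }
    wsum = sum(weights.values())

    models: dict[tuple[str, str], RandomForestClassifier] = {}
    combo_probs: dict[tuple[str, str], np.ndarray] = {}
    for k, combo in enumerate(config.combinations):
        X = features[combo].to_numpy()
        rf = RandomForestClassifier(
            n_estimators=config.rf_trees, random_state=int(config.seed % (2**31 - 1)) + k
        )
        rf.fit(X[train_idx], y[train_idx])
        gbm_col = int(np.flatnonzero(rf.classes_ == 1)[0])
        combo_probs[combo] = rf.predict_proba(X)[:, gbm_col]
        models[combo] = rf

    fused = sum(weights[c] * combo_probs[c] for c in config.combinations) / wsum
    scores = {s.study_id: float(p) for s, p in zip(studies, fused)}
    grades = {s.study_id: s.grade for s in studies}
    heldout_ids = [studies[i].study_id for i in test_idx]
    return BranchResult(
        name="score3",
        model=models,
        scores=scores,
        train_ids=[studies[i].study_id for i in train_idx],
        heldout_ids=heldout_ids,
        heldout_accuracy=heldout_accuracy(scores, grades, heldout_ids),
        extra={
            "combination_probs": {c: dict(zip([s.study_id for s in studies], p)) for c, p in combo_probs.items()},
            "features": features,
        },
    )


def tc_wt_permutation_pvalues(
    result: BranchResult, cohort, n_perm: int = 1000, seed: int = 0
) -> dict[str, float]:
    """Per-sequence permutation test between the TC-mask and WT-mask
    combination predictions on the held-out studies (distinctiveness of
    the two extraction regions)."""
    from .ensemble import permutation_test  # local import avoids a cycle

    studies = {(_study_of(s)).study_id: _study_of(s) for s in cohort}
    ids = result.heldout_ids
    truths = np.array([grade_to_int(studies[i].grade) for i in ids])
    out = {}
    for k, seq in enumerate(SEQUENCES):
        probs_tc = np.array([result.extra["combination_probs"][(seq, "TC")][i] for i in ids])
        probs_wt = np.array([result.extra["combination_probs"][(seq, "WT")][i] for i in ids])
        out[seq] = permutation_test(
            (probs_tc >= 0.5).astype(int), (probs_wt >= 0.5).astype(int), truths,
            n_perm=n_perm, seed=seed + k,
        )
    return out
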