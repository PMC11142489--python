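"""Synthetic multi-sequence MR phantoms with known lesion geometry and grade.

The generator builds, inside a brain ellipsoid, a tumor made of nested
compartments that follow the BraTS vocabulary: an enhancing-tumor (ET) rim
around a necrotic / non-enhancing (NCR/NET) core — together the tumor core
(TC) — surrounded by a peritumoral edema (ED) shell.  Compartment sizes are
driven by two ratios:

* ``et_fraction``       — target ET share of the whole tumor (WT),
* ``necrosis_fraction`` — target NCR/NET share of the tumor core (TC).

Grade-conditional morphology encodes the radiological picture the staging
task relies on: GBM-like phantoms carry an extensive enhancing rim with a
substantial necrotic center; non-GBM-like phantoms have limited enhancement
(a small ET share of the tumor) with the core dominated by non-enhancing
tumor.  Sequence contrast follows the standard semantics: edema bright on
FLAIR and T2, enhancing tumor bright on T1CE, the necrotic core dark on
T1CE and bright on T2.

Geometry is deliberately simple (randomized ellipsoids, not anatomy): the
downstream pipeline consumes intensities and labels, not brain structure.
Compartment boundaries are placed on quantiles of the ellipsoidal radius,
so realized voxel fractions track their targets to counting precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .volume_io import (
    LABEL_ED,
    LABEL_ET,
    LABEL_NCR_NET,
    SEQUENCES,
    LesionLabelMap,
    MultiSequenceStudy,
    VolumeGrid,
)

__all__ = [
    "PhantomSpec",
    "PhantomStudy",
    "GRADE_BOUNDS",
    "DEFAULT_INTENSITY_TABLE",
    "generate_phantom",
    "generate_cohort",
]

TISSUES = ("background", "brain", "NCR/NET", "ED", "ET")

#: per-sequence (mean, sd) for each tissue class, arbitrary MR units.
#: Encodes the sequence-contrast semantics above; exact numbers are
#: configuration, not claims about scanner physics.
DEFAULT_INTENSITY_TABLE: Mapping[str, Mapping[str, tuple[float, float]]] = {
    "FLAIR": {"background": (0, 0), "brain": (80, 8), "NCR/NET": (95, 8), "ED": (170, 10), "ET": (120, 10)},
    "T1CE": {"background": (0, 0), "brain": (110, 8), "NCR/NET": (65, 8), "ED": (120, 10), "ET": (200, 10)},
    "T2": {"background": (0, 0), "brain": (145, 8), "NCR/NET": (185, 10), "ED": (200, 10), "ET": (175, 10)},
}

#: Grade-conditional sampling bounds used by :func:`generate_cohort`.
#: GBM: extensive enhancement with a substantial necrotic center.
#: non-GBM: limited enhancement; tumor core dominated by non-enhancing tumor.
#: The et_fraction and necrosis_fraction intervals are disjoint across
#: grades, which makes the volumetric diagnostic ratios separable by
#: construction (an intended, controllable effect size).
GRADE_BOUNDS: Mapping[str, Mapping[str, tuple[float, float]]] = {
    "GBM": {"et_fraction": (0.35, 0.60), "necrosis_fraction": (0.20, 0.50), "tc_radius_mm": (8.0, 11.0)},
    "nonGBM": {"et_fraction": (0.02, 0.15), "necrosis_fraction": (0.55, 0.85), "tc_radius_mm": (5.0, 7.5)},
}


@dataclass
class PhantomSpec:
    """Parameters of one synthetic study.

    ``edema_margin`` controls the ED shell: ``None`` (default) solves the
    shell extent so the realized ET share of WT matches ``et_fraction``;
    an explicit value in mm dilates WT beyond TC by that margin instead
    (0 means no edema at all).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    grade: str = "GBM"
    et_fraction: float = 0.45
    necrosis_fraction: float = 0.35
    edema_margin: float | None = None
    tc_radius_mm: float = 9.0
    intensity_table: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: DEFAULT_INTENSITY_TABLE
    )
    noise_sd: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(s) < 16 for s in self.grid_shape):
            raise ValueError(f"grid_shape axes must be >= 16, got {self.grid_shape}")
        if self.grade not in ("GBM", "nonGBM"):
            raise ValueError(f"grade must be 'GBM' or 'nonGBM', got {self.grade!r}")
        if not (0.0 <= self.et_fraction <= 1.0):
            raise ValueError("et_fraction must lie in [0, 1]")
        if not (0.0 <= self.necrosis_fraction <= 1.0):
            raise ValueError("necrosis_fraction must lie in [0, 1]")
        if self.edema_margin is not None and self.edema_margin < 0:
            raise ValueError("edema_margin must be >= 0 mm")
        if self.tc_radius_mm <= 0:
            raise ValueError("tc_radius_mm must be positive")
        means = {seq: np.mean([m for m, _ in self.intensity_table[seq].values()]) for seq in SEQUENCES}
        vals = sorted(means.values())
        if min(b - a for a, b in zip(vals, vals[1:])) < 1e-9:
            raise ValueError(
                "intensity_table rows must differ across sequences "
                "(sequence identity would not be learnable)"
            )


@dataclass
class PhantomStudy:
    """A generated study bundled with the spec that produced it."""

    study: MultiSequenceStudy
    spec: PhantomSpec


def _radius_field(shape, spacing, center_mm, semi_axes_mm) -> np.ndarray:
    """Normalized ellipsoidal radius rho (<=1 inside) at every voxel center."""
    axes = [(np.arange(n) * sp - c) / a for n, sp, c, a in zip(shape, spacing, center_mm, semi_axes_mm)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij", sparse=True)
    return np.sqrt(xx**2 + yy**2 + zz**2)


def _quantile_radius(rho_sorted: np.ndarray, n_target: int) -> float:
    """Radius whose ball contains exactly n_target of the sorted rho values."""
    n_target = min(max(n_target, 1), rho_sorted.size)
    return float(rho_sorted[n_target - 1])


def generate_phantom(spec: PhantomSpec) -> PhantomStudy:
    """Generate one phantom study; deterministic given ``spec.seed``.

    Raises ``ValueError`` when the requested tumor cannot fit inside the
    brain ellipsoid (never silently truncates).
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.grid_shape)
    spacing = spec.voxel_spacing
    extent_mm = [n * sp for n, sp in zip(shape, spacing)]

    # brain: ellipsoid filling most of the grid, mild random anisotropy
    brain_center = [0.5 * e for e in extent_mm]
    brain_axes = [0.42 * e * rng.uniform(0.95, 1.05) for e in extent_mm]
    rho_brain = _radius_field(shape, spacing, brain_center, brain_axes)
    brain = rho_brain <= 1.0

    # tumor center offset inside the brain; axes mildly anisotropic
    offset = rng.uniform(-0.15, 0.15, size=3) * np.asarray(brain_axes)
    tumor_center = [c + o for c, o in zip(brain_center, offset)]
    anis = rng.uniform(0.85, 1.18, size=3)
    anis /= anis.prod() ** (1.0 / 3.0)
    tumor_axes = [spec.tc_radius_mm * a for a in anis]
    rho = _radius_field(shape, spacing, tumor_center, tumor_axes)

    voxel_vol = float(np.prod(spacing))
    n_tc = max(int(round(4.0 / 3.0 * np.pi * spec.tc_radius_mm**3 / voxel_vol)), 8)

    rho_in_brain = rho[brain]
    if rho_in_brain.size < n_tc:
        raise ValueError(
            f"infeasible geometry: tumor core needs {n_tc} voxels but the brain "
            f"ellipsoid holds only {rho_in_brain.size}"
        )
    rho_sorted = np.sort(rho_in_brain)

    r_tc = _quantile_radius(rho_sorted, n_tc)
    n_tc_real = int(np.searchsorted(rho_sorted, r_tc, side="right"))

    # whole tumor: either solved from et_fraction or an explicit mm margin
    n_et_target = int(round((1.0 - spec.necrosis_fraction) * n_tc_real))
    if spec.edema_margin is None:
        if spec.et_fraction <= 0:
            raise ValueError("et_fraction must be > 0 when edema_margin is unset")
        if spec.et_fraction > 1.0 - spec.necrosis_fraction + 1e-12:
            raise ValueError(
                "infeasible partition: with nested compartments the ET share of WT "
                f"cannot exceed the ET share of TC = {1 - spec.necrosis_fraction:.3f} "
                f"(requested et_fraction={spec.et_fraction})"
            )
        n_wt = int(round(n_et_target / spec.et_fraction))
        if n_wt > rho_sorted.size:
            raise ValueError(
                f"infeasible geometry: whole tumor needs {n_wt} voxels but the "
                f"brain ellipsoid holds only {rho_sorted.size} "
                "(reduce tc_radius_mm or raise et_fraction)"
            )
        r_wt = _quantile_radius(rho_sorted, n_wt)
    else:
        r_wt = (spec.tc_radius_mm + spec.edema_margin) / spec.tc_radius_mm * r_tc

    n_core = int(round(spec.necrosis_fraction * n_tc_real))
    r_core = _quantile_radius(rho_sorted, n_core) if n_core > 0 else 0.0

    labels = np.zeros(shape, dtype=np.int16)
    inside = brain
    labels[inside & (rho <= r_wt)] = LABEL_ED
    labels[inside & (rho <= r_tc)] = LABEL_ET
    if n_core > 0:
        labels[inside & (rho <= r_core)] = LABEL_NCR_NET

    # intensities: per-tissue Gaussian draw plus additive scanner noise
    tissue_index = np.zeros(shape, dtype=np.int8)  # 0 bg, 1 brain, 2 ncr, 3 ed, 4 et
    tissue_index[brain] = 1
    tissue_index[labels == LABEL_NCR_NET] = 2
    tissue_index[labels == LABEL_ED] = 3
    tissue_index[labels == LABEL_ET] = 4
    tissue_order = ("background", "brain", "NCR/NET", "ED", "ET")

    sequences: dict[str, VolumeGrid] = {}
    for seq in SEQUENCES:
        table = spec.intensity_table[seq]
        means = np.array([table[t][0] for t in tissue_order])
        sds = np.array([table[t][1] for t in tissue_order])
        data = means[tissue_index] + sds[tissue_index] * rng.standard_normal(shape)
        data += spec.noise_sd * rng.standard_normal(shape)
        data[~brain] = 0.0  # skull-stripped background is exactly zero
        sequences[seq] = VolumeGrid(data, spacing=spacing)

    study = MultiSequenceStudy(
        study_id=f"phantom-{spec.grade}-{spec.seed}",
        sequences=sequences,
        labels=LesionLabelMap(labels, spacing=spacing),
        grade=spec.grade,
        meta={"seed": spec.seed},
    )
    return PhantomStudy(study=study, spec=spec)


def generate_cohort(
    n_per_grade: int,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
    bounds: Mapping[str, Mapping[str, tuple[float, float]]] = GRADE_BOUNDS,
) -> list[PhantomStudy]:
    """Balanced cohort of GBM and non-GBM phantoms.

    Per-phantom ratios and tumor scale are jittered uniformly within the
    grade's bounds; everything is reproducible from ``seed``.
    """
    if n_per_grade < 1:
        raise ValueError("n_per_grade must be >= 1")
    base = base_spec if base_spec is not None else PhantomSpec()
    rng = np.random.default_rng(seed)
    # tc_radius bounds are stated for the default 64 mm grid extent; scale
    # them with the actual grid so phantoms stay proportionate
    extent_scale = min(n * sp for n, sp in zip(base.grid_shape, base.voxel_spacing)) / 64.0
    studies: list[PhantomStudy] = []
    for grade in ("GBM", "nonGBM"):
        b = bounds[grade]
        for i in range(n_per_grade):
            nf = float(rng.uniform(*b["necrosis_fraction"]))
            # ET share of WT is capped by ET share of TC; keep a thin ED shell
            et_lo, et_hi = b["et_fraction"]
            et_hi = min(et_hi, (1.0 - nf) - 0.02)
            et_lo = min(et_lo, et_hi)
            spec = replace(
                base,
                grade=grade,
                et_fraction=float(rng.uniform(et_lo, et_hi)),
                necrosis_fraction=nf,
                tc_radius_mm=float(rng.uniform(*b["tc_radius_mm"])) * extent_scale,
                edema_margin=None,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            ph = generate_phantom(spec)
            ph.study.study_id = f"phantom-{grade}-{i:03d}"
            studies.append(ph)
    return studies
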