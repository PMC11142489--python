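"""Volume containers, preprocessing and NIfTI I/O.

The atoms of the pipeline: a 3D scalar field (:class:`VolumeGrid`), an
integer lesion label map (:class:`LesionLabelMap`) following the BraTS
labelling convention (0 background, 1 NCR/NET, 2 ED, 4 ET), and boolean
region masks derived from it, including the composite regions

* ``TC`` (tumor core)  = NCR/NET ∪ ET
* ``WT`` (whole tumor) = NCR/NET ∪ ET ∪ ED

Preprocessing matches what BraTS-style studies receive before any model
sees them: Z-score intensity normalization (brain voxels only by default,
since skull-stripped backgrounds are exactly zero) and a center crop/pad
to a fixed grid.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import nibabel as nib
import numpy as np

__all__ = [
    "SEQUENCES",
    "LABEL_BACKGROUND",
    "LABEL_NCR_NET",
    "LABEL_ED",
    "LABEL_ET",
    "REGIONS",
    "VolumeGrid",
    "LesionLabelMap",
    "RegionMask",
    "MultiSequenceStudy",
    "zscore_normalize",
    "center_crop",
    "derive_mask",
    "read_study",
    "write_study",
    "write_manifest",
    "read_manifest",
]

SEQUENCES = ("FLAIR", "T1CE", "T2")

LABEL_BACKGROUND = 0
LABEL_NCR_NET = 1
LABEL_ED = 2
LABEL_ET = 4
VALID_LABELS = frozenset({LABEL_BACKGROUND, LABEL_NCR_NET, LABEL_ED, LABEL_ET})

#: region name -> set of raw labels belonging to it
REGIONS: Mapping[str, frozenset[int]] = {
    "ET": frozenset({LABEL_ET}),
    "NCR/NET": frozenset({LABEL_NCR_NET}),
    "ED": frozenset({LABEL_ED}),
    "TC": frozenset({LABEL_NCR_NET, LABEL_ET}),
    "WT": frozenset({LABEL_NCR_NET, LABEL_ET, LABEL_ED}),
}

Triple = tuple[float, float, float]


@dataclass
class VolumeGrid:
    """A 3D scalar field with voxel spacing (mm) and world origin (mm)."""

    data: np.ndarray
    spacing: Triple = (1.0, 1.0, 1.0)
    origin: Triple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"VolumeGrid must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("VolumeGrid contains non-finite values")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))


@dataclass
class LesionLabelMap:
    """Integer lesion label field using BraTS labels {0, 1, 2, 4}."""

    data: np.ndarray
    spacing: Triple = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.all(self.data == np.round(self.data)):
                raise ValueError("label map must hold integers")
            self.data = self.data.astype(np.int16)
        if self.data.ndim != 3:
            raise ValueError(f"label map must be 3D, got shape {self.data.shape}")
        present = set(np.unique(self.data).tolist())
        if not present <= VALID_LABELS:
            raise ValueError(
                f"label map contains invalid labels {sorted(present - VALID_LABELS)}; "
                f"allowed labels are {sorted(VALID_LABELS)}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def region_volume(self, region: str) -> int:
        """Voxel count of a (possibly composite) region."""
        return int(np.count_nonzero(derive_mask(self, region).data))


@dataclass
class RegionMask:
    """Boolean mask for one of the lesion regions {ET, NCR/NET, ED, TC, WT}."""

    data: np.ndarray
    region: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}; valid: {sorted(REGIONS)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class MultiSequenceStudy:
    """Co-registered FLAIR/T1CE/T2 volumes with optional labels and grade.

    ``grade`` is ``"GBM"`` or ``"nonGBM"`` when known; the GBM class is the
    positive class of the staging task throughout the package.
    """

    study_id: str
    sequences: dict[str, VolumeGrid]
    labels: LesionLabelMap | None = None
    grade: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [s for s in SEQUENCES if s not in self.sequences]
        if missing:
            raise ValueError(f"study {self.study_id}: missing sequences {missing}")
        shapes = {s: self.sequences[s].shape for s in SEQUENCES}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"study {self.study_id}: sequence shape mismatch {shapes}")
        spacings = {tuple(np.round(self.sequences[s].spacing, 6)) for s in SEQUENCES}
        if len(spacings) != 1:
            raise ValueError(f"study {self.study_id}: sequence spacing mismatch")
        if self.labels is not None:
            if self.labels.shape != self.sequences[SEQUENCES[0]].shape:
                raise ValueError(
                    f"study {self.study_id}: label map shape {self.labels.shape} "
                    f"differs from sequences {self.sequences[SEQUENCES[0]].shape}"
                )
        if self.grade is not None and self.grade not in ("GBM", "nonGBM"):
            raise ValueError(f"grade must be 'GBM' or 'nonGBM', got {self.grade!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.sequences[SEQUENCES[0]].shape


# ---------------------------------------------------------------------------
# preprocessing


def zscore_normalize(vol: VolumeGrid, foreground_only: bool = True) -> VolumeGrid:
    """Z-score a volume so its support has mean 0 and unit variance.

    With ``foreground_only`` (the default) the support is the nonzero
    voxels — the brain, in skull-stripped data whose background is exactly
    zero — and background voxels stay 0 in the output.  A constant support
    cannot be z-scored and raises ``ValueError``.
    """
    x = vol.data
    support = (x != 0) if foreground_only else np.ones_like(x, dtype=bool)
    n = int(np.count_nonzero(support))
    if n < 2:
        raise ValueError(f"normalization support has {n} voxels; need at least 2")
    vals = x[support]
    mu = float(vals.mean())
    sd = float(vals.std())
    if sd == 0.0:
        raise ValueError("zero-variance support: a constant image cannot be z-scored")
    out = np.zeros_like(x, dtype=np.float64)
    out[support] = (vals - mu) / sd
    if not foreground_only:
        out = (x - mu) / sd
    return replace(vol, data=out)


def _crop_slices(src: int, dst: int) -> tuple[slice, slice]:
    """Source and destination slices for one axis of a center crop/pad.

    Ties break toward the low index on both the crop and the pad side.
    """
    if dst <= 0:
        raise ValueError(f"target extent must be positive, got {dst}")
    if dst <= src:
        lo = (src - dst) // 2
        return slice(lo, lo + dst), slice(0, dst)
    lo = (dst - src) // 2
    return slice(0, src), slice(lo, lo + src)


def center_crop(vol: VolumeGrid, target_shape: tuple[int, int, int]) -> VolumeGrid:
    """Center-crop (and zero-pad where the target exceeds the source).

    The canonical use is taking a 240x240x155 BraTS grid to 160x160x160:
    x/y are cropped and the z deficit of 5 slices is zero-padded
    symmetrically (2 low / 3 high, tie toward the low index).
    """
    if len(target_shape) != 3:
        raise ValueError("target_shape must be a triple")
    out = np.zeros(tuple(int(t) for t in target_shape), dtype=vol.data.dtype)
    src_sl, dst_sl = zip(*(_crop_slices(s, int(t)) for s, t in zip(vol.shape, target_shape)))
    out[tuple(dst_sl)] = vol.data[tuple(src_sl)]
    return replace(vol, data=out)


def center_crop_labels(labels: LesionLabelMap, target_shape: tuple[int, int, int]) -> LesionLabelMap:
    """Center crop/pad for label maps; padding is background (0)."""
    out = np.zeros(tuple(int(t) for t in target_shape), dtype=labels.data.dtype)
    src_sl, dst_sl = zip(*(_crop_slices(s, int(t)) for s, t in zip(labels.shape, target_shape)))
    out[tuple(dst_sl)] = labels.data[tuple(src_sl)]
    return LesionLabelMap(out, spacing=labels.spacing)


def derive_mask(labels: LesionLabelMap, region: str) -> RegionMask:
    """Boolean mask of a region; composite regions are label unions."""
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}; valid: {sorted(REGIONS)}")
    mask = np.isin(labels.data, sorted(REGIONS[region]))
    return RegionMask(mask, region=region)


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(spacing: Triple, origin: Triple) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def _write_nifti(path: Path, data: np.ndarray, spacing: Triple, origin: Triple) -> None:
    img = nib.Nifti1Image(np.asarray(data), _affine(spacing, origin))
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def _read_nifti(path: Path) -> tuple[np.ndarray, Triple, Triple]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return data, zooms, origin  # type: ignore[return-value]


def write_study(study: MultiSequenceStudy, out_dir: str | Path) -> Path:
    """Write one study as NIfTI volumes plus a small JSON sidecar.

    Layout: ``<out_dir>/<study_id>/<study_id>_{flair,t1ce,t2,seg}.nii.gz``
    and ``<study_id>.json`` carrying grade and metadata.
    """
    out = Path(out_dir) / study.study_id
    out.mkdir(parents=True, exist_ok=True)
    for seq in SEQUENCES:
        vol = study.sequences[seq]
        _write_nifti(out / f"{study.study_id}_{seq.lower()}.nii.gz", vol.data, vol.spacing, vol.origin)
    if study.labels is not None:
        _write_nifti(
            out / f"{study.study_id}_seg.nii.gz",
            study.labels.data.astype(np.int16),
            study.labels.spacing,
            (0.0, 0.0, 0.0),
        )
    sidecar = {"study_id": study.study_id, "grade": study.grade, "meta": study.meta}
    (out / f"{study.study_id}.json").write_text(json.dumps(sidecar, indent=1, default=str))
    return out


def read_study(study_dir: str | Path) -> MultiSequenceStudy:
    """Read a study written by :func:`write_study`.

    Raises ``FileNotFoundError`` naming the sequence if a volume is
    missing, and ``ValueError`` on NaNs or shape/spacing mismatches.
    """
    study_dir = Path(study_dir)
    study_id = study_dir.name
    sequences: dict[str, VolumeGrid] = {}
    for seq in SEQUENCES:
        path = study_dir / f"{study_id}_{seq.lower()}.nii.gz"
        if not path.exists():
            raise FileNotFoundError(f"study {study_id}: missing {seq} volume at {path}")
        data, spacing, origin = _read_nifti(path)
        if not np.all(np.isfinite(data)):
            raise ValueError(f"study {study_id}: {seq} volume contains non-finite values")
        sequences[seq] = VolumeGrid(data, spacing=spacing, origin=origin)
    labels = None
    seg_path = study_dir / f"{study_id}_seg.nii.gz"
    if seg_path.exists():
        seg, spacing, _ = _read_nifti(seg_path)
        labels = LesionLabelMap(np.rint(seg).astype(np.int16), spacing=spacing)
    grade = None
    meta: dict = {}
    sidecar = study_dir / f"{study_id}.json"
    if sidecar.exists():
        payload = json.loads(sidecar.read_text())
        grade = payload.get("grade")
        meta = payload.get("meta", {})
    return MultiSequenceStudy(study_id, sequences, labels=labels, grade=grade, meta=meta)


def write_manifest(studies: Iterable[MultiSequenceStudy], root: str | Path) -> Path:
    """Write a cohort manifest CSV (study_id, grade, path)."""
    root = Path(root)
    path = root / "manifest.csv"
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["study_id", "grade", "path"])
        for study in studies:
            writer.writerow([study.study_id, study.grade or "", str(root / study.study_id)])
    return path


def read_manifest(path: str | Path) -> list[MultiSequenceStudy]:
    """Load every study listed in a manifest CSV."""
    studies = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            studies.append(read_study(row["path"]))
    return studies
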