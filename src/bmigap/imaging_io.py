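"""NIfTI volume and cohort-table I/O.

Volumes are exchanged as :class:`GMVImage` (data + affine), the feature space
is defined by a :class:`VoxelMask`, and masking/unmasking is a lossless
bijection on in-mask voxels with a fixed canonical ordering (ascending linear
index in C memory order of the mask array).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "GeometryError",
    "ValidationError",
    "GMVImage",
    "VoxelMask",
    "read_gmv_set",
    "vector_to_volume",
    "load_cohort",
    "write_cohort",
    "GROUPS",
    "COHORT_REQUIRED_COLUMNS",
]

AFFINE_ATOL = 1e-4

GROUPS = ("HC", "SCZ", "CHR", "ROD")
SPLITS = ("discovery", "validation", "external", "clinical")

COHORT_REQUIRED_COLUMNS = ("subject_id", "site", "group", "age", "sex", "bmi_measured")

#: optional columns, preserved as missing (NaN) when absent; never imputed here
COHORT_OPTIONAL_COLUMNS = (
    "split",
    "weight_t0",
    "weight_t1",
    "weight_t2",
    "panss_total",
    "age_at_onset",
    "illness_duration",
    "n_hospitalizations",
    "antipsychotic_naive",
    "antidepressant_naive",
    "weightgain_med",
    "cpz_equiv",
    "exercise",
    "somatic_history",
    "tobacco",
)


class GeometryError(ValueError):
    """Grid shape or affine mismatch between volumes."""


class ValidationError(ValueError):
    """Malformed input data (table or volume)."""


@dataclasses.dataclass
class GMVImage:
    """A 3-D gray-matter-volume image with a voxel-to-world (RAS) affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError(f"expected 3-D data, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")
        if not np.isfinite(self.data).all():
            raise ValidationError("image contains non-finite voxels")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValidationError("affine is singular")

    @property
    def voxel_size_mm(self) -> tuple[float, float, float]:
        sizes = np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))
        return tuple(float(s) for s in sizes)

    def to_nifti(self, path: str | Path) -> Path:
        path = Path(path)
        nib.save(nib.Nifti1Image(self.data, self.affine), str(path))
        return path

    @classmethod
    def from_nifti(cls, path: str | Path) -> "GMVImage":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj, dtype=float), np.asarray(img.affine))


@dataclasses.dataclass
class VoxelMask:
    """Boolean brain mask defining the feature space.

    Canonical feature ordering is ascending linear index in C order of the
    mask volume; feature column *j* always refers to the same voxel.
    """

    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.mask.ndim != 3:
            raise ValidationError("mask must be 3-D")
        if self.n_features < 1:
            raise ValidationError("mask selects no voxels")

    @property
    def n_features(self) -> int:
        return int(self.mask.sum())

    @property
    def ordering(self) -> np.ndarray:
        """Linear indices (C order) of in-mask voxels, ascending."""
        return np.flatnonzero(self.mask.ravel(order="C"))

    def apply(self, image: GMVImage) -> np.ndarray:
        """Extract the masked voxels of ``image`` as a feature vector."""
        _check_geometry(image, self)
        return image.data.ravel(order="C")[self.ordering].astype(float)

    def to_nifti(self, path: str | Path) -> Path:
        path = Path(path)
        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), self.affine), str(path))
        return path

    @classmethod
    def from_nifti(cls, path: str | Path) -> "VoxelMask":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj) > 0, np.asarray(img.affine))


def _check_geometry(image: GMVImage, mask: VoxelMask) -> None:
    if image.data.shape != mask.mask.shape:
        raise GeometryError(
            f"image shape {image.data.shape} != mask shape {mask.mask.shape}"
        )
    if not np.allclose(image.affine, mask.affine, atol=AFFINE_ATOL):
        raise GeometryError("image affine differs from mask affine beyond tolerance")


def read_gmv_set(
    images: Sequence[GMVImage | str | Path], mask: VoxelMask
) -> np.ndarray:
    """Stack masked feature vectors, one row per image, in input order."""
    rows = []
    for item in images:
        img = GMVImage.from_nifti(item) if isinstance(item, (str, Path)) else item
        rows.append(mask.apply(img))
    if not rows:
        raise ValidationError("empty image list")
    return np.vstack(rows)


def vector_to_volume(v: np.ndarray, mask: VoxelMask) -> GMVImage:
    """Inverse of masking: place ``v`` at in-mask voxels, zeros elsewhere."""
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size != mask.n_features:
        raise ValidationError(
            f"vector length {v.size} != mask n_features {mask.n_features}"
        )
    flat = np.zeros(mask.mask.size, dtype=float)
    flat[mask.ordering] = v
    return GMVImage(flat.reshape(mask.mask.shape), mask.affine)


_YES_NO = {"yes": True, "no": False, "true": True, "false": False, "1": True, "0": False}


def _coerce_flag(series: pd.Series) -> pd.Series:
    def conv(x):
        if pd.isna(x):
            return np.nan
        if isinstance(x, (bool, np.bool_)):
            return bool(x)
        s = str(x).strip().lower()
        if s in _YES_NO:
            return _YES_NO[s]
        return np.nan

    return series.map(conv)


def load_cohort(
    path: str | Path | pd.DataFrame,
    bmi_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Load and validate a cohort TSV.

    Missing optional fields are preserved as NaN.  ``bmi_range``, when given,
    rejects rows whose measured BMI falls outside the closed interval and
    names them in the error.
    """
    if isinstance(path, pd.DataFrame):
        df = path.copy()
    else:
        df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "site": str})

    missing = [c for c in COHORT_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")

    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate subject_id: {sorted(dup.unique())}")

    bad_group = df.loc[~df["group"].isin(GROUPS), "subject_id"]
    if len(bad_group):
        raise ValidationError(f"unknown group label for subjects: {list(bad_group)}")

    bad_sex = df.loc[~df["sex"].isin(["F", "M"]), "subject_id"]
    if len(bad_sex):
        raise ValidationError(f"sex must be F or M for subjects: {list(bad_sex)}")

    for col in ("age", "bmi_measured", "weight_t0", "weight_t1", "weight_t2",
                "panss_total", "age_at_onset", "illness_duration",
                "n_hospitalizations", "cpz_equiv"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")

    bmi = df["bmi_measured"]
    hard_bad = df.loc[bmi.notna() & ((bmi < 10) | (bmi > 60)), "subject_id"]
    if len(hard_bad):
        raise ValidationError(
            f"bmi_measured outside plausible [10, 60] for subjects: {list(hard_bad)}"
        )
    if bmi_range is not None:
        lo, hi = bmi_range
        out = df.loc[bmi.notna() & ((bmi < lo) | (bmi > hi)), "subject_id"]
        if len(out):
            raise ValidationError(
                f"bmi_measured outside [{lo}, {hi}] for subjects: {list(out)}"
            )

    for col in ("weight_t0", "weight_t1", "weight_t2"):
        if col in df.columns:
            bad = df.loc[df[col].notna() & (df[col] <= 0), "subject_id"]
            if len(bad):
                raise ValidationError(f"non-positive {col} for subjects: {list(bad)}")

    if "split" in df.columns:
        known = df["split"].isna() | df["split"].isin(SPLITS)
        if not known.all():
            raise ValidationError(
                f"unknown split labels: {sorted(df.loc[~known, 'split'].unique())}"
            )

    for col in ("antipsychotic_naive", "antidepressant_naive", "exercise",
                "somatic_history", "tobacco"):
        if col in df.columns:
            df[col] = _coerce_flag(df[col])

    for col in COHORT_OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan

    return df.reset_index(drop=True)


def write_cohort(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path
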