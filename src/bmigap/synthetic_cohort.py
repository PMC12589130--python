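"""Phantom GMV cohorts with planted, recoverable structure.

Generates desk-scale gray-matter-volume volumes plus a phenotype table in
which a spatial pattern is linearly coupled to BMI, a partially overlapping
pattern is coupled to disease load, each subject carries a planted gap
(group shift + individual deviate) expressed in the image as an effective
"brain BMI" of ``bmi + gap_true``, and follow-up weights whose 2-year change
correlates with the planted gap at a configurable level.

Everything is a pure function of the spec and its seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .imaging_io import GROUPS, GMVImage, ValidationError, VoxelMask, write_cohort

__all__ = ["PhantomSpec", "GroundTruth", "SyntheticCohort", "generate_cohort",
           "clinical_fields", "write_cohort_to_dir"]


class SizingError(ValueError):
    """Grid too small for the requested planted supports."""


@dataclasses.dataclass
class PhantomSpec:
    """Design of a synthetic cohort.

    ``beta_bmi`` is the GMV decrease per BMI unit along the planted unit-norm
    BMI pattern; ``group_shift`` is the planted gap effect in BMI units.
    """

    grid_shape: tuple[int, int, int] = (16, 16, 16)
    voxel_size_mm: float = 3.0
    n_per_group: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {"HC": 400, "SCZ": 80, "CHR": 80, "ROD": 80}
    )
    sites: Sequence[tuple[str, float]] = (
        ("SITE_A", 0.0), ("SITE_B", 0.06), ("SITE_C", -0.05)
    )
    bmi_range: tuple[float, float] = (18.5, 35.0)
    age_range: tuple[float, float] = (15.0, 75.0)
    beta_bmi: float = 0.02
    beta_age: float = 0.004
    group_shift: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"HC": 0.0, "SCZ": 1.0, "CHR": 0.5, "ROD": -0.8}
    )
    overlap_fraction: float = 0.25
    noise_sd: float = 0.015
    dw_coupling: float = 0.4
    seed: int = 0
    # secondary knobs (defaults documented, rarely touched)
    gap_sd: float = 0.75
    dx_load: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"HC": 0.0, "SCZ": 1.0, "CHR": 0.4, "ROD": 0.2}
    )
    beta_dx: float = 0.02
    support_fraction_bmi: float = 0.25
    support_fraction_dx: float = 0.08
    dw_scale_kg: float = 1.5
    followup_fraction: float = 1.0

    def validate(self) -> None:
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValidationError("group counts must be >= 0")
        unknown = set(self.n_per_group) - set(GROUPS)
        if unknown:
            raise ValidationError(f"unknown group labels: {sorted(unknown)}")
        lo, hi = self.bmi_range
        if not (10.0 <= lo < hi <= 60.0):
            raise ValidationError("bmi_range must lie within [10, 60]")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValidationError("overlap_fraction must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")


@dataclasses.dataclass
class GroundTruth:
    """Planted quantities used by the recovery oracles downstream."""

    w_bmi: np.ndarray          # unit-norm pattern over masked voxels
    w_dx: np.ndarray           # unit-norm disease pattern, <w_dx, w_bmi> = 0
    gap_true: np.ndarray       # per subject, aligned with the table rows
    site_offset_true: dict[str, float]
    w_age: np.ndarray = None   # nuisance age pattern (not assessed downstream)


@dataclasses.dataclass
class SyntheticCohort:
    images: list[GMVImage]
    table: pd.DataFrame
    truth: GroundTruth
    mask: VoxelMask


def _make_mask(shape: tuple[int, int, int]) -> np.ndarray:
    grid = np.indices(shape).astype(float)
    center = (np.asarray(shape, float) - 1) / 2.0
    radii = np.asarray(shape, float) * 0.45
    d2 = sum(((grid[i] - center[i]) / radii[i]) ** 2 for i in range(3))
    return d2 <= 1.0


def _blob_values(mask_idx: np.ndarray, shape, center_vox, size, rng) -> np.ndarray:
    """Pick the `size` in-mask voxels nearest to `center_vox`; Gaussian bump values."""
    coords = np.column_stack(np.unravel_index(mask_idx, shape)).astype(float)
    d = np.linalg.norm(coords - np.asarray(center_vox, float), axis=1)
    order = np.argsort(d, kind="stable")[:size]
    sigma = max(d[order].max(), 1.0) / 1.5
    vals = np.zeros(len(mask_idx))
    vals[order] = np.exp(-0.5 * (d[order] / sigma) ** 2)
    return vals


def _planted_patterns(spec: PhantomSpec, mask: np.ndarray, rng: np.random.Generator):
    """Contiguous-blob patterns; dx support overlaps bmi support by the spec fraction."""
    mask_idx = np.flatnonzero(mask.ravel(order="C"))
    p = len(mask_idx)
    s_bmi = max(int(round(spec.support_fraction_bmi * p)), 10)
    s_dx = max(int(round(spec.support_fraction_dx * p)), 10)
    if p < 50 or s_bmi + s_dx > p:
        raise SizingError(
            f"grid too small: {p} masked voxels cannot hold supports "
            f"{s_bmi}+{s_dx} (need >= 50 masked voxels)"
        )
    shape = mask.shape
    coords = np.column_stack(np.unravel_index(mask_idx, shape)).astype(float)
    centroid = coords.mean(axis=0)
    span = coords.max(axis=0) - coords.min(axis=0)

    # BMI pattern: two opposite-signed blobs left/right of centroid
    c_pos = centroid + np.array([-span[0] / 4, 0, 0])
    c_neg = centroid + np.array([span[0] / 4, 0, 0])
    half = s_bmi // 2
    v_pos = _blob_values(mask_idx, shape, c_pos, half, rng)
    v_neg = _blob_values(mask_idx, shape, c_neg, s_bmi - half, rng)
    # resolve any accidental support collision deterministically
    v_neg[v_pos > 0] = 0.0
    w_bmi = v_pos - v_neg
    w_bmi /= np.linalg.norm(w_bmi)
    bmi_support = np.flatnonzero(w_bmi)

    # disease pattern: one blob centred so that its nearest-voxel support
    # contains round(overlap_fraction * s_dx) voxels of the BMI support
    n_overlap = int(round(spec.overlap_fraction * s_dx))
    d_to_pos = np.linalg.norm(coords - c_pos, axis=1)
    inside = bmi_support[np.argsort(d_to_pos[bmi_support], kind="stable")[:n_overlap]]
    outside_pool = np.setdiff1d(np.arange(p), bmi_support)
    c_dx = centroid + np.array([0, span[1] / 4, 0])
    d_dx = np.linalg.norm(coords - c_dx, axis=1)
    outside = outside_pool[np.argsort(d_dx[outside_pool], kind="stable")[: s_dx - n_overlap]]
    support_dx = np.concatenate([inside, outside])
    w_dx = np.zeros(p)
    sigma = max(np.median(d_dx[support_dx]), 1.0)
    w_dx[support_dx] = np.exp(-0.5 * (d_dx[support_dx] / sigma) ** 2) + 0.05
    # orthogonalise against w_bmi on the shared support only (keeps supports exact)
    if n_overlap > 0:
        ip = float(w_dx @ w_bmi)
        denom = float(w_bmi[inside] @ w_bmi[inside])
        if denom > 0:
            sub = w_dx[inside] - ip / denom * w_bmi[inside]
            sub[sub == 0.0] = 1e-9  # preserve support size
            w_dx[inside] = sub
    w_dx /= np.linalg.norm(w_dx)

    # age nuisance pattern: blob elsewhere
    c_age = centroid + np.array([0, -span[1] / 4, 0])
    w_age = _blob_values(mask_idx, shape, c_age, s_dx, rng)
    nrm = np.linalg.norm(w_age)
    if nrm > 0:
        w_age /= nrm
    return w_bmi, w_dx, w_age


def generate_cohort(spec: PhantomSpec) -> SyntheticCohort:
    """Generate images, phenotype table and ground truth for ``spec``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.grid_shape)
    mask_arr = _make_mask(shape)
    affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * spec.voxel_size_mm
    mask = VoxelMask(mask_arr, affine)
    ordering = mask.ordering

    w_bmi, w_dx, w_age = _planted_patterns(spec, mask_arr, rng)

    # smooth random anatomy template, fixed per seed
    template = gaussian_filter(rng.standard_normal(shape), sigma=2.0)
    template = 0.5 + 0.1 * template / max(template.std(), 1e-12)
    template_masked = template.ravel(order="C")[ordering]

    site_names = [s for s, _ in spec.sites]
    site_offset = {s: float(o) for s, o in spec.sites}

    groups = [g for g in GROUPS if spec.n_per_group.get(g, 0) > 0]
    rows = []
    for g in groups:
        for i in range(int(spec.n_per_group[g])):
            rows.append(g)
    n = len(rows)
    if n == 0:
        raise ValidationError("empty cohort")

    lo_b, hi_b = spec.bmi_range
    lo_a, hi_a = spec.age_range
    group = np.array(rows)
    site = np.array(site_names)[rng.integers(0, len(site_names), size=n)]
    age = rng.uniform(lo_a, hi_a, size=n)
    sex = np.where(rng.random(n) < 0.5, "F", "M")
    bmi = rng.uniform(lo_b, hi_b, size=n)
    shift = np.array([spec.group_shift.get(g, 0.0) for g in group])
    gap_true = shift + spec.gap_sd * rng.standard_normal(n)
    dx = np.array([spec.dx_load.get(g, 0.0) for g in group])
    dx = dx * (1.0 + 0.1 * rng.standard_normal(n))

    age_mid = (lo_a + hi_a) / 2.0
    images: list[GMVImage] = []
    for i in range(n):
        vec = (
            template_masked
            - spec.beta_bmi * (bmi[i] + gap_true[i]) * w_bmi
            - spec.beta_dx * dx[i] * w_dx
            + spec.beta_age * (age[i] - age_mid) * w_age
            + site_offset[site[i]]
            + spec.noise_sd * rng.standard_normal(mask.n_features)
        )
        flat = np.zeros(mask_arr.size)
        flat[ordering] = vec
        images.append(GMVImage(flat.reshape(shape), affine))

    # follow-up weights: dW2 affine in the planted gap, tuned to dw_coupling
    height = np.clip(rng.normal(1.70, 0.09, size=n), 1.4, 2.1)
    weight_t0 = bmi * height**2
    gap_c = gap_true - gap_true.mean()
    sd_gap = max(gap_c.std(), 1e-12)

    def _coupled_dw(target_r: float, lam_kg: float, rng: np.random.Generator):
        if abs(target_r) < 1e-12:
            return 2.0 * rng.standard_normal(n)
        lam = np.sign(target_r) * lam_kg
        sd_eps = abs(lam) * sd_gap * np.sqrt(max(1.0 / target_r**2 - 1.0, 0.0))
        return lam * gap_c + sd_eps * rng.standard_normal(n)

    dw2 = _coupled_dw(spec.dw_coupling, spec.dw_scale_kg, rng)
    dw1 = _coupled_dw(0.6 * spec.dw_coupling, 0.6 * spec.dw_scale_kg, rng)
    weight_t1 = weight_t0 + dw1
    weight_t2 = weight_t0 + dw2
    if spec.followup_fraction < 1.0:
        drop = rng.random(n) >= spec.followup_fraction
        weight_t1 = np.where(drop, np.nan, weight_t1)
        weight_t2 = np.where(drop, np.nan, weight_t2)

    table = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:05d}" for i in range(n)],
            "site": site,
            "group": group,
            "age": age,
            "sex": sex,
            "bmi_measured": bmi,
            "weight_t0": weight_t0,
            "weight_t1": weight_t1,
            "weight_t2": weight_t2,
        }
    )
    truth = GroundTruth(
        w_bmi=w_bmi, w_dx=w_dx, gap_true=gap_true,
        site_offset_true=site_offset, w_age=w_age,
    )
    return SyntheticCohort(images=images, table=table, truth=truth, mask=mask)


def clinical_fields(
    table: pd.DataFrame,
    seed: int,
    gap_true: np.ndarray | None = None,
    clinical_coupling: float = 0.3,
    prevalences: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Add clinical scores, medication flags and lifestyle flags.

    Disease-group rows receive PANSS total, age at onset, illness duration and
    hospitalisation counts correlated with ``gap_true`` at
    ``clinical_coupling``; HC rows keep missing markers.  Flags are Bernoulli
    at the given prevalences.
    """
    if "group" not in table.columns:
        raise ValidationError("table lacks group labels")
    prev = {
        "antipsychotic_naive": 0.6,
        "antidepressant_naive": 0.5,
        "weightgain_med": 0.5,
        "exercise": 0.5,
        "somatic_history": 0.3,
        "tobacco": 0.35,
    }
    if prevalences:
        prev.update(prevalences)
    rng = np.random.default_rng(seed)
    out = table.copy()
    n = len(out)
    is_dx = out["group"].isin(["SCZ", "CHR", "ROD"]).to_numpy()

    if gap_true is None:
        g = rng.standard_normal(n)
    else:
        g = np.asarray(gap_true, float)
    gz = (g - g.mean()) / max(g.std(), 1e-12)
    rho = float(np.clip(clinical_coupling, -1.0, 1.0))

    def coupled(loc, scale, lo=None):
        z = rho * gz + np.sqrt(max(1 - rho**2, 0.0)) * rng.standard_normal(n)
        vals = loc + scale * z
        if lo is not None:
            vals = np.maximum(vals, lo)
        return np.where(is_dx, vals, np.nan)

    out["panss_total"] = coupled(50.0, 20.0, lo=30.0)
    out["age_at_onset"] = coupled(24.0, 6.0, lo=12.0)
    out["illness_duration"] = coupled(4.0, 3.0, lo=0.0)
    out["n_hospitalizations"] = np.where(
        is_dx, np.round(np.maximum(coupled(2.0, 1.5), 0.0)), np.nan
    )

    for col in ("antipsychotic_naive", "antidepressant_naive"):
        flag = rng.random(n) < prev[col]
        out[col] = np.where(is_dx, flag, np.nan)
    wg = np.where(rng.random(n) < prev["weightgain_med"], "yes", "neutral_or_none")
    out["weightgain_med"] = np.where(is_dx, wg, "unknown")
    for col in ("exercise", "somatic_history", "tobacco"):
        out[col] = rng.random(n) < prev[col]
    cpz = np.maximum(rng.normal(350.0, 250.0, size=n), 0.0)
    out["cpz_equiv"] = np.where(out["group"].eq("SCZ"), cpz, np.nan)
    return out


def write_cohort_to_dir(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write per-subject NIfTI files, mask, table TSV and truth sidecar."""
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    paths = []
    for sid, img in zip(cohort.table["subject_id"], cohort.images):
        p = outdir / "images" / f"{sid}_gmv.nii.gz"
        img.to_nifti(p)
        paths.append(str(p.relative_to(outdir)))
    cohort.mask.to_nifti(outdir / "mask.nii.gz")
    tbl = cohort.table.copy()
    tbl["image_path"] = paths
    write_cohort(tbl, outdir / "cohort.tsv")
    truth = {
        "w_bmi": cohort.truth.w_bmi.tolist(),
        "w_dx": cohort.truth.w_dx.tolist(),
        "w_age": cohort.truth.w_age.tolist(),
        "gap_true": cohort.truth.gap_true.tolist(),
        "site_offset_true": cohort.truth.site_offset_true,
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth))
    return outdir
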