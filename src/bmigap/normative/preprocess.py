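"""Feature preprocessing chain, fitted on training rows only.

Order is fixed by construction: (1) Gaussian smoothing (a per-image
operation, applied before masking), (2) per-feature age residualisation,
(3) per-site mean-offset correction, (4) PCA at an energy level,
(5) per-component min-max scaling to [0, 1] with clipping.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from ..imaging_io import GMVImage, ValidationError, VoxelMask, read_gmv_set

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def smooth(image: GMVImage, fwhm_mm: float) -> GMVImage:
    """Gaussian-smooth a volume; fwhm 0 is the identity."""
    if fwhm_mm < 0:
        raise ValidationError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return GMVImage(image.data.copy(), image.affine.copy())
    sigmas = [fwhm_mm * FWHM_TO_SIGMA / vs for vs in image.voxel_size_mm]
    # nearest-edge padding: constant volumes are exactly invariant
    return GMVImage(gaussian_filter(image.data, sigma=sigmas, mode="nearest"),
                    image.affine.copy())


def smoothed_feature_sets(
    images: Sequence[GMVImage],
    mask: VoxelMask,
    fwhms: Sequence[float],
) -> dict[float, np.ndarray]:
    """Precompute the masked feature matrix for every smoothing width.

    Smoothing has no fitted parameters, so this is safely shared between
    training and test rows.
    """
    out: dict[float, np.ndarray] = {}
    for fwhm in fwhms:
        out[float(fwhm)] = read_gmv_set([smooth(im, fwhm) for im in images], mask)
    return out


def fit_apply_residualize(
    X_train: np.ndarray,
    age_train: np.ndarray,
    X_apply: np.ndarray | None = None,
    age_apply: np.ndarray | None = None,
):
    """Per-feature OLS of feature on age (with intercept), fitted on train.

    Returns ``(resid_train, resid_apply, slope, intercept)``; the same fitted
    line is subtracted from apply rows (extrapolated, never clamped).
    """
    age_train = np.asarray(age_train, float)
    if not np.isfinite(age_train).all():
        raise ValidationError("non-finite ages")
    if len(age_train) < 3:
        raise ValidationError("need >= 3 training rows to residualize")
    a = age_train - age_train.mean()
    denom = float(a @ a)
    if denom < 1e-12:
        warnings.warn("zero age variance in train; residualization skipped")
        slope = np.zeros(X_train.shape[1])
        intercept = np.zeros(X_train.shape[1])
    else:
        slope = (a @ X_train) / denom
        intercept = X_train.mean(axis=0) - slope * age_train.mean()
    rt = X_train - np.outer(age_train, slope) - intercept
    ra = None
    if X_apply is not None:
        ra = X_apply - np.outer(np.asarray(age_apply, float), slope) - intercept
    return rt, ra, slope, intercept


def fit_apply_site_offset(
    X_train: np.ndarray,
    sites_train: Sequence[str],
    X_apply: np.ndarray | None = None,
    sites_apply: Sequence[str] | None = None,
):
    """Subtract per-site (site mean - grand mean), estimated on train.

    Apply rows from sites unseen in training receive a zero offset.
    Returns ``(corr_train, corr_apply, offsets)``.
    """
    sites_train = np.asarray(sites_train)
    grand = X_train.mean(axis=0)
    offsets: dict[str, np.ndarray] = {}
    Xt = X_train.copy()
    for s in np.unique(sites_train):
        rows = sites_train == s
        off = X_train[rows].mean(axis=0) - grand
        offsets[str(s)] = off
        Xt[rows] -= off
    Xa = None
    if X_apply is not None:
        Xa = X_apply.copy()
        for i, s in enumerate(np.asarray(sites_apply)):
            off = offsets.get(str(s))
            if off is not None:
                Xa[i] -= off
    return Xt, Xa, offsets


def fit_apply_pca(
    X_train: np.ndarray,
    energy: float,
    X_apply: np.ndarray | None = None,
):
    """Train-mean-centred PCA keeping the smallest k with cumulative
    explained-variance ratio >= energy.

    Returns ``(scores_train, scores_apply, mean, components)`` with
    ``components`` of shape (k, p).
    """
    if not (0.0 < energy <= 1.0):
        raise ValidationError("energy must be in (0, 1]")
    if X_train.shape[0] < 2:
        raise ValidationError("need >= 2 training rows for PCA")
    mean = X_train.mean(axis=0)
    Xc = X_train - mean
    # economy SVD: n << p in the imaging setting
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    tot = var.sum()
    if tot <= 0:
        components = Vt[:1] * 0.0
    else:
        ratio = np.cumsum(var) / tot
        tol = 1e-10
        k = int(np.searchsorted(ratio, energy - tol) + 1)
        k = min(k, int((s > s[0] * 1e-12).sum()) if s.size else 1)
        k = max(k, 1)
        components = Vt[:k]
    st = Xc @ components.T
    sa = None
    if X_apply is not None:
        sa = (X_apply - mean) @ components.T
    return st, sa, mean, components


def fit_apply_scale(
    S_train: np.ndarray,
    S_apply: np.ndarray | None = None,
):
    """Per-column min-max from train mapped to [0, 1]; apply values clipped.

    Zero-range columns map to 0.  Returns ``(Z_train, Z_apply, lo, hi)``.
    """
    lo = S_train.min(axis=0)
    hi = S_train.max(axis=0)
    rng = hi - lo
    safe = np.where(rng > 0, rng, 1.0)

    def _scale(S):
        Z = (S - lo) / safe
        Z[:, rng <= 0] = 0.0
        return np.clip(Z, 0.0, 1.0)

    Zt = _scale(S_train)
    Za = _scale(S_apply) if S_apply is not None else None
    return Zt, Za, lo, hi


@dataclasses.dataclass
class PreprocState:
    """Fitted parameters of chain stages (2)-(5) for one training partition."""

    fwhm: float
    energy: float
    age_slope: np.ndarray
    age_intercept: np.ndarray
    site_offsets: dict[str, np.ndarray]
    pca_mean: np.ndarray
    pca_components: np.ndarray  # (k, p)
    scale_lo: np.ndarray
    scale_hi: np.ndarray

    @property
    def n_components(self) -> int:
        return self.pca_components.shape[0]


def fit_preproc(
    X_train: np.ndarray,
    age_train: np.ndarray,
    sites_train: Sequence[str],
    fwhm: float,
    energy: float,
) -> tuple[PreprocState, np.ndarray]:
    """Fit stages (2)-(5) on training rows; returns state + train scores."""
    Rt, _, slope, intercept = fit_apply_residualize(X_train, age_train)
    Ct, _, offsets = fit_apply_site_offset(Rt, sites_train)
    St, _, mean, comps = fit_apply_pca(Ct, energy)
    Zt, _, lo, hi = fit_apply_scale(St)
    state = PreprocState(
        fwhm=float(fwhm), energy=float(energy),
        age_slope=slope, age_intercept=intercept,
        site_offsets=offsets, pca_mean=mean, pca_components=comps,
        scale_lo=lo, scale_hi=hi,
    )
    return state, Zt


def apply_preproc(
    state: PreprocState,
    X: np.ndarray,
    age: np.ndarray,
    sites: Sequence[str],
) -> np.ndarray:
    """Apply a fitted chain to new rows (no parameter re-estimation)."""
    R = X - np.outer(np.asarray(age, float), state.age_slope) - state.age_intercept
    for i, s in enumerate(np.asarray(sites)):
        off = state.site_offsets.get(str(s))
        if off is not None:
            R[i] -= off
    S = (R - state.pca_mean) @ state.pca_components.T
    rng = state.scale_hi - state.scale_lo
    safe = np.where(rng > 0, rng, 1.0)
    Z = (S - state.scale_lo) / safe
    Z[:, rng <= 0] = 0.0
    return np.clip(Z, 0.0, 1.0)
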