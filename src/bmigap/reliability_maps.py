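"""Voxel-space reliability of cross-validated linear models.

Back-projects component-space model weights to voxels, computes
cross-validation-ratio (CVR) maps, exact-binomial sign-based consistency
maps with Benjamini-Hochberg FDR, binarized masks and overlap statistics.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .imaging_io import ValidationError
from .normative.train import FoldModel, TrainedEnsemble

CVR_CAP = 1e6  # zero-variance guard; keeps exported maps finite

__all__ = ["VoxelStatMap", "backproject", "ensemble_weight_vectors", "cvr_map",
           "sign_consistency_map", "threshold_and_binarize", "overlap_maps"]


@dataclasses.dataclass
class VoxelStatMap:
    kind: str                      # weight_mean | cvr | sign_z | binary
    values: np.ndarray             # over masked voxels
    threshold_meta: dict | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind == "binary":
            uniq = set(np.unique(self.values))
            if not uniq <= {0.0, 1.0}:
                raise ValidationError("binary map must take values {0, 1}")


def backproject(model: FoldModel) -> np.ndarray:
    """Map component-space linear weights back to voxel space.

    The fitted chain after PCA is affine per component
    (z = (s - lo) / (hi - lo), clipping ignored for the direction), so the
    voxel-space direction is components^T (coef / range).  Smoothing, age and
    site steps are affine in the features and contribute nothing.
    """
    state = model.state
    rng = state.scale_hi - state.scale_lo
    safe = np.where(rng > 0, rng, 1.0)
    w_comp = model.coef / safe
    w_comp = np.where(rng > 0, w_comp, 0.0)
    return state.pca_components.T @ w_comp


def ensemble_weight_vectors(ensemble: TrainedEnsemble) -> np.ndarray:
    """(n_models, n_voxels) back-projected weights, one row per CV model."""
    return np.vstack([backproject(m) for m in ensemble.models])


def cvr_map(weight_vectors: np.ndarray) -> VoxelStatMap:
    """Per voxel: mean(w) / (sd(w) / sqrt(M)) across the M CV models.

    sd = 0 is guarded: sign(mean) * CAP (0 if the mean is also 0).
    """
    W = np.asarray(weight_vectors, dtype=float)
    if W.ndim != 2 or W.shape[0] < 2:
        raise ValidationError("need >= 2 model weight vectors")
    M = W.shape[0]
    mean = W.mean(axis=0)
    sd = W.std(axis=0, ddof=1)
    se = sd / np.sqrt(M)
    with np.errstate(divide="ignore", invalid="ignore"):
        cvr = mean / se
    degenerate = se == 0
    cvr[degenerate] = np.sign(mean[degenerate]) * CVR_CAP
    return VoxelStatMap(kind="cvr", values=cvr)


def sign_consistency_map(
    weight_vectors: np.ndarray,
    alpha: float = 0.05,
) -> VoxelStatMap:
    """Exact two-sided binomial test of sign agreement across CV models.

    Per voxel, k = #{models with w > 0} of M is tested against p0 = 0.5;
    p-values are BH-FDR adjusted over the masked voxels.  Surviving voxels
    keep the majority sign (+1/-1), others are 0.
    """
    W = np.asarray(weight_vectors, dtype=float)
    if W.ndim != 2 or W.shape[0] < 2:
        raise ValidationError("need >= 2 model weight vectors")
    M = W.shape[0]
    k = (W > 0).sum(axis=0)
    # two-sided exact binomial at p0=0.5: symmetric, p = 2*min(cdf, sf+pmf)
    lower = stats.binom.cdf(k, M, 0.5)
    upper = stats.binom.sf(k - 1, M, 0.5)
    p_raw = np.minimum(2.0 * np.minimum(lower, upper), 1.0)
    reject, p_adj, _, _ = multipletests(p_raw, alpha=alpha, method="fdr_bh")
    sign = np.where(k > M - k, 1.0, -1.0)
    sign[k * 2 == M] = 0.0
    values = np.where(reject, sign, 0.0)
    return VoxelStatMap(
        kind="sign_z", values=values,
        threshold_meta={"alpha": alpha, "method": "fdr_bh", "M": M,
                        "p_raw": p_raw, "p_adj": p_adj},
    )


def threshold_and_binarize(cvr: VoxelStatMap, sign_map: VoxelStatMap) -> VoxelStatMap:
    """Binary map of voxels surviving the sign-consistency threshold."""
    if cvr.values.shape != sign_map.values.shape:
        raise ValidationError("map shapes differ")
    binary = (sign_map.values != 0).astype(float)
    meta = dict(sign_map.threshold_meta or {})
    meta["cvr_masked"] = np.where(binary > 0, cvr.values, 0.0)
    return VoxelStatMap(kind="binary", values=binary, threshold_meta=meta)


def overlap_maps(a: VoxelStatMap, b: VoxelStatMap) -> tuple[VoxelStatMap, dict]:
    """Voxelwise AND of two binary maps plus overlap statistics (incl. Dice)."""
    if a.values.shape != b.values.shape:
        raise ValidationError("map shapes differ")
    for m in (a, b):
        if m.kind != "binary":
            raise ValidationError("overlap requires binary maps")
    inter = ((a.values > 0) & (b.values > 0)).astype(float)
    na, nb, ni = int(a.values.sum()), int(b.values.sum()), int(inter.sum())
    dice = 2.0 * ni / (na + nb) if (na + nb) > 0 else 0.0
    stats_d = {"n_a": na, "n_b": nb, "n_intersection": ni, "dice": dice}
    return VoxelStatMap(kind="binary", values=inter), stats_d
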