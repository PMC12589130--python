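"""Sparse partial least squares between a clinical feature block and an
overlap-region voxel block.

Saliences are extracted by alternating power iterations on the cross-product
matrix with projection onto an L1 ball (soft-thresholding, bisection on the
threshold), projection deflation between latent variables (LVs), row
permutation tests for LV reliability and bootstrap ratios for salience
stability.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .imaging_io import ValidationError
from .normative.stats import permutation_pvalue

log = logging.getLogger(__name__)

BSR_CAP = 1e6
CLINICAL_COLUMNS = ["bmigap_corrected", "dx_expression_score", "panss_total",
                    "age_at_onset", "illness_duration", "n_hospitalizations"]

__all__ = ["ClinicalMatrix", "SPLSResult", "build_clinical_matrix", "spls_fit",
           "lv_permutation_test", "bootstrap_ratios", "select_sparsity",
           "CLINICAL_COLUMNS"]


@dataclasses.dataclass
class ClinicalMatrix:
    values: np.ndarray            # (n, 6), standardized
    subject_ids: list[str]
    columns: list[str]
    means: np.ndarray
    sds: np.ndarray


@dataclasses.dataclass
class LatentVariable:
    u: np.ndarray                 # clinical saliences, unit L2
    v: np.ndarray                 # voxel saliences, unit L2
    rho: float                    # corr(Xu, Yv)
    converged: bool
    n_iter: int
    X_deflated: np.ndarray        # block states *before* extracting this LV
    Y_deflated: np.ndarray


@dataclasses.dataclass
class SPLSResult:
    lvs: list[LatentVariable]
    c_u: float
    c_v: float
    permutation_p: list[float] | None = None
    bootstrap_u: np.ndarray | None = None   # (n_lv, 6) BSRs
    bootstrap_v: np.ndarray | None = None


def build_clinical_matrix(
    table: pd.DataFrame,
    gaps: pd.DataFrame,
    dx_scores: pd.Series,
    groups: Sequence[str] = ("SCZ",),
) -> ClinicalMatrix:
    """Standardized six-feature matrix for disease-group subjects.

    Rows with any missing feature are listwise deleted (and logged).
    """
    df = table[table["group"].isin(groups)][
        ["subject_id", "panss_total", "age_at_onset", "illness_duration",
         "n_hospitalizations"]
    ].merge(
        gaps[["subject_id", "gap_corrected"]].rename(
            columns={"gap_corrected": "bmigap_corrected"}),
        on="subject_id")
    df["dx_expression_score"] = df["subject_id"].map(dx_scores)
    df = df[["subject_id"] + CLINICAL_COLUMNS]
    complete = df.dropna()
    n_drop = len(df) - len(complete)
    if n_drop:
        log.warning("listwise deletion removed %d incomplete rows", n_drop)
    if len(complete) < 10:
        raise ValidationError(f"only {len(complete)} complete rows (< 10)")
    vals = complete[CLINICAL_COLUMNS].to_numpy(float)
    means = vals.mean(axis=0)
    sds = vals.std(axis=0, ddof=0)
    if (sds < 1e-12).any():
        raise ValidationError("constant clinical column")
    z = (vals - means) / sds
    return ClinicalMatrix(values=z, subject_ids=list(complete["subject_id"]),
                          columns=list(CLINICAL_COLUMNS), means=means, sds=sds)


def _soft(a: np.ndarray, delta: float) -> np.ndarray:
    return np.sign(a) * np.maximum(np.abs(a) - delta, 0.0)


def _l1_ball_unit(a: np.ndarray, c: float) -> np.ndarray:
    """Unit-L2 vector proportional to soft-thresholded ``a`` with L1 norm <= c."""
    nrm = np.linalg.norm(a)
    if nrm == 0:
        return a.copy()
    u = a / nrm
    if np.abs(u).sum() <= c + 1e-12:
        return u
    lo, hi = 0.0, float(np.abs(a).max())
    for _ in range(60):
        mid = (lo + hi) / 2.0
        s = _soft(a, mid)
        ns = np.linalg.norm(s)
        if ns == 0 or np.abs(s).sum() / ns > c:
            lo = mid
        else:
            hi = mid
    s = _soft(a, hi)
    ns = np.linalg.norm(s)
    if ns == 0:  # fall back to the 1-sparse vertex
        s = np.zeros_like(a)
        s[int(np.argmax(np.abs(a)))] = np.sign(a[int(np.argmax(np.abs(a)))])
        return s
    return s / ns


def _orient(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fix the joint sign so the largest-magnitude clinical salience is positive."""
    j = int(np.argmax(np.abs(u)))
    if u[j] < 0:
        return -u, -v
    return u, v


def _fit_one_lv(X: np.ndarray, Y: np.ndarray, c_u: float, c_v: float,
                tol: float = 1e-6, max_iter: int = 500,
                v_init: np.ndarray | None = None):
    """One sparse LV by alternating L1-projected power iterations on X^T Y."""
    M = X.T @ Y
    if v_init is None:
        # dominant right singular direction as the starting point
        _, _, Vt = np.linalg.svd(M, full_matrices=False)
        v = Vt[0]
    else:
        v = v_init / max(np.linalg.norm(v_init), 1e-12)
    u = np.zeros(X.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        u_new = _l1_ball_unit(M @ v, c_u)
        v_new = _l1_ball_unit(M.T @ u_new, c_v)
        if max(np.abs(u_new - u).max(), np.abs(v_new - v).max()) < tol:
            u, v = u_new, v_new
            converged = True
            break
        u, v = u_new, v_new
    u, v = _orient(u, v)
    xs, ys = X @ u, Y @ v
    if np.std(xs) < 1e-12 or np.std(ys) < 1e-12:
        rho = 0.0
    else:
        rho = float(stats.pearsonr(xs, ys)[0])
    return u, v, rho, converged, it


def spls_fit(
    X: ClinicalMatrix | np.ndarray,
    Y: np.ndarray,
    c_u: float,
    c_v: float,
    max_lv: int = 5,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> SPLSResult:
    """Extract up to ``max_lv`` sparse LVs with projection deflation.

    ``c_u`` must lie in [1, sqrt(q)] and ``c_v`` in [1, sqrt(p)] (L1-ball
    radii of unit-L2 vectors).
    """
    Xv = X.values if isinstance(X, ClinicalMatrix) else np.asarray(X, float)
    Yv = np.asarray(Y, float)
    if Xv.shape[0] != Yv.shape[0]:
        raise ValidationError("row mismatch between blocks")
    q, p = Xv.shape[1], Yv.shape[1]
    if not (1.0 <= c_u <= np.sqrt(q) + 1e-9):
        raise ValidationError(f"c_u must be in [1, sqrt({q})]")
    if not (1.0 <= c_v <= np.sqrt(p) + 1e-9):
        raise ValidationError(f"c_v must be in [1, sqrt({p})]")
    Xd, Yd = Xv.copy(), Yv.copy()
    lvs: list[LatentVariable] = []
    for _ in range(max_lv):
        u, v, rho, conv, it = _fit_one_lv(Xd, Yd, c_u, c_v, tol, max_iter)
        if not conv:
            log.warning("LV %d did not converge after %d iterations",
                        len(lvs) + 1, it)
        lvs.append(LatentVariable(u=u, v=v, rho=rho, converged=conv,
                                  n_iter=it, X_deflated=Xd.copy(),
                                  Y_deflated=Yd.copy()))
        # projection deflation: remove the extracted directions
        Xd = Xd - np.outer(Xd @ u, u)
        Yd = Yd - np.outer(Yd @ v, v)
    return SPLSResult(lvs=lvs, c_u=c_u, c_v=c_v)


def lv_permutation_test(
    fit: SPLSResult,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[float]:
    """Row-permutation reliability per LV.

    For LV j the clinical block rows of the j-th deflated matrices are
    permuted and a single LV refit; p = (1 + #{rho_perm >= rho_obs}) /
    (n_perm + 1).  Callers stop extraction at the first p > alpha.
    """
    if n_perm < 99:
        raise ValidationError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    pvals = []
    for lv in fit.lvs:
        null = np.empty(n_perm)
        n = lv.X_deflated.shape[0]
        for b in range(n_perm):
            perm = rng.permutation(n)
            _, _, rho, _, _ = _fit_one_lv(lv.X_deflated[perm], lv.Y_deflated,
                                          fit.c_u, fit.c_v, tol=1e-4,
                                          max_iter=100)
            null[b] = rho
        pvals.append(permutation_pvalue(lv.rho, null, smaller_is_better=False))
    fit.permutation_p = pvals
    return pvals


def bootstrap_ratios(
    fit: SPLSResult,
    n_boot: int = 500,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """BSR = original salience / bootstrap SE, with sign alignment.

    Replicate saliences whose correlation with the original is negative are
    flipped before the SE is taken.  Zero SE yields a signed cap.
    """
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    bsr_u = np.empty((len(fit.lvs), fit.lvs[0].u.size))
    bsr_v = np.empty((len(fit.lvs), fit.lvs[0].v.size))
    for j, lv in enumerate(fit.lvs):
        n = lv.X_deflated.shape[0]
        us = np.empty((n_boot, lv.u.size))
        vs = np.empty((n_boot, lv.v.size))
        for b in range(n_boot):
            rows = rng.integers(0, n, size=n)
            u, v, _, _, _ = _fit_one_lv(lv.X_deflated[rows], lv.Y_deflated[rows],
                                        fit.c_u, fit.c_v, tol=1e-4,
                                        max_iter=100, v_init=lv.v)
            if np.dot(u, lv.u) + np.dot(v, lv.v) < 0:
                u, v = -u, -v
            us[b], vs[b] = u, v
        for orig, reps, out in ((lv.u, us, bsr_u), (lv.v, vs, bsr_v)):
            se = reps.std(axis=0, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = orig / se
            zero = se == 0
            if zero.any():
                log.warning("LV %d: %d zero-SE saliences capped", j + 1,
                            int(zero.sum()))
            ratio[zero] = np.sign(orig[zero]) * BSR_CAP
            out[j] = ratio
    fit.bootstrap_u, fit.bootstrap_v = bsr_u, bsr_v
    return bsr_u, bsr_v


def select_sparsity(
    X: np.ndarray,
    Y: np.ndarray,
    c_u_grid: Sequence[float],
    c_v_grid: Sequence[float],
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[float, float]:
    """Pick (c_u, c_v) maximizing mean out-of-fold LV1 correlation."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    best, best_val = None, -np.inf
    for cu in c_u_grid:
        for cv in c_v_grid:
            vals = []
            for f in folds:
                tr = np.setdiff1d(order, f)
                u, v, _, _, _ = _fit_one_lv(X[tr], Y[tr], cu, cv,
                                            tol=1e-4, max_iter=100)
                xs, ys = X[f] @ u, Y[f] @ v
                if np.std(xs) < 1e-12 or np.std(ys) < 1e-12:
                    vals.append(0.0)
                else:
                    vals.append(float(stats.pearsonr(xs, ys)[0]))
            m = float(np.mean(vals))
            if m > best_val:
                best, best_val = (float(cu), float(cv)), m
    return best
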