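"""Weight-change outcomes: delta-weight tables, percent-gain subgroups,
stratified gap/weight-change correlations with FDR, and the multivariate
weight-gain classifier with gap-feature ablation."""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .imaging_io import ValidationError
from .normative.cv import build_cv
from .normative.stats import (bac_from_predictions, balanced_accuracy,
                              permutation_pvalue, sens_spec_from_counts)

log = logging.getLogger(__name__)

GAIN_THRESHOLDS = (3.0, 5.0, 7.0)
AGE_RANGES_BROAD = ((15, 40), (20, 40), (25, 40), (30, 40), (35, 40))
AGE_RANGES_FINE = ((15, 20), (20, 25), (25, 30), (30, 35), (35, 40))

__all__ = ["compute_weight_change", "StrataSpec", "stratified_correlations",
           "build_feature_frame", "weight_gain_classifier", "compare_models",
           "GAIN_THRESHOLDS", "AGE_RANGES_BROAD", "AGE_RANGES_FINE"]


def compute_weight_change(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject weight deltas, percent changes and gain flags.

    gain_k at horizon h is True iff pct_h >= k (weakly, "at least").
    Missing follow-ups stay missing; subjects with non-positive baseline
    weight are excluded with a log entry.
    """
    df = table.copy()
    bad = df["weight_t0"].notna() & (df["weight_t0"] <= 0)
    if bad.any():
        log.warning("excluding %d subjects with non-positive baseline weight",
                    int(bad.sum()))
        df = df[~bad]
    out = df[["subject_id", "group", "age", "sex"]].copy()
    for h, col in ((1, "weight_t1"), (2, "weight_t2")):
        dw = df[col] - df["weight_t0"]
        pct = 100.0 * dw / df["weight_t0"]
        out[f"dw{h}"] = dw.to_numpy()
        out[f"pct{h}"] = pct.to_numpy()
        for k in GAIN_THRESHOLDS:
            flag = pct >= k
            flag = flag.where(pct.notna(), other=pd.NA)
            out[f"gain{int(k)}_t{h}"] = flag.to_numpy()
    return out.reset_index(drop=True)


@dataclasses.dataclass
class StrataSpec:
    groups: Sequence[str] = ("HC", "CHR", "ROD")
    horizons: Sequence[int] = (1, 2)
    age_ranges: Sequence[tuple[float, float] | None] = (
        (None,) + AGE_RANGES_BROAD + AGE_RANGES_FINE)
    gain_thresholds: Sequence[float | None] = (None,) + GAIN_THRESHOLDS
    by_sex: bool = False


def stratified_correlations(
    gaps: pd.DataFrame,
    wct: pd.DataFrame,
    spec: StrataSpec | None = None,
) -> pd.DataFrame:
    """Pearson r per (group x horizon x age stratum x gain threshold) cell.

    BH-FDR is applied within each (group, horizon) family, matching a
    per-panel correction.  Cells with n < 3 are reported empty.
    """
    spec = spec or StrataSpec()
    df = wct.merge(gaps[["subject_id", "gap_corrected"]], on="subject_id")
    rows = []
    for group in spec.groups:
        gsub = df[df["group"] == group]
        for h in spec.horizons:
            family = []
            for age_rng in spec.age_ranges:
                for thr in spec.gain_thresholds:
                    sexes = ("F", "M", None) if spec.by_sex else (None,)
                    for sex in sexes:
                        sub = gsub[gsub[f"dw{h}"].notna()]
                        if age_rng is not None:
                            lo, hi = age_rng
                            sub = sub[(sub["age"] >= lo) & (sub["age"] <= hi)]
                        if thr is not None:
                            sub = sub[sub[f"pct{h}"] >= thr]
                        if sex is not None:
                            sub = sub[sub["sex"] == sex]
                        cell = {"group": group, "horizon": h,
                                "age_range": age_rng, "gain_threshold": thr,
                                "sex": sex, "n": int(len(sub))}
                        if len(sub) >= 3 and sub["gap_corrected"].std() > 1e-12 \
                                and sub[f"dw{h}"].std() > 1e-12:
                            r, p = stats.pearsonr(sub["gap_corrected"],
                                                  sub[f"dw{h}"])
                            cell["r"], cell["p_raw"] = float(r), float(p)
                        else:
                            cell["r"], cell["p_raw"] = np.nan, np.nan
                        family.append(cell)
            valid = [c for c in family if np.isfinite(c["p_raw"])]
            if valid:
                _, p_adj, _, _ = multipletests([c["p_raw"] for c in valid],
                                               method="fdr_bh")
                for c, pa in zip(valid, p_adj):
                    c["p_fdr"] = float(max(pa, c["p_raw"]))
            for c in family:
                c.setdefault("p_fdr", np.nan)
            rows.extend(family)
    return pd.DataFrame(rows)


def build_feature_frame(
    table: pd.DataFrame,
    gaps: pd.DataFrame,
    include_bmigap: bool = True,
    include_tobacco: bool = True,
) -> pd.DataFrame:
    """Design matrix for the weight-gain classifier.

    Features: gap score (optional), age, sex, study-group indicators
    (ROD, CHR), exercise, history of somatic comorbidities and tobacco use
    (optional, on by default).
    """
    df = table.merge(gaps[["subject_id", "gap_corrected"]], on="subject_id")
    feats = pd.DataFrame({"subject_id": df["subject_id"]})
    if include_bmigap:
        feats["bmigap"] = df["gap_corrected"].to_numpy()
    feats["age"] = df["age"].to_numpy()
    feats["sex_female"] = (df["sex"] == "F").astype(float)
    feats["group_ROD"] = (df["group"] == "ROD").astype(float)
    feats["group_CHR"] = (df["group"] == "CHR").astype(float)
    for col in ("exercise", "somatic_history"):
        feats[col] = df[col].astype(float).to_numpy()
    if include_tobacco:
        feats["tobacco"] = df["tobacco"].astype(float).to_numpy()
    return feats


def weight_gain_classifier(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    K: int = 5,
    P: int = 5,
    inner_K: int = 5,
    inner_P: int = 5,
    Cs: Sequence[float] = (2.0**-5, 2.0**-3, 2.0**-1, 2.0, 2.0**3, 2.0**5),
    seed: int = 0,
    n_perm: int = 0,
) -> dict:
    """Nested-CV linear soft-margin classifier of a binary gain label.

    Features are standardized inside every training partition; inner folds
    select C by balanced accuracy.  Reports outer fold-level BACs, pooled
    sensitivity/specificity, per-feature CVR (mean weight / SE across the
    P*K models) and, optionally, a label-permutation p-value.
    """
    feat_cols = [c for c in features.columns if c != "subject_id"]
    X = features[feat_cols].to_numpy(float)
    y_raw = pd.to_numeric(pd.Series(np.asarray(labels, dtype=object)).astype(object),
                          errors="coerce").to_numpy(float)
    mask = np.isfinite(X).all(axis=1) & np.isfinite(y_raw)
    X, y = X[mask], y_raw[mask].astype(int)
    if len(np.unique(y)) < 2:
        raise ValidationError("labels are single-class")

    def run(y_run: np.ndarray, seed_run: int):
        outer = build_cv(len(y_run), K, P, seed_run, stratify_on=y_run)
        fold_bac, weights = [], []
        tp = fn = tn = fp = 0
        for f in outer:
            Xtr, ytr = X[f.train_idx], y_run[f.train_idx]
            mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
            Ztr = (Xtr - mu) / sd
            Zte = (X[f.test_idx] - mu) / sd
            best_c, best_bac = None, -np.inf
            inner = build_cv(len(ytr), inner_K, inner_P, seed_run + 1,
                             stratify_on=ytr)
            scores = {c: [] for c in Cs}
            for g in inner:
                if len(np.unique(ytr[g.train_idx])) < 2:
                    continue
                for c in Cs:
                    clf = SVC(kernel="linear", C=c)
                    clf.fit(Ztr[g.train_idx], ytr[g.train_idx])
                    pred = clf.predict(Ztr[g.test_idx])
                    try:
                        scores[c].append(bac_from_predictions(ytr[g.test_idx], pred))
                    except ValidationError:
                        scores[c].append(np.nan)
            for c in Cs:
                vals = np.asarray(scores[c], float)
                m = np.nanmean(vals) if len(vals) else -np.inf
                if m > best_bac:
                    best_c, best_bac = c, m
            clf = SVC(kernel="linear", C=best_c)
            clf.fit(Ztr, ytr)
            pred = clf.predict(Zte)
            yte = y_run[f.test_idx]
            tp += int(((yte == 1) & (pred == 1)).sum())
            fn += int(((yte == 1) & (pred == 0)).sum())
            tn += int(((yte == 0) & (pred == 0)).sum())
            fp += int(((yte == 0) & (pred == 1)).sum())
            try:
                fold_bac.append(bac_from_predictions(yte, pred))
            except ValidationError:
                fold_bac.append(np.nan)
            weights.append(np.asarray(clf.coef_).ravel())
        sens, spec = sens_spec_from_counts(tp, fn, tn, fp)
        return np.asarray(fold_bac), np.vstack(weights), sens, spec

    fold_bac, W, sens, spec = run(y, seed)
    M = W.shape[0]
    wm = W.mean(axis=0)
    wse = W.std(axis=0, ddof=1) / np.sqrt(M)
    with np.errstate(divide="ignore", invalid="ignore"):
        cvr = np.where(wse > 0, wm / wse, np.sign(wm) * 1e6)
    out = {
        "bac": balanced_accuracy(sens, spec),
        "sensitivity": sens,
        "specificity": spec,
        "fold_bac": fold_bac,
        "mean_fold_bac": float(np.nanmean(fold_bac)),
        "feature_names": feat_cols,
        "feature_cvr": cvr,
        "n": int(len(y)),
    }
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for b in range(n_perm):
            yp = y[rng.permutation(len(y))]
            if len(np.unique(yp)) < 2:
                null[b] = 50.0
                continue
            fb, _, s1, s2 = run(yp, seed)
            null[b] = balanced_accuracy(s1, s2)
        out["permutation_p"] = permutation_pvalue(out["bac"], null,
                                                  smaller_is_better=False)
    return out


def compare_models(bac_with: Sequence[float], bac_without: Sequence[float]) -> dict:
    """Two-sided paired t-test between fold-level BAC lists."""
    a = np.asarray(bac_with, float)
    b = np.asarray(bac_without, float)
    if a.shape != b.shape:
        raise ValidationError("paired BAC lists differ in length")
    d = a - b
    if np.std(d, ddof=1) < 1e-12:
        if np.allclose(d, 0):
            return {"t": 0.0, "df": len(d) - 1, "p": 1.0,
                    "flag": "identical fold BACs"}
        return {"t": np.nan, "df": len(d) - 1, "p": np.nan,
                "flag": "constant nonzero differences, sd 0"}
    t, p = stats.ttest_rel(a, b)
    return {"t": float(t), "df": int(len(d) - 1), "p": float(p)}
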