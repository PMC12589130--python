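"""Gap scores (predicted minus measured BMI), bias correction, and the
group / medication / dosage association analyses."""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .imaging_io import ValidationError

log = logging.getLogger(__name__)

__all__ = ["BiasCorrection", "BMIgapResult", "compute_gap",
           "fit_bias_correction", "apply_bias_correction", "group_tests",
           "medication_contrasts", "dosage_correlation", "variance_ratio_test"]


@dataclasses.dataclass
class BiasCorrection:
    """OLS line of raw gap on measured BMI, fitted on one named sample."""

    slope: float
    intercept: float
    fit_sample: str
    n_fit: int


@dataclasses.dataclass
class BMIgapResult:
    table: pd.DataFrame  # subject_id, group, bmi_measured, bmi_predicted, gap_raw[, gap_corrected]
    correction: BiasCorrection | None = None


def compute_gap(predictions: pd.Series, table: pd.DataFrame) -> BMIgapResult:
    """gap_raw = predicted - measured; positive = brain looks heavier.

    Subjects missing a measured BMI are dropped with a log entry.
    """
    df = table.set_index("subject_id")
    common = [s for s in predictions.index if s in df.index]
    missing_bmi = [s for s in common if pd.isna(df.at[s, "bmi_measured"])]
    if missing_bmi:
        log.warning("dropping %d subjects with missing BMI: %s",
                    len(missing_bmi), missing_bmi[:5])
    keep = [s for s in common if s not in set(missing_bmi)]
    out = pd.DataFrame({
        "subject_id": keep,
        "group": df.loc[keep, "group"].to_numpy(),
        "bmi_measured": df.loc[keep, "bmi_measured"].astype(float).to_numpy(),
        "bmi_predicted": predictions.loc[keep].astype(float).to_numpy(),
    })
    out["gap_raw"] = out["bmi_predicted"] - out["bmi_measured"]
    return BMIgapResult(table=out)


def fit_bias_correction(result: BMIgapResult, fit_sample: str = "discovery_oof") -> BiasCorrection:
    """OLS of raw gap on measured BMI over the rows of ``result``.

    Fit on discovery out-of-fold gaps only; the fitted line is then applied
    unchanged to every other sample.
    """
    bmi = result.table["bmi_measured"].to_numpy()
    gap = result.table["gap_raw"].to_numpy()
    if len(bmi) < 3:
        raise ValidationError("need >= 3 subjects to fit the correction")
    if np.std(bmi) < 1e-12:
        raise ValidationError("zero BMI variance in the correction sample")
    slope, intercept = np.polyfit(bmi, gap, 1)
    return BiasCorrection(slope=float(slope), intercept=float(intercept),
                          fit_sample=fit_sample, n_fit=len(bmi))


def apply_bias_correction(result: BMIgapResult, correction: BiasCorrection) -> BMIgapResult:
    """gap_corrected = gap_raw - (intercept + slope * bmi_measured)."""
    tbl = result.table.copy()
    tbl["gap_corrected"] = tbl["gap_raw"] - (
        correction.intercept + correction.slope * tbl["bmi_measured"]
    )
    return BMIgapResult(table=tbl, correction=correction)


def _gap_col(df: pd.DataFrame) -> str:
    return "gap_corrected" if "gap_corrected" in df.columns else "gap_raw"


def group_tests(result: BMIgapResult, reference: str = "HC") -> dict:
    """One-way ANOVA across groups plus pairwise Welch t-tests vs reference."""
    df = result.table
    col = _gap_col(df)
    groups = [g for g, sub in df.groupby("group") if len(sub) >= 2]
    dropped = sorted(set(df["group"]) - set(groups))
    if dropped:
        log.warning("groups with n < 2 excluded: %s", dropped)
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups with n >= 2")
    samples = [df.loc[df["group"] == g, col].to_numpy() for g in groups]
    F, p = stats.f_oneway(*samples)
    n_tot = sum(len(s) for s in samples)
    report = {
        "anova": {"F": float(F), "p": float(p),
                  "df_between": len(groups) - 1, "df_within": n_tot - len(groups)},
        "group_means": {g: float(np.mean(s)) for g, s in zip(groups, samples)},
        "group_n": {g: int(len(s)) for g, s in zip(groups, samples)},
        "pairwise": {},
    }
    if reference in groups:
        ref = df.loc[df["group"] == reference, col].to_numpy()
        for g, s in zip(groups, samples):
            if g == reference:
                continue
            t, tp = stats.ttest_ind(ref, s, equal_var=False)
            report["pairwise"][f"{reference}_vs_{g}"] = {"t": float(t), "p": float(tp)}
    return report


def variance_ratio_test(x: Sequence[float], y: Sequence[float]) -> dict:
    """Two-sided F test for equality of variances between two samples."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vy == 0:
        raise ValidationError("zero variance in the denominator sample")
    F = vx / vy
    dfx, dfy = len(x) - 1, len(y) - 1
    p = 2 * min(stats.f.cdf(F, dfx, dfy), stats.f.sf(F, dfx, dfy))
    return {"F": float(F), "df": (dfx, dfy), "p": float(min(p, 1.0))}


def medication_contrasts(result: BMIgapResult, table: pd.DataFrame,
                         groups: Sequence[str] = ("CHR", "ROD")) -> dict:
    """Naive/treated ANOVA strata and weight-gain vs weight-neutral t-tests.

    Reports stratum sizes with percentages alongside each contrast.
    """
    df = result.table.merge(
        table[["subject_id", "antipsychotic_naive", "antidepressant_naive",
               "weightgain_med"]],
        on="subject_id", how="left")
    col = _gap_col(df)
    report: dict = {}
    scopes = {g: df[df["group"] == g] for g in groups}
    scopes["+".join(groups)] = df[df["group"].isin(groups)]
    for name, sub in scopes.items():
        entry: dict = {"n": int(len(sub))}
        if len(sub) == 0:
            entry["skipped"] = "empty stratum"
            report[name] = entry
            continue
        # medication-naive strata ANOVA
        strata = {
            "antipsychotic_naive": sub[sub["antipsychotic_naive"] == True][col],   # noqa: E712
            "antidepressant_naive": sub[sub["antidepressant_naive"] == True][col], # noqa: E712
            "treated": sub[(sub["antipsychotic_naive"] == False)                   # noqa: E712
                           & (sub["antidepressant_naive"] == False)][col],
        }
        strata = {k: v.to_numpy() for k, v in strata.items() if len(v) >= 2}
        entry["strata_n"] = {
            k: {"n": int(len(v)),
                "pct": round(100.0 * len(v) / len(sub), 2)}
            for k, v in strata.items()}
        if len(strata) >= 2:
            F, p = stats.f_oneway(*strata.values())
            entry["naive_anova"] = {"F": float(F), "p": float(p)}
        else:
            entry["naive_anova"] = None
            log.warning("%s: fewer than two medication strata; ANOVA skipped", name)
        # weight-gain vs weight-neutral medications
        wg = sub.loc[sub["weightgain_med"] == "yes", col].to_numpy()
        wn = sub.loc[sub["weightgain_med"] == "neutral_or_none", col].to_numpy()
        entry["weightgain_n"] = {
            "yes": {"n": int(len(wg)), "pct": round(100.0 * len(wg) / len(sub), 2)},
            "neutral_or_none": {"n": int(len(wn)),
                                "pct": round(100.0 * len(wn) / len(sub), 2)},
        }
        if len(wg) >= 2 and len(wn) >= 2:
            t, p = stats.ttest_ind(wg, wn, equal_var=False)
            entry["weightgain_ttest"] = {"t": float(t), "p": float(p)}
        else:
            entry["weightgain_ttest"] = None
            log.warning("%s: empty weight-gain stratum; contrast skipped", name)
        report[name] = entry
    return report


def dosage_correlation(result: BMIgapResult, table: pd.DataFrame,
                       group: str = "SCZ") -> dict:
    """Two-sided Pearson correlation between gap and chlorpromazine equivalents."""
    df = result.table.merge(table[["subject_id", "cpz_equiv"]],
                            on="subject_id", how="left")
    sub = df[(df["group"] == group) & df["cpz_equiv"].notna()]
    col = _gap_col(sub)
    if len(sub) < 3:
        raise ValidationError("need >= 3 paired observations")
    x = sub[col].to_numpy()
    y = sub["cpz_equiv"].to_numpy()
    if np.std(x) < 1e-12 or np.std(y) < 1e-12:
        return {"r": float("nan"), "p": float("nan"), "n": int(len(sub)),
                "flag": "constant input, r undefined"}
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": int(len(sub))}
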