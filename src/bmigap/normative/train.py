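"""Nested cross-validated linear nu-SVR (BMI) and linear SVM (diagnosis).

All preprocessing parameters and model weights are estimated on training
rows only; inner folds select the (fwhm, energy, nu/C) configuration by
mean inner-test MAE (regression) or balanced accuracy (classification), and
the winner is refit on the full outer-train partition.  Discovery-sample
predictions are strictly out-of-fold.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC, NuSVR

from ..imaging_io import ValidationError
from .cv import CVStructure, build_cv
from .preprocess import PreprocState, apply_preproc, fit_preproc
from .stats import bac_from_predictions, permutation_pvalue

FeatureSets = Mapping[float, np.ndarray]  # fwhm -> (n, p) matrix


@dataclasses.dataclass(frozen=True)
class Candidate:
    """One point of the hyperparameter grid."""

    fwhm: float
    energy: float
    nu: float | None = None  # regression only
    C: float = 1.0


def default_regression_grid(
    fwhms: Sequence[float] = (0.0, 3.0, 6.0, 9.0),
    energies: Sequence[float] = (0.25, 0.50, 0.75),
    nus: Sequence[float] = (0.25, 0.5, 0.75),
    Cs: Sequence[float] = (2.0**-5, 2.0**-3, 2.0**-1, 2.0, 2.0**3, 2.0**5),
) -> list[Candidate]:
    return [Candidate(f, e, n, c)
            for f, e, n, c in itertools.product(fwhms, energies, nus, Cs)]


def default_classification_grid(
    fwhms: Sequence[float] = (0.0, 3.0, 6.0, 9.0),
    energies: Sequence[float] = (0.25, 0.50, 0.75),
    Cs: Sequence[float] = (2.0**-5, 2.0**-3, 2.0**-1, 2.0, 2.0**3, 2.0**5),
) -> list[Candidate]:
    return [Candidate(f, e, None, c)
            for f, e, c in itertools.product(fwhms, energies, Cs)]


@dataclasses.dataclass
class FoldModel:
    """One fitted outer-train model: preprocessing state + linear weights."""

    state: PreprocState
    coef: np.ndarray          # component-space weights, shape (k,)
    intercept: float
    candidate: Candidate
    inner_score: float
    repeat: int
    fold: int
    train_idx: np.ndarray
    test_idx: np.ndarray

    def decision(self, Z: np.ndarray) -> np.ndarray:
        return Z @ self.coef + self.intercept

    def apply(self, feature_sets: FeatureSets, age, sites) -> np.ndarray:
        Z = apply_preproc(self.state, np.array(feature_sets[self.state.fwhm],
                                               dtype=float),
                          age, sites)
        return self.decision(Z)


@dataclasses.dataclass
class TrainedEnsemble:
    models: list[FoldModel]
    task: str                         # "regression" | "classification"
    oof_predictions: pd.Series        # indexed by subject id, mean over repeats
    ids: list[str]
    K: int
    P: int
    log: list[dict]


@dataclasses.dataclass
class PredictionResult:
    per_subject: pd.Series            # bmi_predicted or decision score
    per_model: np.ndarray | None = None  # (n_models, n_subjects)


def _new_estimator(task: str, cand: Candidate):
    if task == "regression":
        return NuSVR(kernel="linear", nu=cand.nu, C=cand.C)
    return SVC(kernel="linear", C=cand.C)


def _fit_linear(task: str, cand: Candidate, Z: np.ndarray, y: np.ndarray):
    est = _new_estimator(task, cand)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(Z, y)
    coef = np.asarray(est.coef_).ravel()
    intercept = float(np.asarray(est.intercept_).ravel()[0])
    return coef, intercept


def _score(task: str, y_true, decision) -> float:
    """Inner selection criterion: MAE (regression) or BAC (classification)."""
    if task == "regression":
        return float(np.mean(np.abs(decision - y_true)))
    return bac_from_predictions(y_true, (decision > 0).astype(int))


def _better(task: str, a: float, b: float) -> bool:
    return a < b if task == "regression" else a > b


def _inner_select(
    task: str,
    feature_sets: FeatureSets,
    y: np.ndarray,
    age: np.ndarray,
    sites: np.ndarray,
    train_idx: np.ndarray,
    grid: Sequence[Candidate],
    K2: int,
    P2: int,
    seed: int,
) -> tuple[Candidate, float, list[dict]]:
    """Mean inner-test score per candidate over the P2 x K2 inner folds."""
    y_tr = y[train_idx]
    strat = y_tr if task == "classification" else None
    inner = build_cv(len(train_idx), K2, P2, seed, stratify_on=strat)
    scores = {cand: [] for cand in grid}
    preproc_keys = sorted({(c.fwhm, c.energy) for c in grid})
    for f in inner:
        itr = train_idx[f.train_idx]
        ite = train_idx[f.test_idx]
        if task == "classification" and len(np.unique(y[itr])) < 2:
            warnings.warn("single-class inner fold skipped")
            continue
        for fwhm, energy in preproc_keys:
            X = np.asarray(feature_sets[fwhm], dtype=float)
            state, Ztr = fit_preproc(X[itr], age[itr], sites[itr], fwhm, energy)
            Zte = apply_preproc(state, X[ite], age[ite], sites[ite])
            for cand in grid:
                if (cand.fwhm, cand.energy) != (fwhm, energy):
                    continue
                try:
                    coef, b0 = _fit_linear(task, cand, Ztr, y[itr])
                except Exception as exc:  # solver failure: discard candidate
                    warnings.warn(f"candidate {cand} discarded: {exc}")
                    scores[cand].append(np.nan)
                    continue
                scores[cand].append(_score(task, y[ite], Zte @ coef + b0))
    best, best_score = None, None
    log = []
    for cand in grid:  # deterministic order; ties keep the first
        vals = np.asarray(scores[cand], float)
        if len(vals) == 0 or np.isnan(vals).all():
            continue
        m = float(np.nanmean(vals))
        log.append({"candidate": dataclasses.asdict(cand), "inner_score": m})
        if best is None or _better(task, m, best_score):
            best, best_score = cand, m
    if best is None:
        raise ValidationError("no viable candidate on the grid")
    return best, best_score, log


def train_nusvr(
    feature_sets: FeatureSets,
    y: np.ndarray,
    age: np.ndarray,
    sites: np.ndarray,
    train_idx: np.ndarray,
    grid: Sequence[Candidate],
    K2: int = 5,
    P2: int = 5,
    seed: int = 0,
) -> tuple[PreprocState, np.ndarray, float, Candidate, float, list[dict]]:
    """Inner-CV model selection + refit of a linear nu-SVR on one partition."""
    if len(train_idx) < 2 * K2:
        raise ValidationError(f"need >= {2 * K2} training rows")
    return _select_and_refit("regression", feature_sets, y, age, sites,
                             train_idx, grid, K2, P2, seed)


def train_svm(
    feature_sets: FeatureSets,
    y: np.ndarray,
    age: np.ndarray,
    sites: np.ndarray,
    train_idx: np.ndarray,
    grid: Sequence[Candidate],
    K2: int = 5,
    P2: int = 5,
    seed: int = 0,
):
    """Inner-CV selection (balanced accuracy) + refit of a linear SVM.

    Decision scores are oriented so that larger = more disease-like
    (positive class = label 1).
    """
    return _select_and_refit("classification", feature_sets, y, age, sites,
                             train_idx, grid, K2, P2, seed)


def _select_and_refit(task, feature_sets, y, age, sites, train_idx, grid,
                      K2, P2, seed):
    cand, score, log = _inner_select(task, feature_sets, y, age, sites,
                                     train_idx, grid, K2, P2, seed)
    X = np.asarray(feature_sets[cand.fwhm], dtype=float)
    state, Ztr = fit_preproc(X[train_idx], age[train_idx], sites[train_idx],
                             cand.fwhm, cand.energy)
    coef, b0 = _fit_linear(task, cand, Ztr, y[train_idx])
    return state, coef, b0, cand, score, log


def train_ensemble(
    feature_sets: FeatureSets,
    y: np.ndarray,
    age: np.ndarray,
    sites: Sequence[str],
    ids: Sequence[str],
    task: str = "regression",
    grid: Sequence[Candidate] | None = None,
    K1: int = 5,
    P1: int = 5,
    K2: int = 5,
    P2: int = 5,
    seed: int = 0,
) -> TrainedEnsemble:
    """Repeated nested CV over the discovery sample.

    Returns P1*K1 fitted fold models and the out-of-fold prediction per
    subject (mean over the P1 repeats in which it was held out).
    """
    y = np.asarray(y, float) if task == "regression" else np.asarray(y, int)
    age = np.asarray(age, float)
    sites = np.asarray(sites)
    ids = list(ids)
    n = len(y)
    if grid is None:
        grid = (default_regression_grid() if task == "regression"
                else default_classification_grid())
    strat = y if task == "classification" else None
    outer = build_cv(n, K1, P1, seed, stratify_on=strat)
    ss = np.random.SeedSequence([seed, 1])
    inner_seeds = ss.generate_state(len(outer))

    models: list[FoldModel] = []
    oof_sum = np.zeros(n)
    oof_cnt = np.zeros(n, dtype=int)
    log: list[dict] = []
    for j, f in enumerate(outer):
        state, coef, b0, cand, score, cand_log = _select_and_refit(
            task, feature_sets, y, age, sites, f.train_idx, grid,
            K2, P2, int(inner_seeds[j] % (2**31 - 1)))
        fm = FoldModel(state=state, coef=coef, intercept=b0, candidate=cand,
                       inner_score=score, repeat=f.repeat, fold=f.fold,
                       train_idx=f.train_idx, test_idx=f.test_idx)
        X = np.asarray(feature_sets[cand.fwhm], dtype=float)
        Zte = apply_preproc(state, X[f.test_idx], age[f.test_idx],
                            sites[f.test_idx])
        pred = fm.decision(Zte)
        oof_sum[f.test_idx] += pred
        oof_cnt[f.test_idx] += 1
        models.append(fm)
        log.append({"repeat": f.repeat, "fold": f.fold,
                    "selected": dataclasses.asdict(cand),
                    "inner_score": score, "candidates": cand_log})
    if (oof_cnt == 0).any():
        raise ValidationError("some subjects received no out-of-fold prediction")
    oof = pd.Series(oof_sum / oof_cnt, index=ids, name="oof_prediction")
    return TrainedEnsemble(models=models, task=task, oof_predictions=oof,
                           ids=ids, K=K1, P=P1, log=log)


def predict_ensemble(
    ensemble: TrainedEnsemble,
    feature_sets: FeatureSets,
    age: Sequence[float],
    sites: Sequence[str],
    ids: Sequence[str],
    keep_per_model: bool = False,
) -> PredictionResult:
    """Mean prediction over all fold models, each applying its own state."""
    age = np.asarray(age, float)
    sites = np.asarray(sites)
    n = len(age)
    for X in feature_sets.values():
        if np.asarray(X).shape[0] != n:
            raise ValidationError("feature matrix rows != number of subjects")
    per_model = np.empty((len(ensemble.models), n))
    for m, fm in enumerate(ensemble.models):
        per_model[m] = fm.apply(feature_sets, age, sites)
    series = pd.Series(per_model.mean(axis=0), index=list(ids))
    return PredictionResult(per_subject=series,
                            per_model=per_model if keep_per_model else None)


def cv_metric_frozen(
    feature_sets: FeatureSets,
    y: np.ndarray,
    age: np.ndarray,
    sites: Sequence[str],
    candidate: Candidate,
    K: int = 5,
    P: int = 5,
    seed: int = 0,
    task: str = "regression",
) -> float:
    """Outer-CV metric (mean fold MAE or BAC) at a frozen configuration."""
    y = np.asarray(y, float) if task == "regression" else np.asarray(y, int)
    age = np.asarray(age, float)
    sites = np.asarray(sites)
    strat = y if task == "classification" else None
    cv = build_cv(len(y), K, P, seed, stratify_on=strat)
    X = np.asarray(feature_sets[candidate.fwhm], dtype=float)
    vals = []
    for f in cv:
        state, Ztr = fit_preproc(X[f.train_idx], age[f.train_idx],
                                 sites[f.train_idx],
                                 candidate.fwhm, candidate.energy)
        coef, b0 = _fit_linear(task, candidate, Ztr, y[f.train_idx])
        Zte = apply_preproc(state, X[f.test_idx], age[f.test_idx],
                            sites[f.test_idx])
        vals.append(_score(task, y[f.test_idx], Zte @ coef + b0))
    return float(np.mean(vals))


def permutation_test(
    feature_sets: FeatureSets,
    y: np.ndarray,
    age: np.ndarray,
    sites: Sequence[str],
    candidate: Candidate,
    n_perm: int = 1000,
    K: int = 5,
    P: int = 5,
    seed: int = 0,
    task: str = "regression",
) -> tuple[float, float, np.ndarray]:
    """Label-permutation significance of the cross-validated metric.

    The configuration is frozen at ``candidate`` (the winning configuration);
    labels are permuted within the sample and the full outer CV is re-run per
    permutation.  p = (1 + #{perm at least as good}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    observed = cv_metric_frozen(feature_sets, y, age, sites, candidate,
                                K=K, P=P, seed=seed, task=task)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    y = np.asarray(y)
    for b in range(n_perm):
        yp = y[rng.permutation(len(y))]
        null[b] = cv_metric_frozen(feature_sets, yp, age, sites, candidate,
                                   K=K, P=P, seed=seed, task=task)
    p = permutation_pvalue(observed, null,
                           smaller_is_better=(task == "regression"))
    return p, observed, null
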