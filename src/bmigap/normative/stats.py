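"""Small shared statistics helpers."""

from __future__ import annotations

import numpy as np

from ..imaging_io import ValidationError


def balanced_accuracy(sensitivity: float, specificity: float) -> float:
    """Arithmetic mean of sensitivity and specificity, both in percent."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not (0.0 <= v <= 100.0):
            raise ValidationError(f"{name}={v} outside [0, 100]")
    return (sensitivity + specificity) / 2.0


def sens_spec_from_counts(tp: int, fn: int, tn: int, fp: int) -> tuple[float, float]:
    """Sensitivity and specificity in percent from confusion counts."""
    if tp + fn == 0 or tn + fp == 0:
        raise ValidationError("a class has no members")
    return 100.0 * tp / (tp + fn), 100.0 * tn / (tn + fp)


def bac_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """BAC in percent; positive class is label 1."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    sens, spec = sens_spec_from_counts(tp, fn, tn, fp)
    return balanced_accuracy(sens, spec)


def permutation_pvalue(observed: float, null_values: np.ndarray,
                       smaller_is_better: bool = True) -> float:
    """Add-one permutation p-value; never returns 0."""
    null_values = np.asarray(null_values, float)
    if smaller_is_better:
        hits = int((null_values <= observed).sum())
    else:
        hits = int((null_values >= observed).sum())
    return (1 + hits) / (len(null_values) + 1)
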