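"""Repeated (P x K) cross-validation fold structure."""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold


class SizingError(ValueError):
    pass


@dataclasses.dataclass
class Fold:
    repeat: int
    fold: int
    train_idx: np.ndarray
    test_idx: np.ndarray


@dataclasses.dataclass
class CVStructure:
    folds: list[Fold]
    K: int
    P: int
    n: int

    def __iter__(self):
        return iter(self.folds)

    def __len__(self):
        return len(self.folds)


def build_cv(
    n: int,
    K: int,
    P: int,
    seed: int,
    stratify_on: Sequence | None = None,
) -> CVStructure:
    """P independent shuffles each split into K folds; deterministic in seed.

    Within each repeat the K test sets partition the sample.  For
    classification pass the labels as ``stratify_on``.
    """
    if n < K:
        raise SizingError(f"n={n} < K={K}")
    ss = np.random.SeedSequence(seed)
    repeat_seeds = ss.generate_state(P)
    folds: list[Fold] = []
    idx = np.arange(n)
    for p in range(P):
        rs = int(repeat_seeds[p] % (2**31 - 1))
        if stratify_on is not None:
            splitter = StratifiedKFold(n_splits=K, shuffle=True, random_state=rs)
            split_iter = splitter.split(idx, np.asarray(stratify_on))
        else:
            splitter = KFold(n_splits=K, shuffle=True, random_state=rs)
            split_iter = splitter.split(idx)
        for k, (tr, te) in enumerate(split_iter):
            folds.append(Fold(repeat=p, fold=k, train_idx=tr, test_idx=te))
    return CVStructure(folds=folds, K=K, P=P, n=n)
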