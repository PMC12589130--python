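"""Discovery-sample construction: BMI binning, balanced per-bin selection,
greedy age matching across bins."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .imaging_io import ValidationError

__all__ = ["BinScheme", "SelectionResult", "make_bmi_bins", "stratified_select"]


class SizingError(ValueError):
    pass


@dataclasses.dataclass
class BinScheme:
    """Contiguous half-open BMI bins [a, b) tiling [lo, hi); top edge closed."""

    lo: float
    hi: float
    width: float
    bins: list[tuple[float, float]]

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def assign(self, bmi: float) -> int:
        """Bin index for a BMI value; value equal to `hi` goes to the last bin."""
        if bmi < self.lo or bmi > self.hi:
            raise ValidationError(f"BMI {bmi} outside [{self.lo}, {self.hi}]")
        if bmi == self.hi:
            return self.n_bins - 1
        return min(int((bmi - self.lo) / self.width), self.n_bins - 1)


def make_bmi_bins(lo: float, hi: float, width: float) -> BinScheme:
    if not (hi > lo and width > 0):
        raise ValidationError("need hi > lo and width > 0")
    ratio = (hi - lo) / width
    n = round(ratio)
    if abs(ratio - n) > 1e-9:
        raise ValidationError(
            f"range ({lo}, {hi}) not divisible by width {width}"
        )
    edges = lo + width * np.arange(n + 1)
    edges[-1] = hi
    bins = [(float(edges[i]), float(edges[i + 1])) for i in range(n)]
    return BinScheme(lo=lo, hi=hi, width=width, bins=bins)


@dataclasses.dataclass
class SelectionResult:
    discovery_ids: list[str]
    validation_ids: list[str]
    per_bin_counts: list[int]
    per_bin_mean_age: list[float]
    bin_assignment: dict[str, int]


def _quotas(candidate_counts: np.ndarray, target_n: int) -> np.ndarray:
    """Per-bin quotas: floor split + remainder to sparsest bins, then
    redistribute shortfall from undersized bins to bins with spare capacity."""
    n_bins = len(candidate_counts)
    base = target_n // n_bins
    rem = target_n - base * n_bins
    quota = np.full(n_bins, base, dtype=int)
    # remainder: bins sorted by candidate count ascending, ties by bin index
    order = sorted(range(n_bins), key=lambda b: (candidate_counts[b], b))
    for b in order[:rem]:
        quota[b] += 1
    # cap at availability, redistribute the shortfall
    while True:
        short = int(np.maximum(quota - candidate_counts, 0).sum())
        quota = np.minimum(quota, candidate_counts)
        if short == 0:
            break
        spare = candidate_counts - quota
        if spare.sum() < short:
            raise SizingError("target_n exceeds eligible candidates")
        while short > 0:
            spare = candidate_counts - quota
            # give to the bin with most spare capacity; ties by bin index
            b = int(np.lexsort((np.arange(n_bins), -spare))[0])
            if spare[b] <= 0:
                raise SizingError("target_n exceeds eligible candidates")
            quota[b] += 1
            short -= 1
    return quota


def _greedy_age_pick(ages: np.ndarray, k: int, target_mean: float,
                     order: np.ndarray) -> np.ndarray:
    """Pick k candidates greedily pulling the running mean toward target_mean.

    `order` breaks ties deterministically (a seed-shuffled ordering).
    """
    chosen: list[int] = []
    remaining = list(order)
    total = 0.0
    for _ in range(k):
        best, best_cost = None, np.inf
        for idx in remaining:
            cost = abs((total + ages[idx]) / (len(chosen) + 1) - target_mean)
            if cost < best_cost - 1e-12:
                best, best_cost = idx, cost
        chosen.append(best)
        total += ages[best]
        remaining.remove(best)
    return np.asarray(chosen, dtype=int)


def stratified_select(
    table: pd.DataFrame,
    scheme: BinScheme,
    target_n: int,
    seed: int,
) -> SelectionResult:
    """Balanced per-bin selection with greedy age matching.

    The table must already be restricted to eligible subjects (HC, age range,
    BMI inside the scheme).  Unselected eligible subjects form the validation
    split.  Deterministic in (table, scheme, target_n, seed).
    """
    df = table.reset_index(drop=True)
    if target_n > len(df):
        raise SizingError(f"target_n={target_n} > eligible n={len(df)}")
    bin_idx = df["bmi_measured"].map(scheme.assign).to_numpy()
    counts = np.bincount(bin_idx, minlength=scheme.n_bins)
    quota = _quotas(counts, target_n)
    pooled_mean_age = float(df["age"].mean())

    rng = np.random.default_rng(seed)
    discovery: list[str] = []
    per_bin_counts, per_bin_mean_age = [], []
    assignment: dict[str, int] = {}
    for b in range(scheme.n_bins):
        members = np.flatnonzero(bin_idx == b)
        for i in members:
            assignment[df.at[i, "subject_id"]] = b
        if len(members) == 0:
            per_bin_counts.append(0)
            per_bin_mean_age.append(float("nan"))
            continue
        order = rng.permutation(len(members))
        ages = df["age"].to_numpy()[members]
        pick = _greedy_age_pick(ages, int(quota[b]), pooled_mean_age, order)
        sel = members[pick]
        discovery.extend(df["subject_id"].iloc[sel])
        per_bin_counts.append(int(quota[b]))
        per_bin_mean_age.append(float(ages[pick].mean()) if len(pick) else float("nan"))

    disc_set = set(discovery)
    validation = [s for s in df["subject_id"] if s not in disc_set]
    return SelectionResult(
        discovery_ids=discovery,
        validation_ids=validation,
        per_bin_counts=per_bin_counts,
        per_bin_mean_age=per_bin_mean_age,
        bin_assignment=assignment,
    )
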