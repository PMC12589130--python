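import numpy as np
import pandas as pd
import pytest

from bmigap.imaging_io import ValidationError
from bmigap.weight_outcomes import (StrataSpec, build_feature_frame,
                                    compare_models, compute_weight_change,
                                    stratified_correlations,
                                    weight_gain_classifier)


def _weights_table(t0, t1=None, t2=None, groups=None):
    n = len(t0)
    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "group": groups if groups is not None else ["ROD"] * n,
        "age": np.full(n, 30.0),
        "sex": ["F", "M"] * (n // 2) + ["F"] * (n % 2),
        "weight_t0": np.asarray(t0, float),
        "weight_t1": np.asarray(t1, float) if t1 is not None else np.nan,
        "weight_t2": np.asarray(t2, float) if t2 is not None else np.nan,
    })


class TestComputeWeightChange:
    def test_delta_arithmetic(self):
        wct = compute_weight_change(_weights_table([78.0], [80.0]))
        assert wct["dw1"].iloc[0] == pytest.approx(2.0)

    def test_pct_and_thresholds_at_7percent(self):
        wct = compute_weight_change(_weights_table([70.0], None, [75.0]))
        assert wct["pct2"].iloc[0] == pytest.approx(100 * 5 / 70)  # 7.142..%
        assert bool(wct["gain3_t2"].iloc[0])
        assert bool(wct["gain5_t2"].iloc[0])
        assert bool(wct["gain7_t2"].iloc[0])

    def test_no_change_all_flags_false(self):
        wct = compute_weight_change(_weights_table([70.0], None, [70.0]))
        assert not bool(wct["gain3_t2"].iloc[0])

    def test_exact_boundary_inclusive(self):
        wct = compute_weight_change(_weights_table([100.0], None, [103.0]))
        assert bool(wct["gain3_t2"].iloc[0])   # >= is weakly "at least"
        assert not bool(wct["gain5_t2"].iloc[0])

    def test_missing_followup_stays_missing(self):
        wct = compute_weight_change(_weights_table([70.0]))
        assert pd.isna(wct["gain3_t1"].iloc[0])
        assert pd.isna(wct["pct1"].iloc[0])

    def test_nonpositive_baseline_excluded(self):
        wct = compute_weight_change(_weights_table([0.0, 70.0], [1.0, 72.0]))
        assert len(wct) == 1

    def test_flags_consistent_with_pct(self):
        rng = np.random.default_rng(0)
        t0 = rng.uniform(50, 100, 50)
        t2 = t0 * rng.uniform(0.9, 1.15, 50)
        wct = compute_weight_change(_weights_table(t0, None, t2))
        for k in (3, 5, 7):
            np.testing.assert_array_equal(
                wct[f"gain{k}_t2"].astype(bool).to_numpy(),
                (wct["pct2"] >= k).to_numpy())


def _gaps_frame(vals):
    return pd.DataFrame({"subject_id": [f"s{i}" for i in range(len(vals))],
                         "gap_corrected": np.asarray(vals, float)})


class TestStratifiedCorrelations:
    def test_perfect_coupling_r_one(self):
        rng = np.random.default_rng(1)
        gaps = rng.normal(size=40)
        t0 = np.full(40, 70.0)
        wct = compute_weight_change(
            _weights_table(t0, None, t0 + gaps, groups=["ROD"] * 40))
        rep = stratified_correlations(
            _gaps_frame(gaps), wct,
            StrataSpec(groups=("ROD",), horizons=(2,), age_ranges=(None,),
                       gain_thresholds=(None,)))
        assert rep["r"].iloc[0] == pytest.approx(1.0)

    def test_small_cells_reported_empty(self):
        wct = compute_weight_change(_weights_table([70.0, 71.0], [71.0, 72.0]))
        rep = stratified_correlations(
            _gaps_frame([0.1, 0.2]), wct,
            StrataSpec(groups=("ROD",), horizons=(1,), age_ranges=(None,),
                       gain_thresholds=(None,)))
        assert rep["n"].iloc[0] == 2
        assert np.isnan(rep["r"].iloc[0])

    def test_planted_coupling_recovered(self):
        """dw_coupling 0.3 planted, n=141 -> r within +-0.15 over 20 seeds."""
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            gap = rng.normal(size=141)
            dw = 0.3 * gap + np.sqrt(1 - 0.3**2) * rng.normal(size=141)
            t0 = np.full(141, 70.0)
            wct = compute_weight_change(
                _weights_table(t0, None, t0 + dw, groups=["ROD"] * 141))
            rep = stratified_correlations(
                _gaps_frame(gap), wct,
                StrataSpec(groups=("ROD",), horizons=(2,), age_ranges=(None,),
                           gain_thresholds=(None,)))
            errs.append(abs(rep["r"].iloc[0] - 0.3))
        assert np.mean(np.asarray(errs) <= 0.15) >= 0.9

    def test_null_fdr_calibration_full_grid(self):
        """Null coupling: FDR-significant cells average <= 5% over seeds."""
        fracs = []
        for seed in range(10):
            rng = np.random.default_rng(500 + seed)
            n = 400
            t0 = rng.uniform(55, 95, n)
            ages = rng.uniform(15, 45, n)
            table = _weights_table(t0, t0 * rng.uniform(0.97, 1.1, n),
                                   t0 * rng.uniform(0.97, 1.12, n),
                                   groups=["ROD"] * (n // 2) + ["CHR"] * (n // 2))
            table["age"] = ages
            wct = compute_weight_change(table)
            rep = stratified_correlations(
                _gaps_frame(rng.normal(size=n)), wct,
                StrataSpec(groups=("ROD", "CHR")))
            valid = rep[np.isfinite(rep["p_fdr"])]
            fracs.append((valid["p_fdr"] <= 0.05).mean())
        assert np.mean(fracs) <= 0.05

    def test_adjusted_p_not_below_raw(self):
        rng = np.random.default_rng(3)
        n = 100
        t0 = rng.uniform(55, 95, n)
        table = _weights_table(t0, t0 + rng.normal(0, 2, n),
                               t0 + rng.normal(0, 3, n))
        table["age"] = rng.uniform(15, 45, n)
        rep = stratified_correlations(_gaps_frame(rng.normal(size=n)),
                                      compute_weight_change(table),
                                      StrataSpec(groups=("ROD",)))
        valid = rep[np.isfinite(rep["p_fdr"])]
        assert (valid["p_fdr"] >= valid["p_raw"] - 1e-12).all()


def _classifier_data(n=160, informative=True, seed=0):
    rng = np.random.default_rng(seed)
    gap = rng.normal(size=n)
    table = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "group": ["ROD"] * (n // 2) + ["CHR"] * (n // 2),
        "age": rng.uniform(15, 45, n),
        "sex": rng.choice(["F", "M"], n),
        "exercise": rng.random(n) < 0.5,
        "somatic_history": rng.random(n) < 0.3,
        "tobacco": rng.random(n) < 0.35,
    })
    gaps = pd.DataFrame({"subject_id": table.subject_id, "gap_corrected": gap})
    if informative:
        labels = (gap + 0.6 * rng.normal(size=n)) > 0
    else:
        labels = rng.random(n) < 0.5
    return table, gaps, pd.Series(labels.astype(int))


class TestWeightGainClassifier:
    def test_feature_frame_columns(self):
        table, gaps, _ = _classifier_data()
        feats = build_feature_frame(table, gaps)
        assert "bmigap" in feats.columns and "tobacco" in feats.columns
        without = build_feature_frame(table, gaps, include_bmigap=False)
        assert "bmigap" not in without.columns

    def test_null_labels_bac_near_chance(self):
        table, gaps, labels = _classifier_data(n=200, informative=False)
        feats = build_feature_frame(table, gaps)
        out = weight_gain_classifier(feats, labels, K=5, P=2, inner_K=3,
                                     inner_P=1, Cs=(1.0,), seed=0)
        assert 45.0 <= out["bac"] <= 55.0

    def test_ablation_of_informative_feature_costs_bac(self):
        """With-gap beats without-gap by >= 3 BAC points over seeds."""
        diffs = []
        for seed in range(6):
            table, gaps, labels = _classifier_data(seed=seed)
            feats = build_feature_frame(table, gaps)
            w = weight_gain_classifier(feats, labels, K=5, P=2, inner_K=3,
                                       inner_P=1, Cs=(1.0,), seed=seed)
            wo = weight_gain_classifier(feats.drop(columns=["bmigap"]), labels,
                                        K=5, P=2, inner_K=3, inner_P=1,
                                        Cs=(1.0,), seed=seed)
            diffs.append(w["bac"] - wo["bac"])
        assert np.mean(diffs) >= 3.0

    def test_bac_aggregation_from_counts(self):
        """TP=24 FN=13 TN=23 FP=20 -> sens 64.9, spec 53.5, BAC 59.2."""
        from bmigap.normative.stats import (balanced_accuracy,
                                            sens_spec_from_counts)
        sens, spec = sens_spec_from_counts(24, 13, 23, 20)
        assert sens == pytest.approx(64.9, abs=0.05)
        assert spec == pytest.approx(53.5, abs=0.05)
        assert balanced_accuracy(sens, spec) == pytest.approx(59.2, abs=0.05)

    def test_single_class_labels_error(self):
        table, gaps, labels = _classifier_data(n=40)
        feats = build_feature_frame(table, gaps)
        with pytest.raises(ValidationError):
            weight_gain_classifier(feats, pd.Series(np.ones(40, int)))


class TestCompareModels:
    def test_identical_lists(self):
        out = compare_models([60.0, 55.0, 70.0], [60.0, 55.0, 70.0])
        assert out["t"] == 0.0 and out["p"] == 1.0

    def test_df_is_n_minus_one(self):
        rng = np.random.default_rng(0)
        a = rng.normal(60, 5, 25)
        out = compare_models(a, a + rng.normal(0, 1, 25))
        assert out["df"] == 24

    def test_constant_nonzero_differences_flagged(self):
        out = compare_models([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])
        assert np.isnan(out["t"]) and "flag" in out

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            compare_models([1.0, 2.0], [1.0])
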