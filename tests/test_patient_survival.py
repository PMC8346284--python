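import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from splicefid.patient_survival import (
    circ_burden,
    classify_inclusion,
    cox_hr,
    km_logrank,
    patient_event_score,
    stratify_quartiles,
    zscore_correlation,
)
from splicefid.synthetic_data import SimConfig, generate_cohort


class TestClassifyInclusion:
    def test_median_plus_shift_rule(self):
        psi = pd.DataFrame({"p1": [0.2], "p2": [0.4], "p3": [0.6]}, index=["e1"])
        high = classify_inclusion(psi)
        # median of {0.2, 0.4, 0.6} = 0.4 -> threshold 0.5
        assert not bool(high.loc["e1", "p1"])
        assert not bool(high.loc["e1", "p2"])
        assert bool(high.loc["e1", "p3"])

    def test_probe_patients_against_reference_median(self):
        # population {0.2, 0.4, 0.6}: a probe at 0.5 is high, at 0.49 low
        ref = pd.Series({"e1": 0.4})
        probes = pd.DataFrame({"x": [0.5], "y": [0.49]}, index=["e1"])
        high = classify_inclusion(probes, medians=ref)
        assert bool(high.loc["e1", "x"])
        assert not bool(high.loc["e1", "y"])

    def test_all_equal_event_marks_everyone_low(self):
        psi = pd.DataFrame({f"p{i}": [0.7] for i in range(5)}, index=["e1"])
        high = classify_inclusion(psi)
        assert not high.loc["e1"].any()

    def test_missing_values_stay_missing(self):
        psi = pd.DataFrame({"a": [0.9], "b": [np.nan], "c": [0.1]}, index=["e"])
        high = classify_inclusion(psi)
        assert pd.isna(high.loc["e", "b"])

    def test_all_missing_event_dropped_with_warning(self):
        psi = pd.DataFrame({"a": [np.nan, 0.5], "b": [np.nan, 0.9]},
                           index=["dead", "live"])
        with pytest.warns(UserWarning):
            high = classify_inclusion(psi)
        assert list(high.index) == ["live"]

    def test_null_cohort_keeps_high_fraction_below_half(self):
        rng = np.random.default_rng(0)
        psi = pd.DataFrame(
            rng.beta(5, 5, size=(20, 1000)),
            index=[f"e{i}" for i in range(20)],
            columns=[f"p{i}" for i in range(1000)],
        )
        high = classify_inclusion(psi)
        assert high.to_numpy(dtype=float).mean() < 0.5


class TestEventScore:
    def test_all_false_scores_zero(self):
        m = pd.DataFrame(False, index=["e1", "e2"], columns=["p1", "p2"]).astype("boolean")
        assert (patient_event_score(m) == 0).all()

    def test_identity_pattern_scores_one(self):
        m = pd.DataFrame(np.eye(5, dtype=bool),
                         index=[f"e{i}" for i in range(5)],
                         columns=[f"p{i}" for i in range(5)]).astype("boolean")
        assert (patient_event_score(m) == 1).all()

    def test_equals_column_sums_with_missing_as_zero(self):
        rng = np.random.default_rng(1)
        vals = rng.random((8, 12))
        m = pd.DataFrame(vals > 0.5).astype("boolean")
        m.iloc[0, 0] = pd.NA
        scores = patient_event_score(m)
        brute = (vals > 0.5)
        brute[0, 0] = False
        assert list(scores) == list(brute.sum(axis=0))


class TestStratification:
    def test_scores_1_to_100_split_quartiles(self):
        scores = pd.Series(range(1, 101), index=[f"p{i}" for i in range(100)])
        res = stratify_quartiles(scores.astype(float))
        assert (res.groups == "high").sum() == 25
        assert (res.groups == "low").sum() == 25
        assert set(res.scores[res.groups == "high"]) == set(range(76, 101))

    def test_all_equal_scores_degenerate(self):
        scores = pd.Series([3.0] * 20, index=[f"p{i}" for i in range(20)])
        with pytest.warns(UserWarning):
            res = stratify_quartiles(scores)
        assert (res.groups == "high").sum() == 0

    def test_binary_scores_tie_behaviour(self):
        # 50:50 zeros and ones: P25 = 0, P75 = 1 -> ones are mid (<= P75)
        scores = pd.Series([0.0] * 10 + [1.0] * 10,
                           index=[f"p{i}" for i in range(20)])
        with pytest.warns(UserWarning):
            res = stratify_quartiles(scores)
        assert (res.groups == "low").sum() == 10
        assert (res.groups == "mid").sum() == 10

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            stratify_quartiles(pd.Series([1.0] * 5))


def _survival_frame(times, events, labels):
    idx = [f"p{i}" for i in range(len(times))]
    return (pd.Series(times, index=idx, dtype=float),
            pd.Series(events, index=idx),
            pd.Series(labels, index=idx))


class TestKmLogrank:
    def test_identical_groups_not_separated(self):
        t, e, g = _survival_frame([10, 20, 30, 10, 20, 30],
                                  [1, 1, 1, 1, 1, 1],
                                  ["low", "low", "low", "high", "high", "high"])
        res = km_logrank(g, t, e)
        assert res["logrank_statistic"] == pytest.approx(0.0, abs=1e-9)
        assert res["logrank_p"] == pytest.approx(1.0, abs=1e-9)

    def test_separated_groups_give_extreme_pvalue(self):
        times = list(range(1, 51)) + list(range(1001, 1051))
        events = [1] * 100
        labels = ["low"] * 50 + ["high"] * 50
        t, e, g = _survival_frame(times, events, labels)
        assert km_logrank(g, t, e)["logrank_p"] < 1e-6

    def test_all_censored_curves_stay_at_one(self):
        t, e, g = _survival_frame([5, 10, 15, 5, 10, 15], [0] * 6,
                                  ["low"] * 3 + ["high"] * 3)
        res = km_logrank(g, t, e)
        for curve in res["curves"].values():
            assert (curve.to_numpy() == 1.0).all()


class TestCoxModel:
    def test_log2_identity(self):
        rng = np.random.default_rng(2)
        n = 100
        z = rng.integers(0, 2, n)
        t = rng.exponential(100 / (1 + z))
        idx = [f"p{i}" for i in range(n)]
        res = cox_hr(pd.Series(z, index=idx, dtype=float),
                     pd.Series(t, index=idx), pd.Series([1] * n, index=idx))
        term = res["terms"]["score"]
        assert term["log2_hr"] == pytest.approx(np.log2(term["hr"]))

    def test_categorical_reference_is_high_group(self):
        rng = np.random.default_rng(3)
        n = 120
        groups = pd.Series((["low"] * 40 + ["mid"] * 40 + ["high"] * 40),
                           index=[f"p{i}" for i in range(n)])
        hazard = groups.map({"low": 3.0, "mid": 2.0, "high": 1.0})
        t = pd.Series(rng.exponential(100 / hazard), index=groups.index)
        e = pd.Series([1] * n, index=groups.index)
        res = cox_hr(groups, t, e)
        assert res["converged"]
        assert res["terms"]["vs_high_low"]["hr"] > 1.5

    def test_recovers_twofold_hazard(self):
        cfg = SimConfig(seed=41, n_patients=200)
        survival, _, _, truth = generate_cohort(cfg)
        latent = pd.Series(truth.patients)[survival.index].astype(float)
        res = cox_hr(latent, survival["time_days"], survival["event"])
        assert res["converged"]
        assert 1.5 <= res["terms"]["score"]["hr"] <= 2.7


class TestCircBurden:
    def test_all_zero_counts_give_zero_burden(self):
        counts = pd.DataFrame(0, index=["c1", "c2"],
                              columns=[f"p{i}" for i in range(10)])
        res = circ_burden(counts)
        assert (res["burden"] == 0).all()

    def test_private_circ_counts_toward_owner(self):
        counts = pd.DataFrame(0, index=["c1"],
                              columns=[f"p{i}" for i in range(20)])
        counts.loc["c1", "p7"] = 9
        res = circ_burden(counts)
        assert res["burden"]["p7"] == 1
        assert res["burden"].drop("p7").sum() == 0

    def test_anticorrelated_generator_separates_regulator_levels(self):
        cfg = SimConfig(seed=17, n_patients=150)
        survival, _, circ_counts, _ = generate_cohort(cfg)
        res = circ_burden(circ_counts, survival["regulator_fpkm"])
        contrast = res["regulator_contrast"]
        assert contrast["median_high_burden"] < contrast["median_low_burden"]
        assert contrast["ranksum_p"] < 0.05

    def test_patient_mismatch_rejected(self):
        counts = pd.DataFrame(1, index=["c1"], columns=["p1", "p2"])
        reg = pd.Series([1.0, 2.0], index=["p2", "p1"])
        with pytest.raises(ValueError):
            circ_burden(counts, reg)


class TestZscoreCorrelation:
    def test_perfect_anticorrelation(self):
        reg = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        counts = pd.DataFrame([[8.0, 6.0, 4.0, 2.0]], index=["c1"],
                              columns=list("abcd"))
        r, _ = zscore_correlation(counts, reg)
        assert r == pytest.approx(-1.0)

    def test_single_row_matches_raw_pearson(self):
        rng = np.random.default_rng(5)
        reg = pd.Series(rng.random(30), index=[f"p{i}" for i in range(30)])
        counts = pd.DataFrame([rng.random(30)], index=["c1"], columns=reg.index)
        r, _ = zscore_correlation(counts, reg)
        raw = stats.pearsonr(counts.loc["c1"], reg)[0]
        assert r == pytest.approx(raw, abs=1e-12)

    def test_independent_data_near_zero(self):
        rng = np.random.default_rng(6)
        cols = [f"p{i}" for i in range(1000)]
        reg = pd.Series(rng.random(1000), index=cols)
        counts = pd.DataFrame(rng.random((3, 1000)), columns=cols,
                              index=["c1", "c2", "c3"])
        r, _ = zscore_correlation(counts, reg)
        assert abs(r) < 0.1

    def test_zero_variance_row_dropped_with_warning(self):
        reg = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        counts = pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 2.0, 4.0]],
                              index=["flat", "var"], columns=list("abc"))
        with pytest.warns(UserWarning):
            r, _ = zscore_correlation(counts, reg)
        assert np.isfinite(r)
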