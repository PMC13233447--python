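"""Survival machinery: stratification, complete-case filtering, Cox and
log-rank behaviour, triage rule, and baseline tables."""

import numpy as np
import pandas as pd
import pytest

from conftest import logrank_oracle
from splicescreen.survival import (FitError, SurvivalFit, clinical_table,
                                   complete_case_filter, fit_ph, logrank,
                                   median_split, survival_triage)
from splicescreen.synth import simulate_survival_cohort


def surv_records(df, endpoint="os"):
    out = df.rename(columns={"time": f"{endpoint}_time",
                             "event": f"{endpoint}_event"})
    out.index = [f"P{i}" for i in range(len(out))]
    return out


class TestMedianSplit:
    def test_even_split(self):
        s = pd.Series([1, 2, 3, 4])
        labels = median_split(s)
        assert list(labels) == ["low", "low", "high", "high"]

    def test_ties_go_low(self):
        labels = median_split(pd.Series([1, 2, 2, 3]))
        assert list(labels) == ["low", "low", "low", "high"]

    def test_partition_is_exact(self, rng):
        s = pd.Series(rng.normal(size=101))
        labels = median_split(s)
        assert set(labels.index) == set(s.index)
        assert set(labels.unique()) <= {"low", "high"}

    def test_constant_vector_all_low(self):
        labels = median_split(pd.Series([5.0] * 10))
        assert (labels == "low").all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_split(pd.Series(dtype=float))


class TestCompleteCase:
    def make(self):
        return pd.DataFrame({
            "age": [60, np.nan, 70, 55],
            "grade": ["G3", "G3", np.nan, "G3"],
            "os_time": [100.0, 50.0, 30.0, 0.0],
            "os_event": [1, 0, 1, 1]})

    def test_zero_day_followup_excluded(self):
        out = complete_case_filter(self.make(), ["age"], "os")
        assert 3 not in out.index  # time = 0 row dropped

    def test_model_specific_missingness(self):
        df = self.make()
        with_grade = complete_case_filter(df, ["age", "grade"], "os")
        without = complete_case_filter(df, ["age"], "os")
        assert 2 not in with_grade.index  # missing grade matters
        assert 2 in without.index  # grade not in this model

    def test_complete_cohort_is_identity(self):
        df = self.make().iloc[[0]].copy()
        out = complete_case_filter(df, ["age", "grade"], "os")
        assert len(out) == 1


class TestLogrank:
    def test_identical_groups_give_null(self):
        df = pd.DataFrame({"os_time": [5, 10, 15, 5, 10, 15],
                           "os_event": [1, 1, 0, 1, 1, 0]})
        labels = pd.Series(["a"] * 3 + ["b"] * 3, index=df.index)
        stat, p = logrank(df, labels, "os")
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_strong_separation_is_significant(self):
        df = pd.DataFrame({"os_time": [1.0] * 10 + [10.0] * 10,
                           "os_event": [1] * 10 + [0] * 10})
        labels = pd.Series(["a"] * 10 + ["b"] * 10, index=df.index)
        _, p = logrank(df, labels, "os")
        assert p < 0.001

    def test_matches_textbook_oracle_on_random_cohorts(self):
        for seed in range(50):
            r = np.random.default_rng(seed)
            n = int(r.integers(10, 40))
            df = pd.DataFrame({
                "os_time": r.integers(1, 15, size=n).astype(float),
                "os_event": r.integers(0, 2, size=n)})
            labels = pd.Series(r.choice(["a", "b"], size=n), index=df.index)
            if labels.nunique() < 2:
                continue
            stat, _ = logrank(df, labels, "os")
            a, b = df[labels == "a"], df[labels == "b"]
            expected = logrank_oracle(a.os_time, a.os_event,
                                      b.os_time, b.os_event)
            assert stat == pytest.approx(expected, rel=1e-6, abs=1e-9)

    def test_single_group_rejected(self):
        df = pd.DataFrame({"os_time": [1.0, 2.0], "os_event": [1, 1]})
        labels = pd.Series(["a", "a"], index=df.index)
        with pytest.raises(ValueError):
            logrank(df, labels, "os")


class TestFitPh:
    def test_two_group_hazard_recovery(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            df = surv_records(simulate_survival_cohort(
                400, np.log(2.0), r, two_group=True))
            fit = fit_ph(df, ["x"], "os")[0]
            hits += 1.5 <= fit.hr <= 2.6
        assert hits >= 18

    def test_hr_invariant_under_time_rescaling(self, rng):
        df = surv_records(simulate_survival_cohort(300, 0.5, rng))
        fit_days = fit_ph(df, ["x"], "os")[0]
        df2 = df.copy()
        df2["os_time"] = df2["os_time"] / 30.44  # days -> months
        fit_months = fit_ph(df2, ["x"], "os")[0]
        assert fit_days.hr == pytest.approx(fit_months.hr, rel=1e-6)
        assert fit_days.p == pytest.approx(fit_months.p, rel=1e-6)

    def test_categorical_covariates_expand(self, cohort):
        bundle, _ = cohort
        fits = fit_ph(bundle.clinical_table,
                      ["expression", "age", "stage", "grade"], "os")
        names = {f.covariate for f in fits}
        assert "expression" in names
        assert any(n.startswith("stage_") for n in names)

    def test_zero_variance_covariate_rejected(self):
        df = pd.DataFrame({"x": [1.0] * 20,
                           "os_time": np.arange(1, 21, dtype=float),
                           "os_event": [1] * 20})
        with pytest.raises(FitError, match="zero-variance"):
            fit_ph(df, ["x"], "os")

    def test_no_events_rejected(self):
        df = pd.DataFrame({"x": np.arange(10.0),
                           "os_time": np.arange(1, 11, dtype=float),
                           "os_event": [0] * 10})
        with pytest.raises(FitError, match="no events"):
            fit_ph(df, ["x"], "os")


class TestSurvivalTriage:
    def fits(self, *hrps):
        return [SurvivalFit(ep, "x", hr, hr * 0.8, hr * 1.2, p, 100, 60)
                for ep, (hr, p) in zip(["os", "pfs", "dfs"], hrps)]

    def test_consistent_harmful_gene_is_stable(self):
        flags = survival_triage({"g": self.fits((1.4, 0.01), (1.3, 0.02))})
        assert flags == {"g": True}

    def test_inconsistent_direction_not_stable(self):
        flags = survival_triage({"g": self.fits((1.4, 0.01), (0.8, 0.01))})
        assert flags == {"g": False}

    def test_nonsignificant_endpoint_not_stable(self):
        flags = survival_triage({"g": self.fits((1.4, 0.01), (1.3, 0.2))})
        assert flags == {"g": False}

    def test_single_endpoint_rejected(self):
        with pytest.raises(ValueError):
            survival_triage({"g": self.fits((1.4, 0.01))})


class TestClinicalTable:
    def test_percentages_sum_to_100_within_each_group(self, cohort):
        bundle, _ = cohort
        clin = bundle.clinical_table.copy()
        clin["age_cat"] = np.where(clin.age < 60, "< 60", ">= 60")
        clin.loc[clin.age.isna(), "age_cat"] = np.nan
        labels = median_split(clin.expression)
        tab = clinical_table(clin, labels, ["age_cat", "stage", "race"])
        for (char), sub in tab.groupby("characteristic"):
            for g in ("low", "high"):
                assert sub[f"{g}_pct"].sum() == pytest.approx(100.0)

    def test_all_missing_characteristic_reports_na(self):
        df = pd.DataFrame({"grade": [np.nan, np.nan, "G3", "G3"]},
                          index=list("abcd"))
        labels = pd.Series(["low", "low", "high", "high"], index=df.index)
        tab = clinical_table(df, labels, ["grade"])
        assert np.isnan(tab.loc[tab.level == "G3", "low_pct"]).all()

    def test_fisher_fallback_on_sparse_2x2(self):
        df = pd.DataFrame({"g": ["a"] * 6 + ["b"] * 2 + ["a"] * 2 + ["b"] * 6})
        labels = pd.Series(["low"] * 8 + ["high"] * 8, index=df.index)
        tab = clinical_table(df, labels, ["g"])
        from scipy.stats import fisher_exact
        expected = fisher_exact([[6, 2], [2, 6]])[1]
        assert tab.p.iloc[0] == pytest.approx(expected)
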