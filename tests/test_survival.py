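import math

import numpy as np
import pandas as pd
import pytest

from filab.errors import FitError, SpecificationError
from filab.survival import (fit_cox, fit_rcs, hr_at, km_logrank, rcs_basis,
                            rcs_knots, subgroup_analysis)


def _surv_frame(time, event, **cols):
    df = pd.DataFrame({"time_28d": time, "death_28d": event})
    for k, v in cols.items():
        df[k] = v
    return df


def logrank_oracle(time, event, group):
    """Brute-force log-rank: sum of hypergeometric O-E over event times."""
    time, event, group = map(np.asarray, (time, event, group))
    groups = np.unique(group)
    assert len(groups) == 2
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == groups[0])).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == groups[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestFitCox:
    def test_two_group_rate_ratio_recovered(self, rng):
        """Exponential times with true rate ratio 2, n=10,000, no
        censoring: the fitted HR's CI covers 2.0."""
        n = 10_000
        g = rng.integers(0, 2, n)
        t = rng.exponential(1.0 / np.where(g == 1, 0.2, 0.1))
        df = _surv_frame(t, np.ones(n, int), filab_per_0_1=g.astype(float))
        fit = fit_cox(df, adjustment="unadjusted")
        row = fit.terms.set_index("term").loc["filab_per_0_1"]
        assert row["ci_low"] <= 2.0 <= row["ci_high"]
        assert row["hr"] == pytest.approx(2.0, rel=0.1)

    def test_breslow_close_to_efron_without_ties(self, rng):
        n = 2000
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.5 * x))
        df = _surv_frame(t, np.ones(n, int), filab_per_0_1=x)
        hr_e = fit_cox(df, ties="efron").exposure_hr()
        hr_b = fit_cox(df, ties="breslow").exposure_hr()
        assert hr_e == pytest.approx(hr_b, rel=1e-3)

    def test_constant_exposure_degenerate(self):
        df = _surv_frame([1, 2, 3, 4], [1, 1, 0, 1],
                         filab_per_0_1=[2.0, 2.0, 2.0, 2.0])
        with pytest.raises(FitError, match="constant"):
            fit_cox(df)

    def test_zero_events_rejected(self, rng):
        df = _surv_frame([1, 2, 3], [0, 0, 0], filab_per_0_1=[1.0, 2.0, 3.0])
        with pytest.raises(FitError, match="no events"):
            fit_cox(df)

    def test_tertile_reference_printed_as_one(self, rng):
        n = 3000
        lab = rng.choice(["T1", "T2", "T3"], n)
        hazard = np.exp(np.where(lab == "T3", 1.0, np.where(lab == "T2", 0.5, 0.0)))
        t = rng.exponential(1 / (0.05 * hazard))
        df = _surv_frame(np.minimum(t, 28), (t <= 28).astype(int), tertile=lab)
        fit = fit_cox(df, coding="tertiles", adjustment="unadjusted")
        terms = fit.terms.set_index("term")
        assert terms.loc["tertile_T1", "hr"] == 1.0
        assert np.isnan(terms.loc["tertile_T1", "ci_low"])
        assert terms.loc["tertile_T3", "hr"] > terms.loc["tertile_T2", "hr"] > 1
        assert fit.p_for_trend < 0.001

    def test_null_coverage_of_unadjusted_ci(self, rng):
        """No true effect: the 95% CI covers HR=1 at ~95% over 200
        replicates (binomial 3-sigma band)."""
        cover = 0
        reps = 200
        for _ in range(reps):
            n = 300
            x = rng.normal(size=n)
            t = rng.exponential(1.0, n)
            df = _surv_frame(np.minimum(t, 2.0), (t <= 2.0).astype(int),
                             filab_per_0_1=x)
            row = fit_cox(df).terms.iloc[0]
            cover += row["ci_low"] <= 1.0 <= row["ci_high"]
        se = math.sqrt(0.95 * 0.05 / reps)
        assert abs(cover / reps - 0.95) <= 3 * se + 0.01


class TestRcs:
    def test_basis_linear_beyond_boundary_knots(self, rng):
        knots = np.array([0.1, 0.4, 0.6, 0.9])
        x = np.linspace(1.5, 3.0, 50)  # beyond the last knot
        b = rcs_basis(x, knots)
        for j in range(b.shape[1]):
            slope = np.diff(b[:, j]) / np.diff(x)
            assert np.allclose(slope, slope[0], atol=1e-9)

    def test_knot_count_validation(self, rng):
        with pytest.raises(SpecificationError):
            rcs_knots(rng.normal(size=100), n_knots=2)

    def test_reference_hr_is_exactly_one(self, rng):
        n = 3000
        x = rng.uniform(0.1, 0.9, n)
        t = rng.exponential(np.exp(-2 * x))
        df = _surv_frame(t, np.ones(n, int), score=x)
        curve = fit_rcs(df, adjustment="unadjusted", reference=0.5)
        assert hr_at(curve, 0.5) == pytest.approx(1.0, abs=1e-6)
        assert curve.reference == 0.5

    def test_nonlinearity_power_on_quadratic_hazard(self, rng):
        n = 10_000
        x = rng.uniform(0, 1, n)
        lp = 4.0 * (x - 0.5) ** 2
        t = rng.exponential(np.exp(-lp))
        df = _surv_frame(t, np.ones(n, int), score=x)
        curve = fit_rcs(df, adjustment="unadjusted")
        assert curve.p_nonlinearity < 1e-3

    def test_type_one_error_on_linear_hazard(self, rng):
        """Log-linear truth: the non-linearity Wald test rejects at
        ~5%; over 100 replicates at least 90% of p-values exceed 0.05."""
        keep = 0
        reps = 100
        for _ in range(reps):
            n = 1500
            x = rng.uniform(0, 1, n)
            t = rng.exponential(np.exp(-1.5 * x))
            c = rng.exponential(2.0, n)
            df = _surv_frame(np.minimum(t, c), (t <= c).astype(int), score=x)
            keep += fit_rcs(df, adjustment="unadjusted").p_nonlinearity > 0.05
        assert keep / reps >= 0.90


class TestKmLogrank:
    def test_hand_product_limit(self):
        """Times {1 event, 2 censored, 3 event}: S(1) = 2/3, and at t=3
        the single remaining subject dies, so S(3) = 2/3 x (1 - 1/1) = 0."""
        df = _surv_frame([1, 2, 3], [1, 0, 1], tertile=["all"] * 3)
        res = km_logrank(df, group_col="tertile")
        s = res.curves.set_index("time")["survival"]
        assert s.loc[1.0] == pytest.approx(2 / 3)
        assert s.loc[3.0] == pytest.approx(0.0)
        assert res.logrank_stat is None

    def test_hand_product_limit_with_late_risk_set(self):
        """{1 event, 2 censored, 3 event, 4 censored}: S(3) = 2/3 x 1/2."""
        df = _surv_frame([1, 2, 3, 4], [1, 0, 1, 0], tertile=["all"] * 4)
        res = km_logrank(df, group_col="tertile")
        s = res.curves.set_index("time")["survival"]
        assert s.loc[1.0] == pytest.approx(3 / 4)
        assert s.loc[3.0] == pytest.approx(3 / 4 * 1 / 2)

    def test_identical_groups_give_zero_statistic(self):
        time = [1, 2, 3, 4, 5, 6]
        event = [1, 0, 1, 1, 0, 1]
        df = _surv_frame(time + time, event + event,
                         tertile=["a"] * 6 + ["b"] * 6)
        res = km_logrank(df, group_col="tertile")
        assert res.logrank_stat == pytest.approx(0.0, abs=1e-12)
        assert res.logrank_p == pytest.approx(1.0)

    def test_matches_hand_hypergeometric_oracle(self, rng):
        n = 20
        time = rng.integers(1, 15, n).astype(float)
        event = rng.integers(0, 2, n)
        group = np.array(["x"] * 10 + ["y"] * 10)
        if event.sum() == 0:
            event[0] = 1
        df = _surv_frame(time, event, tertile=group)
        res = km_logrank(df, group_col="tertile")
        assert res.logrank_stat == pytest.approx(
            logrank_oracle(time, event, group), rel=1e-9)
        assert res.df == 1

    def test_survival_monotone_and_starts_at_one(self, small_cohort, registry):
        from filab.score import score_stays
        scores = score_stays(small_cohort.lab_events, small_cohort.vitals,
                             registry, stay_ids=small_cohort.stays["stay_id"],
                             tertile_cutpoints="empirical")
        df = small_cohort.stays.merge(scores, on="stay_id")
        res = km_logrank(df, horizon=28)
        for _, g in res.curves.groupby("group"):
            vals = g.sort_values("time")["survival"].to_numpy()
            assert vals[0] == 1.0
            assert (np.diff(vals) <= 1e-12).all()
        assert 0 <= res.logrank_p <= 1

    def test_no_censoring_km_equals_event_fraction(self, rng):
        n = 500
        t = rng.exponential(10, n)
        df = _surv_frame(np.minimum(t, 28), (t <= 28).astype(int),
                         tertile=["all"] * n)
        res = km_logrank(df, group_col="tertile", horizon=28)
        s_end = res.curves["survival"].iloc[-1]
        assert s_end == pytest.approx(1 - (t <= 28).mean(), abs=1e-9)


class TestSubgroups:
    @staticmethod
    def _cohort(rng, n=4000, interaction=0.0):
        x = rng.normal(4.8, 0.9, n)
        male = rng.integers(0, 2, n)
        cols = dict(
            filab_per_0_1=x, sex_male=male, age=rng.uniform(30, 90, n),
            race_white=rng.integers(0, 2, n), sepsis=rng.integers(0, 2, n),
            mv=rng.integers(0, 2, n), heart_failure=rng.integers(0, 2, n),
            sofa=rng.uniform(0, 15, n),
        )
        lp = 0.25 * (x - 4.8) + interaction * male * (x - 4.8)
        t = rng.exponential(np.exp(-lp) / 0.01)
        return _surv_frame(np.minimum(t, 28), (t <= 28).astype(int), **cols)

    def test_strata_partition_and_estimates(self, rng):
        df = self._cohort(rng)
        out = subgroup_analysis(df, variables=["sex", "sofa_5"],
                                adjustment="unadjusted")
        for var in ("sex", "sofa_5"):
            sub = out[out["variable"] == var]
            assert sub["n"].sum() == len(df)
            assert sub["estimable"].all()
            assert ((sub["ci_low"] < sub["hr"]) & (sub["hr"] < sub["ci_high"])).all()

    def test_injected_interaction_detected(self, rng):
        df = self._cohort(rng, n=20_000, interaction=0.5)
        out = subgroup_analysis(df, variables=["sex"], adjustment="unadjusted")
        assert out["p_interaction"].iloc[0] < 0.01

    def test_null_interaction_type_one_error(self, rng):
        """No true interaction: rejection rate at alpha=0.05 stays in
        the binomial band around 5% over 100 replicates."""
        rejections = 0
        reps = 100
        for _ in range(reps):
            df = self._cohort(rng, n=800)
            out = subgroup_analysis(df, variables=["sex"],
                                    adjustment="unadjusted")
            rejections += out["p_interaction"].iloc[0] < 0.05
        se = math.sqrt(0.05 * 0.95 / reps)
        assert abs(rejections / reps - 0.05) <= 3 * se + 0.01

    def test_constant_stratifier_not_estimable(self, rng):
        df = self._cohort(rng, n=200)
        df["sex_male"] = 1
        out = subgroup_analysis(df, variables=["sex"], adjustment="unadjusted")
        assert np.isnan(out["p_interaction"]).all()
        assert len(out) == 1  # only the populated stratum

    def test_zero_event_stratum_flagged(self, rng):
        df = self._cohort(rng, n=300)
        df.loc[df["sex_male"] == 1, "death_28d"] = 0
        out = subgroup_analysis(df, variables=["sex"], adjustment="unadjusted")
        male = out[out["level"] == "male"].iloc[0]
        assert not male["estimable"] and np.isnan(male["hr"])
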