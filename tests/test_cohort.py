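import math

import numpy as np
import pandas as pd
import pytest

from filab.cohort import (FILTER_ORDER, apply_filters, drop_sparse_missing,
                          impute_covariates, prepare_analysis_table, vif_screen)
from filab.errors import DataError
from filab.score import score_stays
from filab.simulate import SimulationConfig, generate_cohort


def _stay(stay_id, **overrides):
    base = dict(
        stay_id=stay_id, age=55.0, icu_los_days=3.0, pregnant=0,
        is_first_icu_stay=1, respiratory_rate=28.0, bicarbonate=24.0,
        glucocorticoid=1.0, montelukast=0.0,
    )
    base.update(overrides)
    return base


def _scores(stay_ids, ineligible=()):
    return pd.DataFrame({
        "stay_id": stay_ids,
        "score": [0.4] * len(stay_ids),
        "eligible": [sid not in ineligible for sid in stay_ids],
    })


class TestApplyFilters:
    def test_one_violation_per_rule(self):
        """Six stays, five violating one exclusion rule each: one stay
        survives and the log attributes exactly one removal per rule."""
        stays = pd.DataFrame([
            _stay(1),                                   # clean
            _stay(2, age=16.0),                         # minor
            _stay(3, icu_los_days=0.5),                 # < 24 h stay
            _stay(4, pregnant=1),                       # pregnancy
            _stay(5, respiratory_rate=np.nan),          # missing field
            _stay(6),                                   # FI-Lab ineligible
        ])
        cohort, log = apply_filters(stays, _scores(stays.stay_id, ineligible={6}))
        assert list(cohort["stay_id"]) == [1]
        frame = log.to_frame()
        assert list(frame["rule"]) == FILTER_ORDER
        assert frame["n_removed"].sum() == 5
        assert log.n_final == 1 and log.n_initial == 6
        removed = dict(zip(frame["rule"], frame["n_removed"]))
        assert removed["repeat_icu_stay"] == 0
        for rule in FILTER_ORDER[1:]:
            assert removed[rule] == 1, rule

    def test_no_violations_is_identity(self):
        stays = pd.DataFrame([_stay(i) for i in range(1, 5)])
        cohort, log = apply_filters(stays, _scores(stays.stay_id))
        assert len(cohort) == 4
        assert (log.to_frame()["n_removed"] == 0).all()

    def test_cascade_idempotent(self):
        stays = pd.DataFrame([_stay(1), _stay(2, age=15.0), _stay(3, pregnant=1)])
        cohort, _ = apply_filters(stays, _scores(stays.stay_id))
        again, log2 = apply_filters(
            cohort.drop(columns=["score", "eligible"]),
            _scores(cohort.stay_id))
        assert (log2.to_frame()["n_removed"] == 0).all()
        assert list(again["stay_id"]) == list(cohort["stay_id"])

    def test_missing_filab_result_rejected(self):
        stays = pd.DataFrame([_stay(1), _stay(2)])
        with pytest.raises(DataError, match="FI-Lab"):
            apply_filters(stays, _scores([1]))

    def test_injected_violation_rate_recovered(self, registry):
        """10% injected minors at n=2,000: removal count within 3
        binomial SEs of 200."""
        cfg = SimulationConfig(
            n_patients=2000, seed=37,
            filter_violation_fractions={"age_under_18": 0.10})
        t = generate_cohort(cfg)
        scores = score_stays(t.lab_events, t.vitals, registry,
                             stay_ids=t.stays["stay_id"])
        _, log = apply_filters(t.stays, scores)
        removed = dict(zip(log.to_frame()["rule"], log.to_frame()["n_removed"]))
        se = math.sqrt(0.1 * 0.9 * 2000)
        assert abs(removed["age_under_18"] - 200) <= 3 * se

    def test_counts_sum_to_initial(self, registry, small_cohort):
        scores = score_stays(small_cohort.lab_events, small_cohort.vitals,
                             registry, stay_ids=small_cohort.stays["stay_id"])
        cohort, log = apply_filters(small_cohort.stays, scores)
        frame = log.to_frame()
        assert len(small_cohort.stays) - frame["n_removed"].sum() == len(cohort)
        assert (frame["n_remaining"].diff().dropna() <= 0).all()


class TestDropSparseMissing:
    def test_sub_threshold_rows_dropped(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=1000), "b": rng.normal(size=1000)})
        df.loc[[3, 400, 777], "a"] = np.nan
        out, report = drop_sparse_missing(df, threshold=0.01)
        assert len(out) == 997
        rep = report.set_index("variable")
        assert rep.loc["a", "dropped"] and rep.loc["a", "n_missing"] == 3

    def test_above_threshold_untouched(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=200), "b": rng.normal(size=200)})
        df.loc[:9, "a"] = np.nan  # 5% missing: routed to imputation instead
        out, report = drop_sparse_missing(df, threshold=0.01)
        assert len(out) == 200
        assert not report.set_index("variable").loc["a", "dropped"]

    def test_complete_table_identity(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50)})
        out, _ = drop_sparse_missing(df)
        pd.testing.assert_frame_equal(out, df)

    def test_column_mode_drops_column(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=1000), "b": rng.normal(size=1000)})
        df.loc[5, "a"] = np.nan
        out, _ = drop_sparse_missing(df, mode="columns")
        assert "a" not in out.columns and len(out) == 1000


class TestImputeCovariates:
    def test_no_missing_identity(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=40), "y": rng.normal(size=40)})
        pd.testing.assert_frame_equal(impute_covariates(df), df)

    def test_linear_relation_recovered(self, rng):
        """y = 2x exactly; the chained ridge imputation of a missing y
        at x = 5 lands near 10 (ridge shrinkage tolerance 0.1)."""
        x = np.arange(0, 10.0)
        df = pd.DataFrame({"x": x, "y": 2 * x, "z": np.ones(10)})
        df.loc[5, "y"] = np.nan
        out = impute_covariates(df, columns=["x", "y"])
        assert out.loc[5, "y"] == pytest.approx(10.0, abs=0.1)
        # observed cells untouched
        assert (out.loc[out.index != 5, "y"] == df.loc[df.index != 5, "y"]).all()

    def test_beats_mean_imputation_on_correlated_data(self, rng):
        n = 5000
        x = rng.normal(size=n)
        y = 0.9 * x + math.sqrt(1 - 0.81) * rng.normal(size=n)
        df = pd.DataFrame({"x": x, "y": y})
        mask = rng.random(n) < 0.05
        df.loc[mask, "y"] = np.nan
        out = impute_covariates(df, seed=1)
        rmse = float(np.sqrt(np.mean((out.loc[mask, "y"] - y[mask]) ** 2)))
        assert rmse < np.std(y)        # beats marginal-mean imputation
        assert rmse == pytest.approx(math.sqrt(1 - 0.81), rel=0.25)

    def test_deterministic_given_seed(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=100), "y": rng.normal(size=100),
                           "z": rng.normal(size=100)})
        df.loc[:4, "z"] = np.nan
        a = impute_covariates(df, seed=3)
        b = impute_covariates(df, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_all_missing_column_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [np.nan, np.nan], "z": [3.0, 4.0]})
        with pytest.raises(DataError, match="entirely missing"):
            impute_covariates(df)


class TestVifScreen:
    def test_orthogonal_columns(self):
        n = 64
        i = np.arange(n)
        df = pd.DataFrame({
            "a": np.where(i % 2 == 0, 1.0, -1.0),
            "b": np.where((i // 2) % 2 == 0, 1.0, -1.0),
            "c": np.where((i // 4) % 2 == 0, 1.0, -1.0),
        })
        rep = vif_screen(df)
        assert np.allclose(rep["vif"], 1.0)
        assert not rep["flagged"].any()

    def test_duplicated_column_infinite(self, rng):
        x = rng.normal(size=100)
        rep = vif_screen(pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=100)}))
        r = rep.set_index("variable")
        assert np.isinf(r.loc["a", "vif"]) and r.loc["a", "flagged"]

    def test_closed_form_from_known_correlation(self, rng):
        """corr 0.8 => R^2 = 0.64 => VIF = 1/(1-0.64) ~ 2.78, flagged."""
        n = 200_000
        x = rng.normal(size=n)
        y = 0.8 * x + 0.6 * rng.normal(size=n)
        rep = vif_screen(pd.DataFrame({"x": x, "y": y})).set_index("variable")
        assert rep.loc["x", "vif"] == pytest.approx(1 / (1 - 0.64), rel=0.02)
        assert rep.loc["x", "flagged"]

    def test_matches_direct_r2(self, rng):
        df = pd.DataFrame(rng.normal(size=(500, 4)),
                          columns=["a", "b", "c", "d"])
        df["d"] = df["a"] * 0.5 + df["b"] * 0.3 + rng.normal(size=500)
        rep = vif_screen(df).set_index("variable")
        # independent oracle: R^2 via numpy correlation of fitted values
        X = np.column_stack([np.ones(500), df[["a", "b", "c"]].to_numpy()])
        beta, *_ = np.linalg.lstsq(X, df["d"].to_numpy(), rcond=None)
        r2 = np.corrcoef(X @ beta, df["d"])[0, 1] ** 2
        assert rep.loc["d", "vif"] == pytest.approx(1 / (1 - r2), rel=1e-6)

    def test_missing_rejected(self):
        df = pd.DataFrame({"a": [1.0, np.nan], "b": [1.0, 2.0]})
        with pytest.raises(DataError):
            vif_screen(df)


def test_prepare_analysis_table_codings():
    df = pd.DataFrame({
        "stay_id": [1, 2], "sex": ["male", "female"],
        "race": ["white", "nonwhite"], "score": [0.4, 0.6],
    })
    out = prepare_analysis_table(df)
    assert list(out["sex_male"]) == [1, 0]
    assert list(out["race_white"]) == [1, 0]
    assert out["filab_per_0_1"].tolist() == pytest.approx([4.0, 6.0])
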