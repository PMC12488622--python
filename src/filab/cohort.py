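"""Cohort assembly: inclusion/exclusion cascade, covariate imputation,
multicollinearity screening.

The exclusion cascade mirrors the usual ICU admission-cohort filters,
applied in a fixed, audited order: repeat ICU stays, age < 18 years,
ICU length of stay < 24 h, pregnancy, missing required first-day fields
(respiratory rate, bicarbonate, glucocorticoid, montelukast), and
frailty-index ineligibility (more than 12 of the 33 items unmeasured).
Each step is logged with the number removed and remaining, so the
counts are reproducible and order-auditable.

Missing covariate handling follows common EHR practice: variables with
less than 1% missingness are resolved by complete-case row removal
(optionally column dropping), anything above that is completed by
chained-equation single imputation with a Bayesian ridge regressor in
each round-robin step (scikit-learn's iterative imputer).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, SpecificationError

__all__ = [
    "FILTER_ORDER", "ExclusionLog", "apply_filters", "prepare_analysis_table",
    "drop_sparse_missing", "impute_covariates", "vif_screen",
]

#: fixed exclusion order; counts are order-dependent and logged
FILTER_ORDER = [
    "repeat_icu_stay",
    "age_under_18",
    "icu_los_under_24h",
    "pregnancy",
    "missing_required_field",
    "filab_ineligible",
]

REQUIRED_FIELDS = ["respiratory_rate", "bicarbonate", "glucocorticoid", "montelukast"]


@dataclass
class ExclusionLog:
    """Ordered record of the filter cascade."""

    steps: pd.DataFrame  # columns: rule, n_removed, n_remaining

    @property
    def n_initial(self) -> int:
        return int(self.steps["n_removed"].sum() + self.n_final)

    @property
    def n_final(self) -> int:
        return int(self.steps["n_remaining"].iloc[-1]) if len(self.steps) else 0

    def to_frame(self) -> pd.DataFrame:
        return self.steps.copy()


def _violates(rule: str, df: pd.DataFrame) -> pd.Series:
    if rule == "repeat_icu_stay":
        return df["is_first_icu_stay"].astype(float) == 0
    if rule == "age_under_18":
        return df["age"].astype(float) < 18
    if rule == "icu_los_under_24h":
        return df["icu_los_days"].astype(float) < 1.0
    if rule == "pregnancy":
        return df["pregnant"].astype(float) == 1
    if rule == "missing_required_field":
        return df[REQUIRED_FIELDS].isna().any(axis=1)
    if rule == "filab_ineligible":
        return ~df["eligible"].astype(bool)
    raise SpecificationError(f"unknown filter rule {rule!r}")


def apply_filters(
    stays: pd.DataFrame, filab_results: pd.DataFrame
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the exclusion cascade in :data:`FILTER_ORDER`.

    ``filab_results`` must cover every stay (columns ``stay_id``,
    ``eligible``, ``score``...).  Returns the surviving stays joined
    with their FI-Lab columns, plus the ordered exclusion log.
    """
    missing_scores = set(stays["stay_id"]) - set(filab_results["stay_id"])
    if missing_scores:
        raise DataError(
            f"{len(missing_scores)} stay(s) lack a FI-Lab result, "
            f"e.g. {sorted(missing_scores)[:5]}"
        )
    score_cols = [c for c in filab_results.columns if c != "stay_id"]
    merged = stays.merge(filab_results, on="stay_id", how="left", validate="1:1")

    rows = []
    current = merged
    for rule in FILTER_ORDER:
        bad = _violates(rule, current)
        n_removed = int(bad.sum())
        current = current.loc[~bad]
        rows.append({"rule": rule, "n_removed": n_removed, "n_remaining": len(current)})
    log = ExclusionLog(pd.DataFrame(rows, columns=["rule", "n_removed", "n_remaining"]))
    return current.reset_index(drop=True), log


def prepare_analysis_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add model-ready numeric codings to a filtered cohort.

    Adds ``sex_male`` / ``race_white`` indicators and the per-0.1-unit
    exposure ``filab_per_0_1`` = score / 0.1.
    """
    out = cohort.copy()
    out["sex_male"] = (out["sex"] == "male").astype(int)
    out["race_white"] = (out["race"] == "white").astype(int)
    out["filab_per_0_1"] = out["score"].astype(float) / 0.1
    return out


def drop_sparse_missing(
    table: pd.DataFrame,
    threshold: float = 0.01,
    columns: list[str] | None = None,
    mode: str = "rows",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Resolve sub-threshold missingness by complete-case removal.

    For each covariate whose missing fraction is strictly positive and
    below ``threshold``, rows with a missing value are dropped
    (``mode="rows"``, default) or the column itself is dropped
    (``mode="columns"``).  Covariates at or above the threshold are left
    untouched (they are routed to imputation instead).  Returns the
    reduced table and a per-variable report.
    """
    if not 0 < threshold < 1:
        raise SpecificationError(f"threshold must be in (0, 1), got {threshold}")
    if mode not in ("rows", "columns"):
        raise SpecificationError(f"mode must be 'rows' or 'columns', got {mode!r}")
    cols = columns if columns is not None else list(table.columns)
    n = len(table)
    report_rows = []
    out = table
    for c in cols:
        n_missing = int(out[c].isna().sum())
        frac = n_missing / n if n else 0.0
        acted = 0 < frac < threshold
        report_rows.append(
            {"variable": c, "n_missing": n_missing, "fraction": frac, "dropped": acted}
        )
        if acted:
            if mode == "rows":
                out = out.loc[out[c].notna()]
            else:
                out = out.drop(columns=[c])
    report = pd.DataFrame(report_rows, columns=["variable", "n_missing", "fraction", "dropped"])
    return out.reset_index(drop=True), report


def impute_covariates(
    table: pd.DataFrame,
    columns: list[str] | None = None,
    max_iter: int = 10,
    seed: int = 0,
    tol: float = 1e-3,
) -> pd.DataFrame:
    """Chained-equation single imputation with a Bayesian ridge estimator.

    Each incomplete numeric column is regressed on the others in
    round-robin order until ``max_iter`` cycles or the maximum absolute
    cell change falls below ``tol``; observed cells are never altered.
    Deterministic given ``seed``.
    """
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer
    from sklearn.linear_model import BayesianRidge

    if columns is None:
        columns = [
            c for c in table.columns
            if pd.api.types.is_numeric_dtype(table[c])
        ]
    sub = table[columns]
    incomplete = [c for c in columns if sub[c].isna().any()]
    if not incomplete:
        return table.copy()
    for c in incomplete:
        if sub[c].isna().all():
            raise DataError(f"column {c!r} is entirely missing; cannot impute")
        if not pd.api.types.is_numeric_dtype(sub[c]):
            raise DataError(f"column {c!r} is non-numeric; imputation unsupported")
    if len(columns) < 2 or len(columns) == len(incomplete):
        raise DataError("need at least one complete predictor column to impute")

    imp = IterativeImputer(
        estimator=BayesianRidge(),
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
        sample_posterior=False,
        keep_empty_features=True,
    )
    completed = imp.fit_transform(sub.to_numpy(dtype=float))
    out = table.copy()
    filled = pd.DataFrame(completed, columns=columns, index=sub.index)
    for c in incomplete:
        mask = sub[c].isna()
        out.loc[mask, c] = filled.loc[mask, c]
    return out


def vif_screen(design: pd.DataFrame, flag_above: float = 2.0) -> pd.DataFrame:
    """Variance inflation factors, VIF_j = 1 / (1 - R²_j).

    Each column is regressed (with intercept) on all the others;
    perfectly collinear columns get an infinite VIF and are flagged
    rather than raising.  Requires a complete numeric matrix with at
    least two columns.
    """
    if design.shape[1] < 2:
        raise SpecificationError("VIF needs at least 2 columns")
    if design.isna().any().any():
        raise DataError("VIF requires a complete (no-missing) design matrix")
    X = design.to_numpy(dtype=float)
    n = X.shape[0]
    rows = []
    for j, name in enumerate(design.columns):
        y = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_tot = float(((y - y.mean()) ** 2).sum())
        ss_res = float((resid**2).sum())
        if ss_tot <= 0:
            r2 = 0.0  # constant column carries no collinearity signal
        else:
            r2 = 1.0 - ss_res / ss_tot
        vif = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append({"variable": name, "r_squared": r2, "vif": vif,
                     "flagged": bool(vif > flag_above)})
    return pd.DataFrame(rows, columns=["variable", "r_squared", "vif", "flagged"])
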