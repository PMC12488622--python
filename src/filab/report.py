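"""Baseline-characteristics summaries and the run report.

``summarize_baseline`` produces a Table-1-style summary by group:
continuous variables as mean ± SD with one-way ANOVA when every group
passes Shapiro-Wilk normality (alpha = 0.05, configurable), otherwise
median (IQR) with a Kruskal-Wallis rank test; categorical variables as
n (%) with a chi-square test, or Fisher's exact test for 2x2 tables
with any expected cell of 5 or fewer.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

__all__ = ["summarize_baseline", "render_report"]


def _is_categorical(s: pd.Series) -> bool:
    if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool:
        return True
    vals = s.dropna().unique()
    return len(vals) <= 2 and set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}


def _shapiro_normal(x: np.ndarray, alpha: float, seed: int = 0) -> bool:
    x = x[np.isfinite(x)]
    if len(x) < 3 or np.ptp(x) == 0:
        return False
    if len(x) > 5000:  # Shapiro-Wilk p is unreliable beyond ~5k; subsample
        rng = np.random.default_rng(seed)
        x = rng.choice(x, 5000, replace=False)
    return stats.shapiro(x).pvalue > alpha


def summarize_baseline(
    df: pd.DataFrame,
    group_col: str,
    variables: list[str] | None = None,
    shapiro_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-variable group summaries with between-group tests."""
    if group_col not in df.columns:
        raise DataError(f"grouping column {group_col!r} absent")
    groups = sorted(df[group_col].dropna().unique())
    if not groups:
        raise DataError("grouping column has no non-missing levels")
    for g in groups:
        if not len(df[df[group_col] == g]):
            raise DataError(f"group {g!r} is empty")
    if variables is None:
        variables = [c for c in df.columns if c != group_col]

    rows = []
    for var in variables:
        series = df[var]
        by_group = [df.loc[df[group_col] == g, var] for g in groups]
        row: dict = {"variable": var}
        if _is_categorical(series):
            counts = pd.crosstab(df[group_col], series.astype(str))
            if counts.shape[1] < 2:
                p, test = np.nan, "degenerate"
            else:
                chi2, p_chi, _, expected = stats.chi2_contingency(counts)
                if counts.shape == (2, 2) and (expected <= 5).any():
                    _, p = stats.fisher_exact(counts.to_numpy())
                    test = "fisher_exact"
                else:
                    p, test = p_chi, "chi_square"
            row["type"] = "categorical"
            total_n = series.notna().sum()
            if set(counts.columns) <= {"0", "1", "0.0", "1.0", "True", "False"}:
                k_all = int(df[var].astype(float).sum())
                row["overall"] = f"{k_all} ({100 * k_all / total_n:.1f})"
                for g, sub in zip(groups, by_group):
                    k = int(sub.astype(float).sum())
                    row[str(g)] = f"{k} ({100 * k / len(sub):.1f})" if len(sub) else ""
            else:
                row["overall"] = "; ".join(
                    f"{lvl}: {int(series.astype(str).eq(lvl).sum())}"
                    for lvl in counts.columns)
                for g, sub in zip(groups, by_group):
                    row[str(g)] = "; ".join(
                        f"{lvl}: {int(sub.astype(str).eq(lvl).sum())}"
                        for lvl in counts.columns)
        else:
            arrs = [g.dropna().to_numpy(dtype=float) for g in by_group]
            normal = all(_shapiro_normal(a, shapiro_alpha) for a in arrs)
            whole = series.dropna().to_numpy(dtype=float)
            if normal:
                row["type"] = "continuous (normal)"
                row["overall"] = f"{whole.mean():.1f} +/- {whole.std(ddof=1):.1f}"
                for g, a in zip(groups, arrs):
                    row[str(g)] = f"{a.mean():.1f} +/- {a.std(ddof=1):.1f}"
                try:
                    _, p = stats.f_oneway(*arrs)
                    test = "anova"
                except ValueError:
                    p, test = np.nan, "degenerate"
            else:
                row["type"] = "continuous (non-normal)"
                q = np.percentile(whole, [50, 25, 75])
                row["overall"] = f"{q[0]:.1f} ({q[1]:.1f}, {q[2]:.1f})"
                for g, a in zip(groups, arrs):
                    qq = np.percentile(a, [50, 25, 75]) if len(a) else [np.nan] * 3
                    row[str(g)] = f"{qq[0]:.1f} ({qq[1]:.1f}, {qq[2]:.1f})"
                try:
                    if len(arrs) >= 2:
                        _, p = stats.kruskal(*arrs)
                        test = "kruskal_wallis"
                    else:
                        p, test = np.nan, "single_group"
                except ValueError:
                    p, test = np.nan, "degenerate"
        row["p"] = p
        row["test"] = test
        rows.append(row)

    cols = ["variable", "type", "overall", *map(str, groups), "p", "test"]
    return pd.DataFrame(rows)[cols]


def _md_table(df: pd.DataFrame, float_fmt: str = "{:.3g}") -> str:
    """Minimal GitHub-style table renderer."""
    def fmt(v):
        if isinstance(v, float):
            return "" if not np.isfinite(v) else float_fmt.format(v)
        return "" if v is None else str(v)

    header = "| " + " | ".join(map(str, df.columns)) + " |"
    sep = "|" + "|".join(["---"] * len(df.columns)) + "|"
    body = ["| " + " | ".join(fmt(v) for v in row) + " |"
            for row in df.itertuples(index=False)]
    return "\n".join([header, sep, *body])


def _fmt_p(p) -> str:
    if p is None or (isinstance(p, float) and not np.isfinite(p)):
        return ""
    return "< 0.001" if p < 0.001 else f"{p:.3f}"


def render_report(
    baseline: pd.DataFrame,
    cox_results: pd.DataFrame,
    rcs_summary: dict,
    km_summary: dict,
    subgroup: pd.DataFrame,
    roc_per_score: pd.DataFrame,
    roc_pairwise: pd.DataFrame,
    meta: dict,
) -> str:
    """Assemble the Markdown run report."""
    lines = ["# FI-Lab cohort analysis report", ""]
    lines += [f"- {k}: {v}" for k, v in meta.items()]
    lines += ["", "## Baseline characteristics by FI-Lab tertile", ""]
    lines.append(_md_table(baseline))
    lines += ["", "## Cox regression of mortality on FI-Lab", ""]
    lines.append(_md_table(cox_results))
    lines += ["", "## Dose-response (restricted cubic spline)", ""]
    lines += [f"- {k}: {v}" for k, v in rcs_summary.items()]
    lines += ["", "## Kaplan-Meier / log-rank", ""]
    lines += [f"- {k}: {v}" for k, v in km_summary.items()]
    lines += ["", "## Subgroup analysis (FI-Lab per 0.1 unit)", ""]
    lines.append(_md_table(subgroup))
    lines += ["", "## Discrimination (28-day mortality)", ""]
    lines.append(_md_table(roc_per_score))
    lines += [""]
    lines.append(_md_table(roc_pairwise))
    lines.append("")
    return "\n".join(lines)
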