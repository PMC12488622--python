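"""ROC discrimination analysis: AUC with DeLong variance, Youden-index
optimal cutoff, and DeLong's paired test for correlated AUCs.

The AUC is the midrank Mann-Whitney statistic; its variance and the
covariance between two scores measured on the same subjects come from
DeLong's structural components (per-observation placement values),
giving the classical nonparametric test for comparing correlated ROC
curves.  These routines are written here because no installed package
exposes the DeLong variance/covariance machinery; tests check them
against brute-force pair enumeration and bootstrap resampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

__all__ = [
    "auc_delong", "youden_cutoff", "delong_paired_test", "roc_table",
    "RocComparison",
]


def _split(scores: np.ndarray, outcome: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome)
    if scores.shape != outcome.shape:
        raise DataError("scores and outcome must have equal length")
    if np.isnan(scores).any():
        raise DataError("scores contain missing values")
    pos = scores[outcome == 1]
    neg = scores[outcome == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise DataError("both outcome classes must be non-empty")
    return pos, neg


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components via midranks.

    V10[i] = P(X_i > Y) + P(X_i = Y)/2 over negatives Y, and dually V01.
    """
    m, n = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    r_all = stats.rankdata(allv)          # midranks in the pooled sample
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    return v10, v01


def auc_delong(
    scores, outcome, alpha: float = 0.05
) -> tuple[float, float, tuple[float, float]]:
    """AUC, DeLong variance, and normal-approximation CI (truncated to
    [0, 1])."""
    pos, neg = _split(np.asarray(scores), np.asarray(outcome))
    v10, v01 = _placements(pos, neg)
    auc = float(v10.mean())
    m, n = len(pos), len(neg)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = float(s10 / m + s01 / n)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    return auc, var, ci


def youden_cutoff(scores, outcome) -> tuple[float, float, float]:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Candidate thresholds are the observed unique score values; the
    classification rule is score >= cutoff => predicted positive, and
    J-ties break toward the lower threshold.
    """
    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome)
    pos, neg = _split(scores, outcome)
    best = None
    for t in np.unique(scores):          # ascending: first max wins => lowest
        sens = float((pos >= t).mean())
        spec = float((neg < t).mean())
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, t, sens, spec)
    _, cutoff, sens, spec = best
    return float(cutoff), sens, spec


def delong_paired_test(score_a, score_b, outcome) -> tuple[float, float]:
    """DeLong's test for two correlated AUCs measured on the same
    subjects: z = (AUC_a - AUC_b) / sqrt(var_a + var_b - 2 cov), with a
    two-sided normal p.  Degenerate variance (e.g. identical scores)
    reports z = 0, p = 1.
    """
    score_a = np.asarray(score_a, dtype=float)
    score_b = np.asarray(score_b, dtype=float)
    outcome = np.asarray(outcome)
    if score_a.shape != score_b.shape:
        raise DataError("paired scores must have equal length")
    pos_a, neg_a = _split(score_a, outcome)
    pos_b, neg_b = _split(score_b, outcome)
    va10, va01 = _placements(pos_a, neg_a)
    vb10, vb01 = _placements(pos_b, neg_b)
    m, n = len(pos_a), len(neg_a)
    auc_a, auc_b = float(va10.mean()), float(vb10.mean())
    if m > 1:
        s10 = np.cov(np.vstack([va10, vb10]), ddof=1)
    else:
        s10 = np.zeros((2, 2))
    if n > 1:
        s01 = np.cov(np.vstack([va01, vb01]), ddof=1)
    else:
        s01 = np.zeros((2, 2))
    s = s10 / m + s01 / n
    var_diff = float(s[0, 0] + s[1, 1] - 2 * s[0, 1])
    if var_diff <= 1e-15:
        return 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = float(2 * stats.norm.sf(abs(z)))
    return float(z), p


@dataclass
class RocComparison:
    """Per-score discrimination summary plus pairwise DeLong tests."""

    per_score: pd.DataFrame    # score, auc, variance, ci_low, ci_high,
                               # cutoff, sensitivity, specificity
    pairwise: pd.DataFrame     # score_a, score_b, auc_diff, z, p


def roc_table(
    df: pd.DataFrame,
    score_cols: list[str],
    outcome_col: str = "death_28d",
) -> RocComparison:
    """Discrimination of several scores for one binary outcome, with
    all pairwise DeLong comparisons."""
    outcome = df[outcome_col].to_numpy()
    rows = []
    for c in score_cols:
        auc, var, ci = auc_delong(df[c], outcome)
        cutoff, sens, spec = youden_cutoff(df[c], outcome)
        rows.append({
            "score": c, "auc": auc, "variance": var,
            "ci_low": ci[0], "ci_high": ci[1],
            "cutoff": cutoff, "sensitivity": sens, "specificity": spec,
        })
    pairs = []
    for i, a in enumerate(score_cols):
        for b in score_cols[i + 1:]:
            auc_a, _, _ = auc_delong(df[a], outcome)
            auc_b, _, _ = auc_delong(df[b], outcome)
            z, p = delong_paired_test(df[a], df[b], outcome)
            pairs.append({
                "score_a": a, "score_b": b,
                "auc_diff": auc_a - auc_b, "z": z, "p": p,
            })
    return RocComparison(
        per_score=pd.DataFrame(rows),
        pairwise=pd.DataFrame(
            pairs, columns=["score_a", "score_b", "auc_diff", "z", "p"]),
    )
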