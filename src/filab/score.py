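"""FI-Lab score computation.

The laboratory frailty index (FI-Lab) treats each out-of-range test
result as one accumulated health deficit.  For every registry item the
earliest in-window value (labs) or the 24-h mean (vitals) is
dichotomized against its reference interval — 0 inside, 1 outside —
and the score is the fraction of deficits among *measured* items:

    score = n_deficits / n_measured,   0 <= score <= 1.

A stay with more than ``max_missing`` (default 12) unmeasured items is
ineligible and receives no score.  Dividing by the measured-item count
rather than the fixed registry length keeps the score on the 0–1 scale
under allowed missingness; ``denominator="fixed_total"`` switches to
dividing by the registry length for sensitivity analyses.

Conventions (documented, configurable where sensible):

* reference intervals are closed: a value equal to a bound is normal;
* window endpoints are inclusive;
* with several values of one lab in window, the chronologically first
  is used, ties broken by input order;
* tertile intervals are half-open: T1 = [0, c1), T2 = [c1, c2),
  T3 = [c2, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, SpecificationError
from .registry import ItemRegistry, ItemSpec

#: required columns of a long measurement table
RECORD_COLUMNS = ["stay_id", "item", "charttime_h", "value"]

#: published ICU-asthma tertile cutpoints of FI-Lab at admission
DEFAULT_TERTILE_CUTPOINTS = (0.43, 0.54)


@dataclass(frozen=True)
class FiLabResult:
    """Per-stay FI-Lab outcome."""

    stay_id: object
    n_items_total: int
    n_measured: int
    n_missing: int
    n_deficits: int
    score: float | None
    eligible: bool
    tertile: str | None = None


def select_item_value(
    records: pd.DataFrame | Sequence[tuple[float, object]],
    spec: ItemSpec,
) -> object | None:
    """Pick the value to score for one stay and one item.

    ``records`` is either a DataFrame with ``charttime_h``/``value``
    columns or a sequence of ``(charttime_h, value)`` pairs, times in
    hours from ICU admission.  Records outside the item's window
    (boundaries inclusive) are discarded; ``first_in_window`` returns
    the earliest remaining value with ties broken by input order,
    ``mean_in_window`` the arithmetic mean of remaining numeric values.
    Returns ``None`` when nothing falls in the window.
    """
    if isinstance(records, pd.DataFrame):
        pairs = list(zip(records["charttime_h"].tolist(), records["value"].tolist()))
    else:
        pairs = list(records)
    in_window = [
        (t, v) for (t, v) in pairs if spec.window_low_h <= t <= spec.window_high_h
    ]
    if not in_window:
        return None
    if spec.aggregation == "first_in_window":
        # stable min: earliest time, first occurrence wins ties
        best_i = min(range(len(in_window)), key=lambda i: (in_window[i][0], i))
        return in_window[best_i][1]
    if not spec.is_numeric:
        raise SpecificationError(
            f"item {spec.name!r}: mean_in_window is undefined for categorical items"
        )
    return float(np.mean([float(v) for _, v in in_window]))


def dichotomize(value: object, spec: ItemSpec) -> int:
    """Score one measured value: 0 = within reference, 1 = deficit."""
    if spec.is_numeric:
        try:
            x = float(value)
        except (TypeError, ValueError):
            raise DataError(
                f"item {spec.name!r}: non-numeric value {value!r} for numeric item"
            ) from None
        if not np.isfinite(x):
            raise DataError(f"item {spec.name!r}: non-finite value {value!r}")
        lo = -np.inf if spec.reference_low is None else spec.reference_low
        hi = np.inf if spec.reference_high is None else spec.reference_high
        return 0 if lo <= x <= hi else 1
    return 1 if str(value) in spec.abnormal_categories else 0


def assign_tertile(
    score: float, cutpoints: tuple[float, float] = DEFAULT_TERTILE_CUTPOINTS
) -> str:
    """Map a score to T1/T2/T3 with half-open intervals [c1, c2)."""
    c1, c2 = cutpoints
    if not c1 < c2:
        raise SpecificationError(f"cutpoints must be strictly increasing, got {cutpoints}")
    if not 0 <= score <= 1:
        raise DataError(f"score {score} outside [0, 1]")
    if score < c1:
        return "T1"
    if score < c2:
        return "T2"
    return "T3"


def compute_filab(
    records: pd.DataFrame,
    registry: ItemRegistry,
    stay_id: object = None,
    max_missing: int = 12,
    denominator: str = "measured",
) -> FiLabResult:
    """Compute the FI-Lab for a single stay from its long record table.

    ``records`` holds columns ``item``, ``charttime_h``, ``value`` (a
    ``stay_id`` column is allowed and, if present with ``stay_id=None``,
    must be constant).  Items absent from the registry are ignored.
    """
    if stay_id is None and "stay_id" in records.columns and len(records):
        ids = records["stay_id"].unique()
        if len(ids) > 1:
            raise DataError("records contain multiple stay ids; pass stay_id explicitly")
        stay_id = ids[0]

    n_deficits = 0
    n_measured = 0
    for spec in registry:
        sub = records[records["item"] == spec.name]
        value = select_item_value(sub, spec) if len(sub) else None
        if value is None:
            continue
        n_measured += 1
        n_deficits += dichotomize(value, spec)

    return _assemble_result(
        stay_id, len(registry), n_measured, n_deficits, max_missing, denominator
    )


def _assemble_result(
    stay_id, n_total: int, n_measured: int, n_deficits: int,
    max_missing: int, denominator: str,
) -> FiLabResult:
    if denominator not in ("measured", "fixed_total"):
        raise SpecificationError(f"unknown denominator policy {denominator!r}")
    n_missing = n_total - n_measured
    eligible = n_missing <= max_missing
    score = None
    if eligible:
        denom = n_measured if denominator == "measured" else n_total
        score = n_deficits / denom if denom else None
        if score is None:
            eligible = False
    return FiLabResult(
        stay_id=stay_id,
        n_items_total=n_total,
        n_measured=n_measured,
        n_missing=n_missing,
        n_deficits=n_deficits,
        score=score,
        eligible=eligible,
    )


def score_stays(
    labevents: pd.DataFrame | None,
    vitals: pd.DataFrame | None,
    registry: ItemRegistry,
    stay_ids: Iterable | None = None,
    max_missing: int = 12,
    denominator: str = "measured",
    tertile_cutpoints: tuple[float, float] | str | None = None,
) -> pd.DataFrame:
    """Vectorized FI-Lab scoring of a whole cohort.

    ``labevents`` and ``vitals`` are long tables with columns
    ``stay_id, item, charttime_h, value`` (either may be ``None``).
    ``stay_ids`` optionally fixes the output universe so that stays with
    no records at all still appear (as fully missing).  With
    ``tertile_cutpoints`` a pair, tertile labels use those cutpoints;
    with ``"empirical"``, cohort 33rd/67th percentiles of the score.

    Returns one row per stay with all :class:`FiLabResult` fields.
    """
    frames = [f for f in (labevents, vitals) if f is not None and len(f)]
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=RECORD_COLUMNS)
    for col in RECORD_COLUMNS:
        if col not in df.columns:
            raise DataError(f"record table lacks column {col!r}")

    reg_frame = registry.to_frame()[
        ["name", "kind", "reference_low", "reference_high", "window_low_h",
         "window_high_h", "aggregation"]
    ].rename(columns={"name": "item"})

    df = df[df["item"].isin(registry.names)].copy()
    df["_order"] = np.arange(len(df))
    df = df.merge(reg_frame, on="item", how="left")
    df["charttime_h"] = df["charttime_h"].astype(float)
    df = df[
        (df["charttime_h"] >= df["window_low_h"])
        & (df["charttime_h"] <= df["window_high_h"])
    ]

    deficits = []
    # first_in_window: stable sort then first record per (stay, item)
    first = df[df["aggregation"] == "first_in_window"]
    if len(first):
        first = first.sort_values(["charttime_h", "_order"], kind="stable")
        first = first.groupby(["stay_id", "item"], sort=False, as_index=False).first()
        numeric = first["kind"].isin(("numeric_lab", "vital_sign"))
        vals = pd.to_numeric(first.loc[numeric, "value"], errors="coerce")
        if vals.isna().any():
            bad = first.loc[numeric].loc[vals.isna()].iloc[0]
            raise DataError(
                f"stay {bad['stay_id']}, item {bad['item']!r}: non-numeric value "
                f"{bad['value']!r} for numeric item"
            )
        lo = first.loc[numeric, "reference_low"].astype(float).fillna(-np.inf)
        hi = first.loc[numeric, "reference_high"].astype(float).fillna(np.inf)
        num_def = (~((vals >= lo) & (vals <= hi))).astype(int)
        cat = first.loc[~numeric]
        cat_def = pd.Series(
            [
                1 if str(v) in registry[i].abnormal_categories else 0
                for i, v in zip(cat["item"], cat["value"])
            ],
            index=cat.index,
            dtype=int,
        )
        out = first[["stay_id", "item"]].copy()
        out["deficit"] = pd.concat([num_def, cat_def]).reindex(first.index)
        deficits.append(out)

    # mean_in_window: arithmetic mean of in-window numeric values
    mean = df[df["aggregation"] == "mean_in_window"]
    if len(mean):
        if (~mean["kind"].isin(("numeric_lab", "vital_sign"))).any():
            raise SpecificationError("mean_in_window on a categorical item")
        vals = pd.to_numeric(mean["value"], errors="coerce")
        if vals.isna().any():
            bad = mean.loc[vals.isna()].iloc[0]
            raise DataError(
                f"stay {bad['stay_id']}, item {bad['item']!r}: non-numeric value "
                f"{bad['value']!r} for numeric item"
            )
        m = mean.assign(_v=vals).groupby(["stay_id", "item"], as_index=False).agg(
            _v=("_v", "mean"),
            reference_low=("reference_low", "first"),
            reference_high=("reference_high", "first"),
        )
        lo = m["reference_low"].astype(float).fillna(-np.inf)
        hi = m["reference_high"].astype(float).fillna(np.inf)
        out = m[["stay_id", "item"]].copy()
        out["deficit"] = (~((m["_v"] >= lo) & (m["_v"] <= hi))).astype(int)
        deficits.append(out)

    if deficits:
        defs = pd.concat(deficits, ignore_index=True)
        per_stay = defs.groupby("stay_id").agg(
            n_measured=("deficit", "size"), n_deficits=("deficit", "sum")
        )
    else:
        per_stay = pd.DataFrame(columns=["n_measured", "n_deficits"])

    if stay_ids is not None:
        universe = pd.Index(list(stay_ids), name="stay_id")
    else:
        universe = per_stay.index
    per_stay = per_stay.reindex(universe).fillna(0).astype(int)

    n_total = len(registry)
    res = per_stay.reset_index()
    res["n_items_total"] = n_total
    res["n_missing"] = n_total - res["n_measured"]
    res["eligible"] = res["n_missing"] <= max_missing
    denom = (
        res["n_measured"] if denominator == "measured" else pd.Series(n_total, index=res.index)
    )
    if denominator not in ("measured", "fixed_total"):
        raise SpecificationError(f"unknown denominator policy {denominator!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        score = res["n_deficits"] / denom
    res["score"] = np.where(res["eligible"] & (denom > 0), score, np.nan)
    res.loc[denom == 0, "eligible"] = False

    if tertile_cutpoints is not None:
        if isinstance(tertile_cutpoints, str):
            if tertile_cutpoints != "empirical":
                raise SpecificationError(
                    f"unknown tertile policy {tertile_cutpoints!r}"
                )
            c1, c2 = np.nanquantile(res["score"], [1 / 3, 2 / 3])
        else:
            c1, c2 = tertile_cutpoints
        res["tertile"] = [
            assign_tertile(s, (c1, c2)) if np.isfinite(s) else None
            for s in res["score"]
        ]
    else:
        res["tertile"] = None

    cols = [
        "stay_id", "n_items_total", "n_measured", "n_missing",
        "n_deficits", "score", "eligible", "tertile",
    ]
    return res[cols]
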