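"""FI-Lab item registry.

An :class:`ItemRegistry` declares which health deficits enter the
laboratory frailty index and how each one is measured: the reference
interval (numeric items), the set of abnormal report categories
(categorical urinalysis items), the time window around ICU admission in
which measurements count, and how multiple in-window measurements are
aggregated.

The shipped default registry has 33 items — 20 blood tests, 4 arterial
blood-gas values, 6 urinalysis dipstick items and 3 vital signs — with
conventional adult clinical reference intervals.  Laboratory items use a
window from 6 h before to 24 h after ICU admission and take the first
in-window value; vital signs are averaged over the first 24 h.  Every
entry is user-overridable: any CSV with the same columns defines a valid
registry of any length.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd

from .errors import RegistryError

NUMERIC_KINDS = frozenset({"numeric_lab", "vital_sign"})
VALID_KINDS = frozenset({"numeric_lab", "categorical_lab", "vital_sign"})
VALID_AGGREGATIONS = frozenset({"first_in_window", "mean_in_window"})

#: columns of a registry CSV, in canonical order
REGISTRY_COLUMNS = [
    "name",
    "kind",
    "reference_low",
    "reference_high",
    "abnormal_categories",
    "window_low_h",
    "window_high_h",
    "aggregation",
]


@dataclass(frozen=True)
class ItemSpec:
    """Definition of a single FI-Lab item."""

    name: str
    kind: str
    reference_low: float | None = None
    reference_high: float | None = None
    abnormal_categories: frozenset[str] = frozenset()
    window_low_h: float = -6.0
    window_high_h: float = 24.0
    aggregation: str = "first_in_window"

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise RegistryError(f"item {self.name!r}: unknown kind {self.kind!r}")
        if self.aggregation not in VALID_AGGREGATIONS:
            raise RegistryError(
                f"item {self.name!r}: unknown aggregation {self.aggregation!r}"
            )
        if self.kind in NUMERIC_KINDS:
            if self.reference_low is None and self.reference_high is None:
                raise RegistryError(
                    f"item {self.name!r}: numeric item needs at least one "
                    "reference bound"
                )
            if (
                self.reference_low is not None
                and self.reference_high is not None
                and not self.reference_low < self.reference_high
            ):
                raise RegistryError(
                    f"item {self.name!r}: reference_low must be strictly below "
                    f"reference_high (got {self.reference_low} / {self.reference_high})"
                )
        else:
            if not self.abnormal_categories:
                raise RegistryError(
                    f"item {self.name!r}: categorical item needs a non-empty "
                    "abnormal_categories set"
                )
        if not self.window_low_h < self.window_high_h:
            raise RegistryError(
                f"item {self.name!r}: window must satisfy low < high "
                f"(got [{self.window_low_h}, {self.window_high_h}])"
            )

    @property
    def is_numeric(self) -> bool:
        return self.kind in NUMERIC_KINDS


@dataclass(frozen=True)
class ItemRegistry:
    """Ordered, name-unique collection of :class:`ItemSpec`."""

    items: tuple[ItemSpec, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [it.name for it in self.items]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise RegistryError(f"duplicate item name(s): {sorted(dupes)}")
        if not self.items:
            raise RegistryError("registry is empty")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[ItemSpec]:
        return iter(self.items)

    def __getitem__(self, name: str) -> ItemSpec:
        for it in self.items:
            if it.name == name:
                return it
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [it.name for it in self.items]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for it in self.items:
            rows.append(
                {
                    "name": it.name,
                    "kind": it.kind,
                    "reference_low": it.reference_low,
                    "reference_high": it.reference_high,
                    "abnormal_categories": ";".join(sorted(it.abnormal_categories)),
                    "window_low_h": it.window_low_h,
                    "window_high_h": it.window_high_h,
                    "aggregation": it.aggregation,
                }
            )
        return pd.DataFrame(rows, columns=REGISTRY_COLUMNS)


def _opt_float(value) -> float | None:
    if value is None:
        return None
    if isinstance(value, str):
        value = value.strip()
        if not value:
            return None
    f = float(value)
    if math.isnan(f):
        return None
    return f


def load_registry(path: str | Path | None = None) -> ItemRegistry:
    """Load an item registry from a CSV file.

    With no argument the shipped 33-item default registry is returned.
    Invariant violations (duplicate names, inverted reference intervals,
    categorical items without abnormal categories, empty files) raise
    :class:`~filab.errors.RegistryError` naming the offending item.
    """
    if path is None:
        ref = importlib.resources.files("filab").joinpath("data/default_registry.csv")
        with importlib.resources.as_file(ref) as p:
            return load_registry(p)

    df = pd.read_csv(path, dtype=str)
    if df.empty:
        raise RegistryError(f"registry file {path} contains no items")
    missing = set(REGISTRY_COLUMNS) - set(df.columns)
    if missing:
        raise RegistryError(f"registry file {path} lacks columns: {sorted(missing)}")

    items = []
    for _, row in df.iterrows():
        cats = row["abnormal_categories"]
        catset: frozenset[str] = frozenset()
        if isinstance(cats, str) and cats.strip():
            catset = frozenset(c.strip() for c in cats.split(";") if c.strip())
        items.append(
            ItemSpec(
                name=str(row["name"]).strip(),
                kind=str(row["kind"]).strip(),
                reference_low=_opt_float(row["reference_low"]),
                reference_high=_opt_float(row["reference_high"]),
                abnormal_categories=catset,
                window_low_h=float(row["window_low_h"]),
                window_high_h=float(row["window_high_h"]),
                aggregation=str(row["aggregation"]).strip(),
            )
        )
    return ItemRegistry(tuple(items))


def default_registry() -> ItemRegistry:
    """The shipped 33-item default registry (cached per call site)."""
    return load_registry(None)
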