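"""Synthetic ICU cohort generator.

Emulates the statistical structure of a critical-care EHR extract
(stays, long-format lab events, long-format vitals) for an asthma-like
ICU cohort, with *known* ground truth at every level so the scoring,
filtering and survival stages are all testable without any external
data:

* per-item deficit indicators are Bernoulli draws (optionally correlated
  through a single latent frailty factor), and numeric measurement
  values are placed inside the reference interval for non-deficits and
  outside it for deficits — so the dichotomized score is known exactly;
* item-level missingness is Bernoulli per item; a missing item simply
  has no record;
* survival times follow an exponential proportional-hazards model whose
  log-hazard is linear in the true FI-Lab (per 0.1 unit) plus centered
  covariate effects, with administrative censoring at 28 and 90 days;
* ICU death competes with an independent exponential discharge clock;
* configured fractions of stays violate each inclusion rule (minors,
  short stays, pregnancy, heavy item missingness, repeat admissions,
  missing required fields) so the filter cascade has work to do.

Covariates are drawn from fixed simple distributions whose location and
prevalence parameters follow published ICU-asthma cohort summaries;
they are generator inputs, not fitted to any real data source.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .registry import ItemRegistry, default_registry

__all__ = ["SimulationConfig", "RawTables", "generate_cohort", "write_tables", "read_tables"]

#: default per-item probability that the item is a deficit (out of range).
#: Chosen to give a mean FI-Lab near 0.48, the center of the score
#: distribution in published ICU asthma cohorts, with plausible
#: item-to-item variation (electrolytes rarely deranged, inflammatory
#: and gas-exchange markers often so).
DEFAULT_ABNORMALITY_PROBS: dict[str, float] = {
    "hemoglobin": 0.60, "wbc": 0.70, "platelets": 0.40, "alt": 0.35,
    "alkaline_phosphatase": 0.30, "total_bilirubin": 0.30, "albumin": 0.65,
    "ldh": 0.55, "creatinine": 0.50, "bun": 0.55, "glucose": 0.70,
    "sodium": 0.40, "potassium": 0.40, "calcium": 0.55, "phosphate": 0.45,
    "fibrinogen": 0.45, "troponin_t": 0.50, "pt": 0.55, "inr": 0.50,
    "aptt": 0.45, "ph_arterial": 0.60, "pao2": 0.65, "paco2": 0.55,
    "lactate": 0.45, "urine_leukocytes": 0.45, "urine_erythrocytes": 0.40,
    "urine_protein": 0.45, "urine_glucose": 0.30, "urine_ketones": 0.25,
    "urine_bilirubin": 0.15, "sbp": 0.60, "dbp": 0.50, "heart_rate": 0.65,
}

#: default per-item probability that the item is never measured in window.
DEFAULT_MISSINGNESS_PROBS: dict[str, float] = {
    **{k: 0.03 for k in DEFAULT_ABNORMALITY_PROBS},
    "fibrinogen": 0.20, "troponin_t": 0.25, "ldh": 0.10,
    "ph_arterial": 0.12, "pao2": 0.12, "paco2": 0.12, "lactate": 0.12,
    "urine_leukocytes": 0.20, "urine_erythrocytes": 0.20, "urine_protein": 0.20,
    "urine_glucose": 0.20, "urine_ketones": 0.20, "urine_bilirubin": 0.20,
    "sbp": 0.0, "dbp": 0.0, "heart_rate": 0.0,
}

#: default covariate log-hazard effects (centered covariates; see
#: _COVARIATE_CENTERS).  Modest, clinically plausible magnitudes.
DEFAULT_COVARIATE_EFFECTS: dict[str, float] = {
    "age": 0.02, "sex_male": -0.10, "sofa": 0.06, "apsiii": 0.008,
    "cci": 0.06, "sepsis": 0.30, "heart_failure": 0.20, "mv": 0.25,
}

#: generating means/prevalences used both to draw covariates and to
#: center them in the linear predictor.
_COVARIATE_CENTERS: dict[str, float] = {
    "age": 61.3, "sex_male": 0.432, "race_white": 0.588, "smoking": 0.084,
    "obesity": 0.222, "respiratory_rate": 29.3, "bicarbonate": 24.1,
    "apsiii": 47.4, "sofa": 5.2, "apache_ii": 18.4, "cci": 5.0,
    "heart_failure": 0.28, "hypertension": 0.629, "diabetes": 0.29,
    "copd": 0.061, "aeba": 0.048, "cardiac_shock": 0.059, "sepsis": 0.60,
    "mv": 0.515, "vasopressors": 0.385, "glucocorticoid": 0.198,
    "montelukast": 0.063,
}

#: FI-Lab value at which the linear predictor is zero (the score scale's
#: central reference); only shifts the baseline hazard.
FILAB_CENTER = 0.48

#: baseline 28-day hazard (per day) calibrated once, numerically, so the
#: marginal 28-day event rate under all defaults is ~13.2%.
DEFAULT_BASELINE_HAZARD = 4.378e-3

#: exponential ICU discharge rate per day; median LOS ln2/rate ~ 2.8 d.
DEFAULT_DISCHARGE_RATE = 0.25

_VIOLATION_RULES = (
    "repeat_stay", "age_under_18", "los_under_24h", "pregnancy",
    "excess_missing_items", "missing_required_field",
)

STAY_COLUMNS = [
    "stay_id", "admission_time", "age", "sex", "race", "smoking", "obesity",
    "heart_failure", "hypertension", "diabetes", "copd", "aeba",
    "cardiac_shock", "sepsis", "apsiii", "sofa", "apache_ii", "cci",
    "respiratory_rate", "bicarbonate", "pao2_fio2", "mv", "vasopressors",
    "glucocorticoid", "montelukast", "icu_los_days", "is_first_icu_stay",
    "pregnant", "time_28d", "death_28d", "time_90d", "death_90d",
    "time_icu", "death_icu",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions."""

    n_patients: int = 2339
    seed: int = 0
    abnormality_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ABNORMALITY_PROBS))
    missingness_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS_PROBS))
    beta_filab_per_0_1: float = math.log(1.32)
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    baseline_hazard_rate: float = DEFAULT_BASELINE_HAZARD
    icu_discharge_rate: float = DEFAULT_DISCHARGE_RATE
    admin_censor_days: tuple[int, int] = (28, 90)
    filter_violation_fractions: dict[str, float] = field(default_factory=dict)
    latent_correlation: float = 0.0
    window_violation_fraction: float = 0.0
    pao2_fio2_missing_fraction: float = 0.15

    def validate(self, registry: ItemRegistry) -> None:
        if not (isinstance(self.n_patients, (int, np.integer)) and self.n_patients >= 0):
            raise ConfigurationError(f"n_patients must be a non-negative integer, got {self.n_patients}")
        for label, mapping in (
            ("abnormality_probs", self.abnormality_probs),
            ("missingness_probs", self.missingness_probs),
        ):
            for k, v in mapping.items():
                if not (np.isfinite(v) and 0.0 <= v <= 1.0):
                    raise ConfigurationError(f"{label}[{k!r}] = {v} outside [0, 1]")
            missing = set(registry.names) - set(mapping)
            if missing:
                raise ConfigurationError(f"{label} lacks items: {sorted(missing)}")
        for label, v in (
            ("baseline_hazard_rate", self.baseline_hazard_rate),
            ("icu_discharge_rate", self.icu_discharge_rate),
        ):
            if not (np.isfinite(v) and v > 0):
                raise ConfigurationError(f"{label} must be a positive finite rate, got {v}")
        if not np.isfinite(self.beta_filab_per_0_1):
            raise ConfigurationError("beta_filab_per_0_1 must be finite")
        for k, v in self.covariate_effects.items():
            if k not in _COVARIATE_CENTERS:
                raise ConfigurationError(f"covariate_effects names unknown covariate {k!r}")
            if not np.isfinite(v):
                raise ConfigurationError(f"covariate_effects[{k!r}] must be finite")
        for k, v in self.filter_violation_fractions.items():
            if k not in _VIOLATION_RULES:
                raise ConfigurationError(f"unknown filter rule {k!r}")
            if not (np.isfinite(v) and 0.0 <= v <= 1.0):
                raise ConfigurationError(f"filter_violation_fractions[{k!r}] = {v} outside [0, 1]")
        if not (np.isfinite(self.latent_correlation) and 0.0 <= self.latent_correlation < 1.0):
            raise ConfigurationError(f"latent_correlation must be in [0, 1), got {self.latent_correlation}")
        for label, v in (
            ("window_violation_fraction", self.window_violation_fraction),
            ("pao2_fio2_missing_fraction", self.pao2_fio2_missing_fraction),
        ):
            if not (np.isfinite(v) and 0.0 <= v <= 1.0):
                raise ConfigurationError(f"{label} = {v} outside [0, 1]")

    def with_updates(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class RawTables:
    """The generator's output: raw tables plus per-stay ground truth."""

    stays: pd.DataFrame
    lab_events: pd.DataFrame
    vitals: pd.DataFrame
    truth: pd.DataFrame


def _draw_deficits(rng, n, probs, rho):
    """n x k deficit matrix; optional one-factor Gaussian copula."""
    k = len(probs)
    if rho <= 0:
        return (rng.random((n, k)) < probs).astype(np.int8)
    from scipy.stats import norm
    u = rng.standard_normal((n, 1))
    z = math.sqrt(rho) * u + math.sqrt(1 - rho) * rng.standard_normal((n, k))
    return (z < norm.ppf(probs)).astype(np.int8)


def _draw_covariates(rng, n: int) -> pd.DataFrame:
    c = _COVARIATE_CENTERS
    df = pd.DataFrame(index=np.arange(n))
    df["age"] = np.clip(rng.normal(c["age"], 17.1, n), 18.0, 100.0).round(1)
    df["sex"] = np.where(rng.random(n) < c["sex_male"], "male", "female")
    df["race"] = np.where(rng.random(n) < c["race_white"], "white", "nonwhite")
    for flag in ("smoking", "obesity", "heart_failure", "hypertension",
                 "diabetes", "copd", "aeba", "cardiac_shock", "sepsis",
                 "mv", "vasopressors", "glucocorticoid", "montelukast"):
        df[flag] = (rng.random(n) < c[flag]).astype(int)
    df["respiratory_rate"] = np.clip(rng.normal(c["respiratory_rate"], 6.9, n), 8, 60).round(1)
    df["bicarbonate"] = np.clip(rng.normal(c["bicarbonate"], 4.6, n), 5, 50).round(1)
    df["pao2_fio2"] = np.clip(rng.lognormal(math.log(175.0), 0.5, n), 30, 600).round(1)
    df["apsiii"] = np.clip(rng.normal(c["apsiii"], 21.9, n), 0, 200).round(0)
    df["sofa"] = np.clip(rng.normal(c["sofa"], 3.2, n), 0, 24).round(0)
    df["apache_ii"] = np.clip(rng.normal(c["apache_ii"], 7.7, n), 0, 70).round(0)
    df["cci"] = rng.poisson(c["cci"], n).astype(float)
    return df


def _linear_predictor(cfg: SimulationConfig, score: np.ndarray, cov: pd.DataFrame) -> np.ndarray:
    lp = cfg.beta_filab_per_0_1 * (score - FILAB_CENTER) / 0.1
    for name, beta in cfg.covariate_effects.items():
        if beta == 0.0:
            continue
        if name == "sex_male":
            x = (cov["sex"] == "male").astype(float).to_numpy()
        elif name == "race_white":
            x = (cov["race"] == "white").astype(float).to_numpy()
        else:
            x = cov[name].astype(float).to_numpy()
        lp = lp + beta * (x - _COVARIATE_CENTERS[name])
    return lp


def generate_cohort(
    config: SimulationConfig, registry: ItemRegistry | None = None
) -> RawTables:
    """Generate a full synthetic cohort under ``config``.

    Deterministic: the same config (including seed) yields bit-identical
    tables.  See the module docstring for the generating model.
    """
    registry = registry or default_registry()
    config.validate(registry)
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    names = registry.names
    k = len(names)

    p_abn = np.array([config.abnormality_probs[m] for m in names])
    p_mis = np.array([config.missingness_probs[m] for m in names])

    deficits = _draw_deficits(rng, n, p_abn, config.latent_correlation)
    missing = (rng.random((n, k)) < p_mis).astype(np.int8)

    cov = _draw_covariates(rng, n)

    # inclusion-rule violators (independent subsets; may overlap)
    viol = {}
    for rule in _VIOLATION_RULES:
        frac = config.filter_violation_fractions.get(rule, 0.0)
        viol[rule] = rng.random(n) < frac

    if viol["excess_missing_items"].any():
        idx = np.flatnonzero(viol["excess_missing_items"])
        for i in idx:
            n_miss = rng.integers(13, k + 1)
            cols = rng.choice(k, size=n_miss, replace=False)
            missing[i, :] = 0
            missing[i, cols] = 1

    measured = 1 - missing
    n_measured = measured.sum(axis=1)
    n_deficits = (deficits * measured).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(n_measured > 0, n_deficits / np.maximum(n_measured, 1), np.nan)

    # demographic overrides for rule violators
    cov.loc[viol["age_under_18"], "age"] = rng.uniform(
        14, 17.9, int(viol["age_under_18"].sum())).round(1)
    preg = viol["pregnancy"]
    cov.loc[preg, "sex"] = "female"
    cov.loc[preg, "age"] = np.minimum(cov.loc[preg, "age"], 45.0)
    pregnant = preg.astype(int)

    # survival under exponential proportional hazards
    lp = _linear_predictor(config, np.nan_to_num(score, nan=FILAB_CENTER), cov)
    rate = config.baseline_hazard_rate * np.exp(lp)
    t_death = rng.exponential(1.0 / rate) if n else np.array([])
    t_discharge = rng.exponential(1.0 / config.icu_discharge_rate, n)

    h28, h90 = sorted(config.admin_censor_days)
    stays = pd.DataFrame({"stay_id": np.arange(1, n + 1)})
    base = pd.Timestamp("2024-01-01")
    offsets = rng.uniform(0, 365, n)
    stays["admission_time"] = [
        (base + pd.Timedelta(hours=float(o) * 24)).isoformat() for o in offsets
    ]
    for col in cov.columns:
        stays[col] = cov[col].to_numpy()
    stays["pao2_fio2"] = stays["pao2_fio2"].where(
        rng.random(n) >= config.pao2_fio2_missing_fraction, np.nan)

    # ICU stay ends at death or discharge; the cohort emulates admission
    # cohorts conditioned on a >=24 h stay, so non-violators are floored
    los = np.minimum(t_death, t_discharge) if n else np.array([])
    los = np.maximum(los, 1.02)
    los_viol = viol["los_under_24h"]
    los[los_viol] = rng.uniform(0.1, 0.99, int(los_viol.sum()))
    stays["icu_los_days"] = np.round(los, 3)
    stays["is_first_icu_stay"] = (~viol["repeat_stay"]).astype(int)
    stays["pregnant"] = pregnant

    stays["time_28d"] = np.round(np.minimum(t_death, h28), 4)
    stays["death_28d"] = (t_death <= h28).astype(int)
    stays["time_90d"] = np.round(np.minimum(t_death, h90), 4)
    stays["death_90d"] = (t_death <= h90).astype(int)
    stays["time_icu"] = np.round(np.minimum(t_death, t_discharge), 4)
    stays["death_icu"] = (t_death <= t_discharge).astype(int)

    # required-field dropouts
    mrf = viol["missing_required_field"]
    if mrf.any():
        req = ["respiratory_rate", "bicarbonate", "glucocorticoid", "montelukast"]
        stays["glucocorticoid"] = stays["glucocorticoid"].astype(float)
        stays["montelukast"] = stays["montelukast"].astype(float)
        which = rng.integers(0, len(req), n)
        for j, colname in enumerate(req):
            stays.loc[mrf & (which == j), colname] = np.nan

    stays = stays[STAY_COLUMNS]

    lab_events, vital_events = _emit_records(
        rng, registry, deficits, missing, config.window_violation_fraction)

    truth = pd.DataFrame({
        "stay_id": stays["stay_id"],
        "n_measured_true": n_measured,
        "n_deficits_true": n_deficits,
        "score_true": score,
    })
    for j, m in enumerate(names):
        col = deficits[:, j].astype(float)
        col[missing[:, j] == 1] = np.nan
        truth[f"deficit_{m}"] = col

    return RawTables(stays=stays, lab_events=lab_events, vitals=vital_events, truth=truth)


def _emit_records(rng, registry, deficits, missing, window_violation_fraction):
    """Long lab/vital record tables consistent with the deficit matrix."""
    n, _ = deficits.shape
    lab_rows, vital_rows = [], []
    stay_ids = np.arange(1, n + 1)

    for j, spec in enumerate(registry):
        meas = np.flatnonzero(missing[:, j] == 0)
        if meas.size == 0:
            continue
        d = deficits[meas, j].astype(bool)
        if spec.is_numeric:
            lo = spec.reference_low if spec.reference_low is not None else -np.inf
            hi = spec.reference_high if spec.reference_high is not None else np.inf
            width = (hi - lo) if np.isfinite(lo) and np.isfinite(hi) else max(
                abs(lo if np.isfinite(lo) else hi), 1.0)
            vals = np.empty(meas.size)
            inside = ~d
            if np.isfinite(lo) and np.isfinite(hi):
                vals[inside] = rng.uniform(lo, hi, inside.sum())
            elif np.isfinite(hi):
                vals[inside] = rng.uniform(hi - width, hi, inside.sum())
            else:
                vals[inside] = rng.uniform(lo, lo + width, inside.sum())
            # deficit values: 10-50% of the reference width beyond a bound
            delta = rng.uniform(0.1, 0.5, int(d.sum())) * width
            if np.isfinite(lo) and np.isfinite(hi):
                upper = rng.random(int(d.sum())) < 0.5
            elif np.isfinite(hi):
                upper = np.ones(int(d.sum()), bool)
            else:
                upper = np.zeros(int(d.sum()), bool)
            out = np.where(upper, hi + delta, lo - delta)
            # keep non-negative analytes physical where the low bound is >= 0
            if np.isfinite(lo) and lo >= 0:
                neg = out < 0
                out[neg] = hi + delta[neg]
            vals[d] = out
            value_strs = np.char.mod("%.6g", vals)
        else:
            cats = sorted(spec.abnormal_categories)
            picks = rng.integers(0, len(cats), int(d.sum()))
            value_strs = np.where(d, "", "negative").astype(object)
            value_strs[d] = [cats[p] for p in picks]

        if spec.aggregation == "mean_in_window":
            # three repeats of the same value: the 24-h mean equals it
            for rep in range(3):
                t = rng.uniform(spec.window_low_h, spec.window_high_h, meas.size)
                vital_rows.append(pd.DataFrame({
                    "stay_id": stay_ids[meas], "item": spec.name,
                    "charttime_h": np.round(t, 3), "value": value_strs,
                }))
        else:
            t = rng.uniform(spec.window_low_h, spec.window_high_h, meas.size)
            if window_violation_fraction > 0:
                off = rng.random(meas.size) < window_violation_fraction
                t[off] = rng.uniform(
                    spec.window_low_h - 12.0, spec.window_low_h - 0.5, int(off.sum()))
            lab_rows.append(pd.DataFrame({
                "stay_id": stay_ids[meas], "item": spec.name,
                "charttime_h": np.round(t, 3), "value": value_strs,
            }))

    cols = ["stay_id", "item", "charttime_h", "value"]
    labs = (pd.concat(lab_rows, ignore_index=True) if lab_rows
            else pd.DataFrame(columns=cols))
    vits = (pd.concat(vital_rows, ignore_index=True) if vital_rows
            else pd.DataFrame(columns=cols))
    labs = labs.sort_values(["stay_id", "item", "charttime_h"],
                            kind="stable").reset_index(drop=True)
    vits = vits.sort_values(["stay_id", "item", "charttime_h"],
                            kind="stable").reset_index(drop=True)
    return labs[cols], vits[cols]


def write_tables(tables: RawTables, directory: str | Path) -> dict[str, Path]:
    """Write stays/labevents/vitals/truth CSVs; lossless round-trip."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "stays": directory / "stays.csv",
        "labevents": directory / "labevents.csv",
        "vitals": directory / "vitals.csv",
        "truth": directory / "truth.csv",
    }
    tables.stays.to_csv(paths["stays"], index=False)
    tables.lab_events.to_csv(paths["labevents"], index=False)
    tables.vitals.to_csv(paths["vitals"], index=False)
    tables.truth.to_csv(paths["truth"], index=False)
    return paths


def read_tables(directory: str | Path) -> RawTables:
    """Read back a table set written by :func:`write_tables`."""
    directory = Path(directory)
    stays = pd.read_csv(directory / "stays.csv")
    labs = pd.read_csv(directory / "labevents.csv", dtype={"value": str})
    vits = pd.read_csv(directory / "vitals.csv", dtype={"value": str})
    truth_path = directory / "truth.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else pd.DataFrame()
    return RawTables(stays=stays, lab_events=labs, vitals=vits, truth=truth)
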