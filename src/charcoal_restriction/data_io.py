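"""Observation schema, ICD-10 method classification, and descriptive rate tables.

The analysis operates on an *observation table*: one row per site x method x
time interval, holding the event count, the population at risk, the interval
length in days, and calendar covariate weights.  Daily rows carry one-hot
weekday/month weights; weekly rows (used where only weekly aggregates are
released) carry the average of the daily dummies over the days covered, e.g.
1/7 for every weekday of a full week.

All rates are annualized per 100,000 person-years with a 365.25-day year.
"""

from __future__ import annotations

import datetime as dt
import re
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25
RATE_DENOMINATOR = 100_000.0

WEEKDAYS = ["mon", "tue", "wed", "thu", "fri", "sat", "sun"]
MONTHS = ["jan", "feb", "mar", "apr", "may", "jun", "jul", "aug", "sep", "oct", "nov", "dec"]
WEEKDAY_COLS = [f"wd_{d}" for d in WEEKDAYS]
MONTH_COLS = [f"m_{m}" for m in MONTHS]

#: Columns every observation table must carry (weight columns follow).
CORE_COLUMNS = [
    "site",
    "method",
    "period_start",
    "period_length_days",
    "count",
    "population",
    "post_intervention",
    "midpoint_time",
]

CHARCOAL = "charcoal"
OTHER = "other"

#: ICD-10 codes counted as charcoal-burning deaths: intentional self-poisoning
#: by other gases and vapours, plus the undetermined-intent counterpart.
CHARCOAL_CODES = frozenset({"X67", "Y17"})
#: Intentional self-harm and undetermined-intent ranges scanned for suicide deaths.
SUICIDE_RANGES = (("X", 60, 84), ("Y", 10, 34))

_ICD_RE = re.compile(r"^([A-Z])(\d{2})(?:\.\d+)?$")


class ValidationError(ValueError):
    """Raised when an observation table violates the schema invariants."""


def classify_method(code: str) -> str | None:
    """Classify an ICD-10 cause-of-death code into a suicide method category.

    Returns ``"charcoal"`` for X67/Y17, ``"other"`` for any other code in
    X60-X84 or Y10-Y34, and ``None`` for codes outside the suicide ranges.
    A trailing decimal subcode (e.g. ``X67.0``) is accepted and ignored.
    """
    if not isinstance(code, str):
        raise ValueError(f"ICD-10 code must be a string, got {code!r}")
    m = _ICD_RE.match(code.strip().upper())
    if m is None:
        raise ValueError(f"malformed ICD-10 code: {code!r}")
    letter, num = m.group(1), int(m.group(2))
    if f"{letter}{num:02d}" in CHARCOAL_CODES:
        return CHARCOAL
    for rng_letter, lo, hi in SUICIDE_RANGES:
        if letter == rng_letter and lo <= num <= hi:
            return OTHER
    return None


def interval_weights(period_start: dt.date, period_length_days: int) -> tuple[np.ndarray, np.ndarray]:
    """Weekday and month weight vectors for an interval.

    Each weight is the fraction of the interval's days falling on that weekday
    (resp. in that calendar month); a one-day interval yields one-hot vectors,
    a full week yields 1/7 in every weekday slot.
    """
    n = int(period_length_days)
    if n <= 0:
        raise ValueError("period_length_days must be positive")
    days = pd.date_range(period_start, periods=n, freq="D")
    wd = np.bincount(days.dayofweek, minlength=7) / n
    mo = np.bincount(days.month - 1, minlength=12) / n
    return wd, mo


def attach_weights(obs: pd.DataFrame) -> pd.DataFrame:
    """Fill weekday/month weight columns computed from each row's calendar span."""
    obs = obs.copy()
    wd = np.empty((len(obs), 7))
    mo = np.empty((len(obs), 12))
    for i, (start, length) in enumerate(zip(obs["period_start"], obs["period_length_days"])):
        wd[i], mo[i] = interval_weights(pd.Timestamp(start).date(), length)
    obs[WEEKDAY_COLS] = wd
    obs[MONTH_COLS] = mo
    return obs


def finalize_observations(
    obs: pd.DataFrame,
    intervention_date: dt.date,
    study_start: dt.date | None = None,
) -> pd.DataFrame:
    """Derive ``midpoint_time`` / ``post_intervention`` and validate the table.

    ``midpoint_time`` is days since the study start (default: earliest
    ``period_start``) at the interval center.  Rows straddling the
    intervention date raise :class:`ValidationError`.
    """
    obs = obs.copy()
    obs["period_start"] = pd.to_datetime(obs["period_start"])
    if study_start is None:
        study_start = obs["period_start"].min().date()
    t0 = pd.Timestamp(study_start)
    obs["midpoint_time"] = (
        (obs["period_start"] - t0).dt.days + obs["period_length_days"] / 2.0
    )
    iv = pd.Timestamp(intervention_date)
    starts_post = obs["period_start"] >= iv
    ends_pre = obs["period_start"] + pd.to_timedelta(obs["period_length_days"], unit="D") <= iv
    straddle = ~starts_post & ~ends_pre
    if straddle.any():
        bad = obs.index[straddle].tolist()
        raise ValidationError(f"rows straddle the intervention date {intervention_date}: {bad}")
    obs["post_intervention"] = starts_post.astype(int)
    if not set(WEEKDAY_COLS).issubset(obs.columns):
        obs = attach_weights(obs)
    validate_observations(obs)
    return obs


def validate_observations(obs: pd.DataFrame) -> None:
    """Check schema invariants, raising :class:`ValidationError` listing offenders."""
    missing = [c for c in CORE_COLUMNS + WEEKDAY_COLS + MONTH_COLS if c not in obs.columns]
    if missing:
        raise ValidationError(f"missing columns: {missing}")
    problems = []
    if (obs["count"] < 0).any():
        problems.append(f"negative counts at rows {obs.index[obs['count'] < 0].tolist()}")
    if (obs["period_length_days"] <= 0).any():
        problems.append("non-positive period_length_days")
    if (obs["population"] <= 0).any():
        problems.append("non-positive population")
    for cols, label in ((WEEKDAY_COLS, "weekday"), (MONTH_COLS, "month")):
        s = obs[cols].to_numpy().sum(axis=1)
        bad = np.abs(s - 1.0) > 1e-9
        if bad.any():
            problems.append(f"{label} weights do not sum to 1 at rows {obs.index[bad].tolist()}")
    if problems:
        raise ValidationError("; ".join(problems))


def load_observations(
    path,
    intervention_date: dt.date,
    schema_map: Mapping[str, str] | None = None,
    study_start: dt.date | None = None,
) -> pd.DataFrame:
    """Read an observation table from CSV (or XLSX) and validate it.

    ``schema_map`` maps file column names onto the canonical schema
    (``site, method, period_start, period_length_days, count, population``).
    Weight columns are taken from the file when present, otherwise computed
    from each row's calendar span.
    """
    path = str(path)
    if path.endswith((".xlsx", ".xls")):
        raw = pd.read_excel(path)
    else:
        raw = pd.read_csv(path)
    if schema_map:
        raw = raw.rename(columns=dict(schema_map))
    required = ["site", "method", "period_start", "period_length_days", "count", "population"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValidationError(f"input file lacks columns {missing}")
    return finalize_observations(raw, intervention_date, study_start=study_start)


def write_observations(obs: pd.DataFrame, path) -> None:
    """Write the canonical CSV schema (ISO-8601 dates, weights included)."""
    out = obs.copy()
    out["period_start"] = pd.to_datetime(out["period_start"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def annualized_rate(count: float, population: float, period_length_days: float) -> float:
    """Events per 100,000 person-years: ``count * 365.25 / (days * pop / 1e5)``."""
    if population <= 0 or period_length_days <= 0:
        raise ValueError("population and period_length_days must be positive")
    person_years = period_length_days * population / DAYS_PER_YEAR
    return count / person_years * RATE_DENOMINATOR


def percent_change(rate_pre: float, rate_post: float) -> float:
    """Percent reduction from pre to post: ``100 * (1 - post/pre)``."""
    if rate_pre <= 0:
        raise ValueError("rate_pre must be positive")
    return 100.0 * (1.0 - rate_post / rate_pre)


ALL_METHODS = "all"


def combine_methods(obs: pd.DataFrame, label: str = ALL_METHODS) -> pd.DataFrame:
    """Sum counts over method categories within each site x interval.

    Weights, population and exposure are interval properties and are carried
    through unchanged; only ``count`` is aggregated.
    """
    keys = ["site", "period_start"]
    first_cols = [c for c in obs.columns if c not in keys + ["count", "method"]]
    agg = {c: "first" for c in first_cols}
    agg["count"] = "sum"
    out = obs.groupby(keys, as_index=False, sort=True).agg(agg)
    out["method"] = label
    return out[obs.columns.tolist()]


def rate_table(obs: pd.DataFrame, intervention_date: dt.date | None = None) -> pd.DataFrame:
    """Descriptive counts and annualized rates per site x method x period.

    Person-time sums each record's ``population * period_length_days``, so
    per-calendar-year populations are handled exactly.  Includes an
    ``"all"``-methods block equal to the sum over method categories.
    Rates are additionally rounded to one decimal in ``rate_display``.
    """
    if "post_intervention" not in obs.columns:
        if intervention_date is None:
            raise ValueError("intervention_date required when post flags are absent")
        obs = finalize_observations(obs, intervention_date)
    full = pd.concat([obs, combine_methods(obs)], ignore_index=True)
    full["period"] = np.where(full["post_intervention"] == 1, "post", "pre")
    rows = []
    for (site, method, period), grp in full.groupby(["site", "method", "period"], sort=True):
        person_days = float((grp["population"] * grp["period_length_days"]).sum())
        count = int(grp["count"].sum())
        rate = count / (person_days / DAYS_PER_YEAR) * RATE_DENOMINATOR
        rows.append(
            {
                "site": site,
                "method": method,
                "period": period,
                "count": count,
                "person_days": person_days,
                "rate": rate,
                "rate_display": round(rate, 1),
            }
        )
    table = pd.DataFrame(rows)
    periods = set(table["period"])
    if periods != {"pre", "post"}:
        raise ValueError(f"observations must cover both periods, found {sorted(periods)}")
    order = pd.CategoricalDtype(["pre", "post"], ordered=True)
    table["period"] = table["period"].astype(order)
    return table.sort_values(["site", "method", "period"]).reset_index(drop=True)
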