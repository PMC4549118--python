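"""Synthetic multi-site suicide-count series with known ground truth.

The generator draws daily Poisson counts per site x method whose log-mean has
exactly the structure the regression model assumes: a baseline annual rate,
weekday and month seasonality, a smooth secular log-trend (a cubic B-spline),
and a step intervention effect from a fixed calendar date.  Days from an
optional cutover date on are aggregated into weekly records, mirroring
registries that release only weekly aggregates in later years.

Ground-truth regression coefficients implied by a scenario are available via
:func:`truth` for parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from charcoal_restriction import data_io
from charcoal_restriction.data_io import (
    DAYS_PER_YEAR,
    MONTH_COLS,
    RATE_DENOMINATOR,
    WEEKDAY_COLS,
)


@dataclasses.dataclass(frozen=True)
class LogTrend:
    """A cubic B-spline secular trend on the log-rate scale.

    ``knots`` is the full (clamped) knot vector in days since study start and
    ``coefficients`` the spline coefficients; the default is the flat trend.
    """

    knots: tuple[float, ...]
    coefficients: tuple[float, ...]
    degree: int = 3

    def __call__(self, t) -> np.ndarray:
        spl = BSpline(np.asarray(self.knots), np.asarray(self.coefficients), self.degree,
                      extrapolate=False)
        t = np.asarray(t, dtype=float)
        lo, hi = self.knots[self.degree], self.knots[-self.degree - 1]
        return np.asarray(spl(np.clip(t, lo, hi)))

    @classmethod
    def flat(cls, t_max: float = 1.0) -> "LogTrend":
        return cls(knots=(0.0,) * 4 + (float(t_max),) * 4, coefficients=(0.0,) * 4)

    @classmethod
    def linear(cls, slope_per_day: float, t_max: float, t_ref: float = 0.0) -> "LogTrend":
        """Exact linear trend ``slope * (t - t_ref)`` as a clamped cubic spline.

        Coefficients are set at the Greville abscissae, which reproduces any
        affine function exactly.
        """
        knots = np.array((0.0,) * 4 + (float(t_max),) * 4)
        greville = np.array([knots[j + 1 : j + 4].mean() for j in range(4)])
        return cls(knots=tuple(knots), coefficients=tuple(slope_per_day * (greville - t_ref)))


def _per_site_method(value, sites: Sequence[str], methods: Sequence[str], default=1.0):
    """Canonicalize scalar / per-site / per-site-per-method settings."""
    out = {}
    for s in sites:
        for m in methods:
            v = value
            if isinstance(v, Mapping):
                v = v.get(s, default)
            if isinstance(v, Mapping):
                v = v.get(m, default)
            out[(s, m)] = float(v)
    return out


@dataclasses.dataclass
class ScenarioConfig:
    """Ground-truth description of a multi-site count-generating process.

    Parameters
    ----------
    sites
        Mapping site label -> population (persons), either a constant or a
        per-calendar-year mapping ``{year: population}``.
    methods
        Method category labels (e.g. ``["charcoal", "other"]``).
    base_annual_rate
        ``{site: {method: rate}}``, events per 100,000 person-years at average
        seasonality, before trend and intervention.
    weekday_multipliers, month_multipliers
        Positive seasonal multipliers (length 7 / 12).  They are normalized to
        geometric mean one so the base rate stays interpretable and the
        implied regression coefficients are well defined.
    trend
        :class:`LogTrend` (or ``{method: LogTrend}``) added on the log scale;
        ``None`` means flat.
    intervention_date
        First day of the intervention period.
    intervention_multiplier
        Rate multiplier on/after the intervention date; scalar, per site, or
        per site per method.  All ones is the null scenario.
    date_range
        Inclusive ``(start, end)`` study dates.
    weekly_aggregation_from
        Date from which daily records are aggregated into weekly ones
        (``None`` keeps daily granularity throughout).
    seed
        Default RNG seed used by :func:`generate`.
    """

    sites: Mapping[str, float | Mapping[int, float]]
    methods: Sequence[str]
    base_annual_rate: Mapping[str, Mapping[str, float]]
    intervention_date: dt.date
    date_range: tuple[dt.date, dt.date]
    weekday_multipliers: Sequence[float] = (1.0,) * 7
    month_multipliers: Sequence[float] = (1.0,) * 12
    trend: LogTrend | Mapping[str, LogTrend] | None = None
    intervention_multiplier: float | Mapping = 1.0
    weekly_aggregation_from: dt.date | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("at least one site required")
        if self.date_range[1] < self.date_range[0]:
            raise ValueError("empty date_range")
        wd = np.asarray(self.weekday_multipliers, dtype=float)
        mo = np.asarray(self.month_multipliers, dtype=float)
        if wd.shape != (7,) or mo.shape != (12,):
            raise ValueError("need 7 weekday and 12 month multipliers")
        if (wd <= 0).any() or (mo <= 0).any():
            raise ValueError("seasonal multipliers must be positive")
        # normalize to geometric mean 1 (log-mean zero)
        object.__setattr__(self, "weekday_multipliers", tuple(wd / np.exp(np.log(wd).mean())))
        object.__setattr__(self, "month_multipliers", tuple(mo / np.exp(np.log(mo).mean())))
        for site, pops in self.sites.items():
            vals = pops.values() if isinstance(pops, Mapping) else [pops]
            if any(p <= 0 for p in vals):
                raise ValueError(f"non-positive population for {site}")
        im = _per_site_method(self.intervention_multiplier, list(self.sites), list(self.methods))
        if any(v <= 0 for v in im.values()):
            raise ValueError("intervention multipliers must be positive")
        self._intervention = im

    # -- derived helpers -------------------------------------------------
    def population(self, site: str, year: int) -> float:
        pops = self.sites[site]
        if isinstance(pops, Mapping):
            return float(pops[year])
        return float(pops)

    def trend_for(self, method: str) -> LogTrend:
        if self.trend is None:
            return LogTrend.flat(self.n_days)
        if isinstance(self.trend, Mapping):
            return self.trend.get(method) or LogTrend.flat(self.n_days)
        return self.trend

    def intervention_multiplier_for(self, site: str, method: str) -> float:
        return self._intervention[(site, method)]

    @property
    def n_days(self) -> int:
        return (self.date_range[1] - self.date_range[0]).days + 1


def daily_means(config: ScenarioConfig) -> pd.DataFrame:
    """Per-day expected counts for every site x method (the generator's truth).

    Columns: site, method, date, t (midpoint days since start), population,
    mean.  The mean of day *d* is
    ``pop/1e5 * (1/365.25) * base_rate * wd * month * exp(trend(t)) * step``.
    """
    start, end = config.date_range
    dates = pd.date_range(start, end, freq="D")
    t_mid = np.arange(len(dates)) + 0.5
    wd_mult = np.asarray(config.weekday_multipliers)[dates.dayofweek]
    mo_mult = np.asarray(config.month_multipliers)[dates.month - 1]
    post = np.asarray(dates >= pd.Timestamp(config.intervention_date))
    frames = []
    for site in config.sites:
        pop = np.array([config.population(site, y) for y in dates.year])
        for method in config.methods:
            rate = float(config.base_annual_rate[site][method])
            if rate < 0:
                raise ValueError(f"negative base rate for {site}/{method}")
            trend = config.trend_for(method)(t_mid)
            step = np.where(post, config.intervention_multiplier_for(site, method), 1.0)
            mean = (
                pop / RATE_DENOMINATOR / DAYS_PER_YEAR
                * rate * wd_mult * mo_mult * np.exp(trend) * step
            )
            frames.append(
                pd.DataFrame(
                    {
                        "site": site,
                        "method": method,
                        "date": dates,
                        "t": t_mid,
                        "population": pop,
                        "mean": mean,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def _daily_table(config: ScenarioConfig, counts: np.ndarray, means: pd.DataFrame) -> pd.DataFrame:
    obs = pd.DataFrame(
        {
            "site": means["site"],
            "method": means["method"],
            "period_start": means["date"],
            "period_length_days": 1.0,
            "count": counts,
            "population": means["population"],
        }
    )
    dates = pd.DatetimeIndex(means["date"])
    obs[WEEKDAY_COLS] = np.eye(7)[dates.dayofweek]
    obs[MONTH_COLS] = np.eye(12)[dates.month - 1]
    return obs


def aggregate_weekly(
    daily: pd.DataFrame,
    from_date: dt.date,
    intervention_date: dt.date | None = None,
) -> pd.DataFrame:
    """Aggregate daily records into consecutive 7-day blocks from ``from_date``.

    Counts are summed (conserving totals exactly), weight columns averaged,
    population day-weighted; blocks are split at the intervention date so no
    record straddles it.  A short remainder block at the end is kept.
    """
    daily = daily.copy()
    dates = pd.to_datetime(daily["period_start"])
    keep = daily[dates < pd.Timestamp(from_date)]
    agg_part = daily[dates >= pd.Timestamp(from_date)].copy()
    if agg_part.empty:
        return daily.reset_index(drop=True)
    d = pd.to_datetime(agg_part["period_start"])
    block = ((d - pd.Timestamp(from_date)).dt.days // 7).astype(int).to_numpy()
    if intervention_date is not None:
        # separate sub-blocks on either side of the intervention date
        block = block * 2 + (d >= pd.Timestamp(intervention_date)).to_numpy().astype(int)
    agg_part["_block"] = block
    weight_cols = WEEKDAY_COLS + MONTH_COLS
    rows = []
    for (site, method, _b), grp in agg_part.groupby(["site", "method", "_block"], sort=True):
        row = {
            "site": site,
            "method": method,
            "period_start": grp["period_start"].min(),
            "period_length_days": float(grp["period_length_days"].sum()),
            "count": int(grp["count"].sum()),
            "population": float(
                (grp["population"] * grp["period_length_days"]).sum()
                / grp["period_length_days"].sum()
            ),
        }
        w = grp["period_length_days"].to_numpy()[:, None]
        row.update(
            dict(zip(weight_cols, (grp[weight_cols].to_numpy() * w).sum(0) / w.sum()))
        )
        rows.append(row)
    weekly = pd.DataFrame(rows)
    out = pd.concat([keep, weekly], ignore_index=True)
    return out.sort_values(["site", "method", "period_start"]).reset_index(drop=True)


def generate(config: ScenarioConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw one observation table from the scenario (reproducible under seed)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    means = daily_means(config)
    if (means["mean"] < 0).any():
        raise ValueError("negative mean encountered")
    counts = rng.poisson(means["mean"].to_numpy())
    obs = _daily_table(config, counts, means)
    if config.weekly_aggregation_from is not None:
        obs = aggregate_weekly(obs, config.weekly_aggregation_from, config.intervention_date)
    return data_io.finalize_observations(
        obs, config.intervention_date, study_start=config.date_range[0]
    )


def truth(config: ScenarioConfig, method: str, reference_site: str) -> dict[str, float]:
    """Ground-truth regression coefficients implied by the scenario.

    Returns the coefficients of the seasonal count model on its reference-cell
    parameterization (reference site, Monday, January): site and seasonal
    log-multiplier contrasts, the common post-intervention effect (the
    reference site's log multiplier), and per-site extra effects.  The
    intercept is the log daily rate per person at the reference levels,
    excluding the secular trend, which lives in the spline coefficients.
    """
    sites = list(config.sites)
    if reference_site not in sites:
        raise ValueError(f"unknown reference site {reference_site!r}")
    wd = np.log(np.asarray(config.weekday_multipliers))
    mo = np.log(np.asarray(config.month_multipliers))
    rate_ref = float(config.base_annual_rate[reference_site][method])
    out: dict[str, float] = {
        "intercept": np.log(rate_ref / RATE_DENOMINATOR / DAYS_PER_YEAR) + wd[0] + mo[0]
    }
    for site in sorted(s for s in sites if s != reference_site):
        out[f"site_{site}"] = float(
            np.log(config.base_annual_rate[site][method] / rate_ref)
        )
    for j, col in enumerate(WEEKDAY_COLS[1:], start=1):
        out[col] = float(wd[j] - wd[0])
    for j, col in enumerate(MONTH_COLS[1:], start=1):
        out[col] = float(mo[j] - mo[0])
    ref_effect = np.log(config.intervention_multiplier_for(reference_site, method))
    out["post"] = float(ref_effect)
    for site in sorted(s for s in sites if s != reference_site):
        out[f"post_x_{site}"] = float(
            np.log(config.intervention_multiplier_for(site, method)) - ref_effect
        )
    return out


# ---------------------------------------------------------------------------
# Study-calibrated default scenario
# ---------------------------------------------------------------------------

NEW_TAIPEI = "New Taipei City"
TAIPEI = "Taipei City"
KAOHSIUNG = "Kaohsiung City"

INTERVENTION_DATE = dt.date(2012, 5, 1)
STUDY_START = dt.date(2009, 1, 1)
STUDY_END = dt.date(2013, 12, 31)
WEEKLY_FROM = dt.date(2013, 1, 1)

#: Pre-intervention annualized rates per 100,000 person-years (site x method).
BASE_RATES = {
    NEW_TAIPEI: {"charcoal": 6.2, "other": 12.3},
    TAIPEI: {"charcoal": 3.5, "other": 10.8},
    KAOHSIUNG: {"charcoal": 5.3, "other": 14.9},
}

POPULATIONS = {NEW_TAIPEI: 3_900_000, TAIPEI: 2_700_000, KAOHSIUNG: 2_700_000}

#: Intervention-period log-rate effects relative to the reference city
#: (common post effect 0.05; extra effects -0.36 / -0.23 for the intervention
#: city and the adjacent control; none on non-charcoal methods).
INTERVENTION_LOG_EFFECTS = {
    "charcoal": {NEW_TAIPEI: 0.05 - 0.36, TAIPEI: 0.05 - 0.23, KAOHSIUNG: 0.05},
    "other": {NEW_TAIPEI: 0.0, TAIPEI: 0.0, KAOHSIUNG: 0.0},
}

#: Mean secular log-trend level over the intervention period relative to the
#: pre-period mean (charcoal declined markedly in all three cities; other
#: methods were nearly flat).
TREND_POST_MEAN = {"charcoal": -0.16, "other": -0.02}

# Mild, plausibly sized seasonality: Monday peak; spring peak, winter trough.
WEEKDAY_LOG = [0.06, 0.02, 0.0, -0.01, -0.02, -0.03, -0.02]
MONTH_LOG = [-0.08, -0.04, 0.06, 0.10, 0.10, 0.06, 0.02, 0.0, -0.02, -0.04, -0.10, -0.06]


def study_scenario(seed: int = 0, null: bool = False) -> ScenarioConfig:
    """Three-city scenario calibrated to the study's descriptive tables.

    Baseline rates, populations, calendar, weekly 2013 aggregation and
    intervention effects reproduce the published study conditions; the secular
    trend is linear on the log scale with pre-period mean zero and
    intervention-period mean :data:`TREND_POST_MEAN`.  With ``null=True`` all
    intervention multipliers are one (for calibration/size checks).
    """
    n_days = (STUDY_END - STUDY_START).days + 1
    pre_days = (INTERVENTION_DATE - STUDY_START).days
    pre_mid = (pre_days - 1) / 2.0 + 0.5
    post_mid = pre_days + (n_days - pre_days - 1) / 2.0 + 0.5
    trends = {
        m: LogTrend.linear(TREND_POST_MEAN[m] / (post_mid - pre_mid), n_days, t_ref=pre_mid)
        for m in ("charcoal", "other")
    }
    multipliers = (
        1.0
        if null
        else {
            site: {m: float(np.exp(INTERVENTION_LOG_EFFECTS[m][site])) for m in ("charcoal", "other")}
            for site in POPULATIONS
        }
    )
    return ScenarioConfig(
        sites=dict(POPULATIONS),
        methods=["charcoal", "other"],
        base_annual_rate=BASE_RATES,
        weekday_multipliers=tuple(np.exp(WEEKDAY_LOG)),
        month_multipliers=tuple(np.exp(MONTH_LOG)),
        trend=trends,
        intervention_date=INTERVENTION_DATE,
        intervention_multiplier=multipliers,
        date_range=(STUDY_START, STUDY_END),
        weekly_aggregation_from=WEEKLY_FROM,
        seed=seed,
    )
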