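"""Shared fixtures: seeded synthetic scenarios at several scales."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from charcoal_restriction import glm_model, synthetic


@pytest.fixture(scope="session")
def study_obs() -> pd.DataFrame:
    """One draw of the full study-calibrated three-city observation table."""
    return synthetic.generate(synthetic.study_scenario(seed=1))


@pytest.fixture(scope="session")
def study_scenario_cfg() -> synthetic.ScenarioConfig:
    return synthetic.study_scenario(seed=1)


def single_site_scenario(
    rate: float = 6.2,
    pop: float = 3_900_000,
    effect_log: float = 0.0,
    trend_post_mean: float = 0.0,
    years: tuple[dt.date, dt.date] = (synthetic.STUDY_START, synthetic.STUDY_END),
    weekly: bool = True,
    seasonal: bool = True,
    seed: int = 0,
) -> synthetic.ScenarioConfig:
    """One-city one-method scenario on the study calendar, with optional
    intervention step and linear secular trend (pre-period mean zero)."""
    start, end = years
    n_days = (end - start).days + 1
    pre_days = (synthetic.INTERVENTION_DATE - start).days
    trend = None
    if trend_post_mean != 0.0:
        pre_mid = (pre_days - 1) / 2 + 0.5
        post_mid = pre_days + (n_days - pre_days - 1) / 2 + 0.5
        trend = synthetic.LogTrend.linear(
            trend_post_mean / (post_mid - pre_mid), n_days, t_ref=pre_mid
        )
    return synthetic.ScenarioConfig(
        sites={synthetic.NEW_TAIPEI: pop},
        methods=["charcoal"],
        base_annual_rate={synthetic.NEW_TAIPEI: {"charcoal": rate}},
        weekday_multipliers=tuple(np.exp(synthetic.WEEKDAY_LOG)) if seasonal else (1.0,) * 7,
        month_multipliers=tuple(np.exp(synthetic.MONTH_LOG)) if seasonal else (1.0,) * 12,
        trend=trend,
        intervention_date=synthetic.INTERVENTION_DATE,
        intervention_multiplier=float(np.exp(effect_log)),
        date_range=(start, end),
        weekly_aggregation_from=synthetic.WEEKLY_FROM if weekly else None,
        seed=seed,
    )


def tiny_two_site_scenario(seed: int = 3) -> synthetic.ScenarioConfig:
    """24-day two-site fixture with a mid-series intervention, for brute-force
    likelihood oracles (48 records)."""
    return synthetic.ScenarioConfig(
        sites={"A": 1_000_000, "B": 900_000},
        methods=["m"],
        base_annual_rate={"A": {"m": 400.0}, "B": {"m": 300.0}},
        intervention_date=dt.date(2009, 1, 13),
        date_range=(dt.date(2009, 1, 1), dt.date(2009, 1, 24)),
        intervention_multiplier={"A": 0.7, "B": 1.0},
        seed=seed,
    )


def homogeneous_obs(
    mu: float, n_days: int, pop: float = 1.0, seed: int = 0, count_draw: bool = True
) -> pd.DataFrame:
    """Minimal daily observation table with constant Poisson mean ``mu``.

    Bypasses the calendar generator for speed in replicated property tests;
    ``population`` is chosen so the exposure per day is ``pop`` person-days.
    """
    rng = np.random.default_rng(seed)
    counts = rng.poisson(mu, n_days) if count_draw else np.full(n_days, mu)
    start = pd.Timestamp("2009-01-01")
    obs = pd.DataFrame(
        {
            "site": "A",
            "method": "m",
            "period_start": pd.date_range(start, periods=n_days, freq="D"),
            "period_length_days": 1.0,
            "count": counts,
            "population": pop,
            "post_intervention": 0,
            "midpoint_time": np.arange(n_days) + 0.5,
        }
    )
    dates = pd.DatetimeIndex(obs["period_start"])
    from charcoal_restriction.data_io import MONTH_COLS, WEEKDAY_COLS

    obs[WEEKDAY_COLS] = np.eye(7)[dates.dayofweek]
    obs[MONTH_COLS] = np.eye(12)[dates.month - 1]
    return obs


def intercept_only_design(y: np.ndarray) -> glm_model.DesignMatrix:
    """A bare intercept-only design around given counts (unit exposure)."""
    n = len(y)
    stub = homogeneous_obs(0.0, n, count_draw=False)
    stub["count"] = y
    return glm_model.DesignMatrix(
        X=pd.DataFrame({"intercept": np.ones(n)}),
        y=np.asarray(y, dtype=float),
        offset=np.zeros(n),
        spec=glm_model.ModelSpec(reference_site="A", n_interior_knots=0),
        spline_knots=np.array([]),
        dropped_columns=[],
        obs=stub,
    )
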