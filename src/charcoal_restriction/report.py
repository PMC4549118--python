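"""Pipeline orchestration: run every analysis stage and export a report bundle.

The bundle mirrors the published analysis: a descriptive rate table, intensity
curves with the change-point check, per-method coefficient tables with
dispersion/PIT diagnostics and the family actually used, intervention effects
as percent reductions, and the lives-saved simulation.  Everything is
deterministic given the input table and the seed, and every data-driven
decision (knot counts, family switches) is recorded in a structured log.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from charcoal_restriction import counterfactual, data_io, glm_model, intensity


@dataclasses.dataclass
class PipelineConfig:
    """Site roles and stage options for one end-to-end run."""

    intervention_site: str
    reference_site: str
    methods: Sequence[str] = ("charcoal", "other", "all")
    counterfactual_method: str = "charcoal"
    n_interior_knots: int | str = "AIC"
    knot_candidates: Sequence[int] = tuple(range(0, 11))
    bandwidth: float = intensity.DEFAULT_BANDWIDTH
    degree: int = intensity.DEFAULT_DEGREE
    n_grid: int = 101
    n_replicates: int = 10_000
    seed: int = 0
    scope: str = counterfactual.CITY_TOTAL

    def __post_init__(self) -> None:
        if self.intervention_site == self.reference_site:
            raise ValueError("the reference site must be a control site")


@dataclasses.dataclass
class ReportBundle:
    rate_table: pd.DataFrame
    intensity_curves: pd.DataFrame
    changepoints: pd.DataFrame
    analyses: Mapping[str, glm_model.MethodAnalysis]
    effects: pd.DataFrame
    lives_saved: counterfactual.LivesSavedEstimate
    projection: pd.DataFrame
    log: dict


def run_pipeline(obs: pd.DataFrame, config: PipelineConfig) -> ReportBundle:
    """Run every stage of the evaluation on a validated observation table."""
    data_io.validate_observations(obs)
    log: dict = {"stages": []}

    rate_tab = data_io.rate_table(obs, intervention_date=None)
    log["stages"].append("rate_table")

    curves, cps = [], []
    methods_raw = [m for m in config.methods if m != data_io.ALL_METHODS]
    for site in sorted(obs["site"].unique()):
        for method in methods_raw:
            sub = obs[(obs["site"] == site) & (obs["method"] == method)]
            pre, post, t0 = intensity.estimate_segments(
                sub, bandwidth=config.bandwidth, degree=config.degree, n_grid=config.n_grid
            )
            for curve in (pre, post):
                frame = curve.to_frame()
                frame.insert(0, "site", site)
                frame.insert(1, "method", method)
                curves.append(frame)
            check = intensity.changepoint_check(pre, post, t0)
            cps.append(
                {
                    "site": site,
                    "method": method,
                    "t0": t0,
                    "drop_detected": check.drop_detected,
                    "alpha_pre_t0": check.alpha_pre_t0,
                    "alpha_post_t0": check.alpha_post_t0,
                    "post_ci_low": check.post_ci_at_t0[0],
                    "post_ci_high": check.post_ci_at_t0[1],
                }
            )
    log["stages"].append("intensity")

    analyses: dict[str, glm_model.MethodAnalysis] = {}
    effects = []
    log["models"] = {}
    for method in config.methods:
        ana = glm_model.analyze_method(
            obs,
            method,
            reference_site=config.reference_site,
            candidates=config.knot_candidates,
            n_interior_knots=config.n_interior_knots,
        )
        analyses[method] = ana
        log["models"][method] = {
            "n_interior_knots": ana.spec.n_interior_knots,
            "dispersion_statistic": ana.dispersion.statistic,
            "dispersion_p": ana.dispersion.p_value,
            "overdispersed": ana.dispersion.overdispersed,
            "family": ana.fit.family,
            "nb_alpha": ana.fit.nb_alpha,
            "pit_chisq": ana.pit.chisq_stat,
            "pit_p": ana.pit.p_value,
            "aic": ana.fit.aic,
        }
        for site in sorted(obs["site"].unique()):
            for scope in ("contrast", "total"):
                eff = glm_model.effect_estimate(ana.fit, site, scope)
                effects.append(
                    {
                        "method": method,
                        "site": site,
                        "scope": scope,
                        "log_effect": eff.log_effect,
                        "se": eff.se,
                        "pct_reduction": eff.pct_reduction,
                        "ci_low_pct": eff.ci[0],
                        "ci_high_pct": eff.ci[1],
                        "p_value": eff.p_value,
                    }
                )
    log["stages"].append("glm")

    cf_fit = analyses[config.counterfactual_method].fit
    lives = counterfactual.simulate_lives_saved(
        cf_fit,
        config.intervention_site,
        B=config.n_replicates,
        seed=config.seed,
        scope=config.scope,
    )
    projection = counterfactual.projected_vs_actual(cf_fit, config.intervention_site, config.scope)
    log["stages"].append("counterfactual")
    log["lives_saved"] = {
        "site": lives.site,
        "scope": lives.scope,
        "median": lives.median,
        "ci": [lives.ci_low, lives.ci_high],
        "B": lives.n_replicates,
        "observed_total": lives.observed_total,
        "expected_counterfactual_total": lives.expected_counterfactual_total,
    }
    return ReportBundle(
        rate_table=rate_tab,
        intensity_curves=pd.concat(curves, ignore_index=True),
        changepoints=pd.DataFrame(cps),
        analyses=analyses,
        effects=pd.DataFrame(effects),
        lives_saved=lives,
        projection=projection,
        log=log,
    )


def write_bundle(bundle: ReportBundle, outdir, make_plots: bool = False) -> list[pathlib.Path]:
    """Write the bundle as CSV/JSON files (plus plots on request); returns paths."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _csv(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, index=False, float_format="%.10g")
        written.append(path)

    _csv(bundle.rate_table, "rate_table.csv")
    _csv(bundle.intensity_curves, "intensity_curves.csv")
    _csv(bundle.changepoints, "changepoints.csv")
    _csv(bundle.effects, "effects.csv")
    _csv(bundle.projection, "projected_vs_actual.csv")
    for method, ana in bundle.analyses.items():
        tab = ana.fit.coef_table().reset_index(names="term")
        _csv(tab, f"coefficients_{method}.csv")
        if not ana.aic_table.empty:
            _csv(ana.aic_table, f"aic_{method}.csv")
    path = outdir / "log.json"
    path.write_text(json.dumps(bundle.log, indent=2, default=float) + "\n")
    written.append(path)
    if make_plots:
        written.extend(_plots(bundle, outdir))
    return written


def _plots(bundle: ReportBundle, outdir: pathlib.Path) -> list[pathlib.Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    curves = bundle.intensity_curves
    sites = sorted(curves["site"].unique())
    methods = sorted(curves["method"].unique())
    fig, axes = plt.subplots(
        len(methods), len(sites), figsize=(4 * len(sites), 3 * len(methods)),
        squeeze=False, sharex=True,
    )
    for i, method in enumerate(methods):
        for j, site in enumerate(sites):
            ax = axes[i][j]
            for seg, grp in curves[(curves["site"] == site) & (curves["method"] == method)].groupby(
                "segment"
            ):
                ax.plot(grp["time"], grp["alpha"], color="C0" if seg == "pre" else "C3")
                ax.fill_between(grp["time"], grp["ci_low"], grp["ci_high"], alpha=0.2,
                                color="C0" if seg == "pre" else "C3")
            ax.set_title(f"{site} — {method}", fontsize=9)
            ax.set_ylabel("per 100,000 py")
    fig.tight_layout()
    p = outdir / "intensity_curves.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    proj = bundle.projection.copy()
    proj["month"] = pd.to_datetime(proj["period_start"]).dt.to_period("M")
    monthly = proj.groupby("month")[["observed", "fitted", "counterfactual"]].sum()
    fig, ax = plt.subplots(figsize=(7, 4))
    monthly.plot(ax=ax, style=["k.-", "C0-", "C3--"])
    ax.set_ylabel("deaths per month")
    ax.set_title("Projected (no intervention) vs actual counts")
    fig.tight_layout()
    p = outdir / "projected_vs_actual.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)
    return paths
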