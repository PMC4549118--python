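"""Seasonal B-spline count regression with site-by-intervention contrasts.

The mean model for record *i* (count ``y_i``, population ``Pop_i``, interval
length ``T_i`` days, interval midpoint ``t_i``) is

    E[y_i] = Pop_i * T_i * exp{ b0 + B(t_i) b_tr + site contrasts
                                + weekday contrasts + month contrasts
                                + post_i b_post + site_i * post_i b_extra }

fitted by maximum likelihood with a log link and ``log(Pop_i * T_i)`` offset,
as a Poisson GLM, refitted as NB2 when a dispersion test rejects
equidispersion.  The secular trend is a clamped cubic B-spline (order 4) with
evenly spaced interior knots; the number of knots is selected by AIC.  The
reference cell is the reference site on a Monday in January, pre-intervention.

``post`` is the common intervention-period effect (the reference city's own
change beyond the secular trend); ``post_x_<site>`` is the extra effect in
each non-reference city.  Percent rate changes are ``100*(1-exp(beta))``.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
import statsmodels.api as sm
from statsmodels.discrete.discrete_model import NegativeBinomial as _NegBinModel

from charcoal_restriction.data_io import MONTH_COLS, WEEKDAY_COLS

SPLINE_ORDER = 4  # order 4 = cubic
POST = "post"


def site_col(site: str) -> str:
    return f"site_{site}"


def post_site_col(site: str) -> str:
    return f"post_x_{site}"


@dataclasses.dataclass
class ModelSpec:
    """Regression structure: reference site and secular-trend knot count.

    ``n_interior_knots`` may be an integer or ``"AIC"`` (resolve with
    :func:`select_knots`).  Knots are evenly spaced strictly inside the study
    time range; the spline order is fixed at 4 (cubic).
    """

    reference_site: str
    n_interior_knots: int | str = "AIC"

    def resolved(self) -> bool:
        return not isinstance(self.n_interior_knots, str)


@dataclasses.dataclass
class DesignMatrix:
    """Design matrix, offset and response aligned to an observation table."""

    X: pd.DataFrame
    y: np.ndarray
    offset: np.ndarray
    spec: ModelSpec
    spline_knots: np.ndarray
    dropped_columns: list[str]
    obs: pd.DataFrame

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)


def _spline_basis(t: np.ndarray, lo: float, hi: float, n_interior: int) -> tuple[np.ndarray, np.ndarray]:
    interior = lo + (hi - lo) * np.arange(1, n_interior + 1) / (n_interior + 1)
    knots = np.concatenate([[lo] * SPLINE_ORDER, interior, [hi] * SPLINE_ORDER])
    k = SPLINE_ORDER - 1
    basis = BSpline.design_matrix(np.clip(t, lo, hi), knots, k).toarray()
    return basis, knots


def build_design(obs: pd.DataFrame, spec: ModelSpec) -> DesignMatrix:
    """Assemble the model's design matrix from a validated observation table.

    The first B-spline basis column is dropped (the full clamped basis sums to
    one and would be collinear with the intercept).  Columns that are
    structurally zero on this subset (e.g. intervention terms on pre-only
    data, months never observed) are dropped and recorded in
    ``dropped_columns``; any remaining rank deficiency raises ``ValueError``
    naming the collinear columns.
    """
    if not spec.resolved():
        raise ValueError("knot count unresolved; run select_knots first")
    obs = obs.reset_index(drop=True)
    t = obs["midpoint_time"].to_numpy(dtype=float)
    lo = float((obs["midpoint_time"] - obs["period_length_days"] / 2).min())
    hi = float((obs["midpoint_time"] + obs["period_length_days"] / 2).max())
    n_int = int(spec.n_interior_knots)
    basis, knots = _spline_basis(t, lo, hi, n_int)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(obs))}
    for j in range(1, basis.shape[1]):
        cols[f"spline_{j}"] = basis[:, j]
    sites = sorted(obs["site"].unique())
    if spec.reference_site not in sites:
        raise ValueError(f"reference site {spec.reference_site!r} absent from data")
    post = obs["post_intervention"].to_numpy(dtype=float)
    for s in sites:
        if s != spec.reference_site:
            cols[site_col(s)] = (obs["site"] == s).to_numpy(dtype=float)
    for c in WEEKDAY_COLS[1:] + MONTH_COLS[1:]:
        cols[c] = obs[c].to_numpy(dtype=float)
    cols[POST] = post
    for s in sites:
        if s != spec.reference_site:
            cols[post_site_col(s)] = cols[site_col(s)] * post
    X = pd.DataFrame(cols)
    dropped = [c for c in X.columns if not np.any(X[c].to_numpy() != 0.0)]
    X = X.drop(columns=dropped)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name offending columns via tiny R-diagonal entries of a pivoted QR
        r = np.linalg.qr(X.to_numpy(), mode="r")
        diag = np.abs(np.diag(r))
        bad = [X.columns[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    offset = np.log(obs["population"].to_numpy() * obs["period_length_days"].to_numpy())
    return DesignMatrix(
        X=X,
        y=obs["count"].to_numpy(dtype=float),
        offset=offset,
        spec=spec,
        spline_knots=knots,
        dropped_columns=dropped,
        obs=obs,
    )


@dataclasses.dataclass
class FitResult:
    """Fitted count regression: coefficients, covariance, likelihood, family."""

    family: str  # "poisson" | "negbin"
    params: pd.Series
    cov: pd.DataFrame
    loglik: float
    aic: float
    fitted: np.ndarray  # mu_hat per record
    design: DesignMatrix
    nb_alpha: float | None = None
    nb_alpha_se: float | None = None

    def coef_table(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov))
        z = self.params.to_numpy() / se
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": se,
                "z": z,
                "p_value": 2 * stats.norm.sf(np.abs(z)),
            }
        )


def fit_poisson(design: DesignMatrix) -> FitResult:
    """Maximum-likelihood Poisson fit with log link and exposure offset."""
    model = sm.GLM(design.y, design.X, family=sm.families.Poisson(), offset=design.offset)
    res = model.fit(maxiter=200, tol=1e-10)
    if not res.converged:
        raise RuntimeError(f"Poisson IRLS did not converge: {res.fit_history}")
    mu = np.asarray(res.mu)
    return FitResult(
        family="poisson",
        params=pd.Series(res.params, index=design.columns),
        cov=pd.DataFrame(res.cov_params(), index=design.columns, columns=design.columns),
        loglik=float(res.llf),
        aic=float(res.aic),
        fitted=mu,
        design=design,
    )


def select_knots(
    obs: pd.DataFrame,
    spec: ModelSpec,
    candidates: Sequence[int] = tuple(range(0, 11)),
) -> tuple[ModelSpec, pd.DataFrame]:
    """Pick the AIC-minimizing interior-knot count (ties favour fewer knots).

    Returns the resolved spec and the candidate/AIC table.
    """
    if not candidates:
        raise ValueError("empty candidate grid")
    records, failures = [], []
    for n in sorted(candidates):
        try:
            fit = fit_poisson(build_design(obs, dataclasses.replace(spec, n_interior_knots=n)))
            records.append({"n_interior_knots": n, "aic": fit.aic, "loglik": fit.loglik})
        except Exception as exc:  # noqa: BLE001 - record and move on
            failures.append((n, exc))
    if not records:
        raise RuntimeError(f"all candidate fits failed: {failures}")
    table = pd.DataFrame(records)
    best = int(table.loc[table["aic"].idxmin(), "n_interior_knots"])
    return dataclasses.replace(spec, n_interior_knots=best), table


@dataclasses.dataclass
class DispersionTest:
    statistic: float
    p_value: float
    overdispersed: bool
    c_hat: float


def dispersion_test(fit: FitResult, alpha: float = 0.05) -> DispersionTest:
    """Test equidispersion against Var = (1 + c) * mu, one-sided for c > 0.

    Auxiliary least-squares regression of ``((y - mu)^2 - y) / mu`` on a
    constant; the z-statistic of the constant is compared with N(0, 1).
    """
    mu = fit.fitted
    if np.any(mu <= 0):
        raise ValueError("fitted means must be positive")
    y = fit.design.y
    z = ((y - mu) ** 2 - y) / mu
    c_hat = float(np.mean(z))
    sd = float(np.std(z, ddof=1))
    if sd == 0.0:
        statistic = -np.inf if c_hat <= 0 else np.inf
    else:
        statistic = c_hat / (sd / np.sqrt(len(z)))
    p = float(stats.norm.sf(statistic))
    return DispersionTest(statistic=float(statistic), p_value=p,
                          overdispersed=bool(p < alpha), c_hat=c_hat)


def fit_negbin(design: DesignMatrix) -> FitResult:
    """NB2 maximum-likelihood fit (log link, offset, dispersion jointly).

    Variance function ``mu + alpha * mu^2``.  If the dispersion estimate
    collapses to the Poisson boundary a warning is issued and the returned
    fit is the Poisson-equivalent one.
    """
    start = fit_poisson(design)
    model = _NegBinModel(design.y, design.X, loglike_method="nb2", offset=design.offset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(
            start_params=np.r_[start.params.to_numpy(), 0.05],
            method="bfgs", maxiter=500, disp=0,
        )
    est = np.asarray(res.params, dtype=float)
    alpha = float(est[-1])
    if alpha < 1e-8:
        warnings.warn("NB dispersion at the Poisson boundary; returning Poisson fit")
        return dataclasses.replace(start, family="negbin", nb_alpha=0.0)
    names = design.columns
    try:
        full_cov = np.asarray(res.cov_params())
    except (ValueError, np.linalg.LinAlgError):
        # singular information at/near the Poisson boundary
        warnings.warn("NB information matrix singular (dispersion near the "
                      "Poisson boundary); returning Poisson fit")
        return dataclasses.replace(start, family="negbin", nb_alpha=0.0)
    cov = full_cov[: len(names), : len(names)]
    alpha_se = float(np.sqrt(max(full_cov[-1, -1], 0.0)))
    beta = est[: len(names)]
    mu = np.exp(design.X.to_numpy() @ beta + design.offset)
    return FitResult(
        family="negbin",
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        loglik=float(res.llf),
        aic=float(res.aic),
        fitted=mu,
        design=design,
        nb_alpha=alpha,
        nb_alpha_se=alpha_se,
    )


def _count_cdf(fit: FitResult, k: np.ndarray) -> np.ndarray:
    """Predictive CDF F(k) per record under the fitted family (k may be -1)."""
    mu = fit.fitted
    if fit.family == "poisson" or not fit.nb_alpha:
        return stats.poisson.cdf(k, mu)
    r = 1.0 / fit.nb_alpha
    p = r / (r + mu)
    return stats.nbinom.cdf(k, r, p)


@dataclasses.dataclass
class PITResult:
    bin_edges: np.ndarray
    histogram: np.ndarray  # mean PIT density per bin (integrates to 1)
    chisq_stat: float
    p_value: float
    dof: int


def pit_residuals(fit: FitResult, bins: int = 10) -> PITResult:
    """Non-randomized probability-integral-transform diagnostic.

    Each observation's PIT mass is spread uniformly over
    ``[F(y-1), F(y)]``; the aggregated histogram is uniform when the model's
    predictive distributions are correct.  A chi-squared statistic with
    ``bins - 1`` degrees of freedom summarizes departure from uniformity.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    y = fit.design.y
    u_hi = _count_cdf(fit, y)
    u_lo = _count_cdf(fit, y - 1)
    width = np.maximum(u_hi - u_lo, 1e-300)
    edges = np.linspace(0.0, 1.0, bins + 1)
    # mass of [u_lo, u_hi] overlapping each bin, averaged over observations
    overlap = (
        np.clip(edges[None, 1:], u_lo[:, None], u_hi[:, None])
        - np.clip(edges[None, :-1], u_lo[:, None], u_hi[:, None])
    ) / width[:, None]
    counts = overlap.sum(axis=0)
    n = len(y)
    expected = n / bins
    chisq = float(((counts - expected) ** 2 / expected).sum())
    return PITResult(
        bin_edges=edges,
        histogram=counts / n * bins,
        chisq_stat=chisq,
        p_value=float(stats.chi2.sf(chisq, bins - 1)),
        dof=bins - 1,
    )


@dataclasses.dataclass
class InterventionEffect:
    """A site's intervention effect as a percent rate reduction."""

    site: str
    scope: str  # "contrast" | "total"
    log_effect: float
    se: float
    pct_reduction: float
    ci: tuple[float, float]  # percent scale, low <= high
    p_value: float


def effect_estimate(fit: FitResult, site: str, scope: str = "total") -> InterventionEffect:
    """Intervention effect for a site, as ``100 * (1 - exp(beta))`` percent.

    ``scope="contrast"`` uses the site's extra effect relative to the
    reference city; ``scope="total"`` adds the common post term with
    covariance-propagated standard error.  For the reference city both scopes
    equal the common post term.
    """
    if scope not in ("contrast", "total"):
        raise ValueError(f"unknown scope {scope!r}")
    names = list(fit.params.index)
    if POST not in names:
        raise ValueError("fit has no intervention terms")
    ref = fit.design.spec.reference_site
    inter = post_site_col(site)
    if site != ref and inter not in names:
        raise ValueError(f"unknown site {site!r}")
    w = pd.Series(0.0, index=names)
    if site == ref:
        w[POST] = 1.0
    elif scope == "contrast":
        w[inter] = 1.0
    else:
        w[POST] = 1.0
        w[inter] = 1.0
    beta = float(w @ fit.params)
    var = float(w @ fit.cov @ w)
    se = np.sqrt(var)
    lo, hi = beta - 1.96 * se, beta + 1.96 * se
    return InterventionEffect(
        site=site,
        scope=scope,
        log_effect=beta,
        se=se,
        pct_reduction=100.0 * (1.0 - np.exp(beta)),
        ci=(100.0 * (1.0 - np.exp(hi)), 100.0 * (1.0 - np.exp(lo))),
        p_value=float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else np.nan,
    )


@dataclasses.dataclass
class MethodAnalysis:
    """End-to-end fit of one method category: selection, fit, diagnostics."""

    method: str
    spec: ModelSpec
    aic_table: pd.DataFrame
    fit: FitResult
    dispersion: DispersionTest
    pit: PITResult
    poisson_fit: FitResult


def analyze_method(
    obs: pd.DataFrame,
    method: str,
    reference_site: str,
    candidates: Sequence[int] = tuple(range(0, 11)),
    n_interior_knots: int | str = "AIC",
) -> MethodAnalysis:
    """Fit one method category the way the published analysis specifies.

    Subsets to the method (``"all"`` sums the categories), selects knots by
    AIC when requested, fits the Poisson GLM, tests for overdispersion and
    refits as NB2 if detected, then computes PIT diagnostics on the final fit.
    """
    from charcoal_restriction.data_io import ALL_METHODS, combine_methods

    sub = combine_methods(obs) if method == ALL_METHODS else obs[obs["method"] == method]
    if sub.empty:
        raise ValueError(f"no records for method {method!r}")
    spec = ModelSpec(reference_site=reference_site, n_interior_knots=n_interior_knots)
    if not spec.resolved():
        spec, aic_table = select_knots(sub, spec, candidates)
    else:
        aic_table = pd.DataFrame()
    design = build_design(sub, spec)
    pois = fit_poisson(design)
    disp = dispersion_test(pois)
    fit = fit_negbin(design) if disp.overdispersed else pois
    return MethodAnalysis(
        method=method,
        spec=spec,
        aic_table=aic_table,
        fit=fit,
        dispersion=disp,
        pit=pit_residuals(fit),
        poisson_fit=pois,
    )
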