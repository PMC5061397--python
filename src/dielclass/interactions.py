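"""Poisson mixed models for predator--prey and competitor co-detection.

Counts of a focal species at camera site *i* in observation unit *j* are
modelled as

    y_ij ~ Poisson(mu_ij),   log mu_ij = beta0 + beta' x_ij + u_i,
    u_i ~ Normal(0, sigma2),

where x_ij holds the counts of the explanatory species at the same site and
unit and u_i is a site-level random intercept absorbing between-camera
heterogeneity (placement, trail use, effort differences).  A positive
coefficient means the focal species is detected more where and when the
explanatory species is detected more -- the co-detection signal used to
probe predator--prey and competitive association.

The marginal likelihood integrates the random effect out site by site.  The
production fitter uses the Laplace approximation: an inner Newton solve
locates each site's conditional mode u_i-hat, and the integral is replaced by
the Gaussian approximation at the mode.  An adaptive Gauss--Hermite
quadrature mode (nodes recentred and rescaled at the same mode) serves as
the high-accuracy oracle for verifying the Laplace objective.  Maximization
is quasi-Newton over (beta, log sigma2); standard errors come from the
inverse observed information (finite-difference Hessian of the marginal
log-likelihood) at the optimum, giving Wald Z and two-sided p values.

A covariate that is all zero wherever the response is positive cannot be
separated from -infinity; fits then show a large negative coefficient with
an enormous standard error.  Such columns are flagged, not hidden.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp
from scipy import stats

from .records import DetectionEvent, EffortLedger
from .solar import season_of

__all__ = [
    "SiteCounts",
    "GlmmFit",
    "aggregate_site_counts",
    "glmm_marginal_loglik",
    "fit_poisson_glmm",
]

logger = logging.getLogger(__name__)

#: inner Newton tolerance on the mode gradient
_MODE_TOL = 1e-10
#: outer gradient-norm threshold for declaring convergence
_GRAD_TOL = 1e-6
#: a Wald SE above this flags a practically unidentified (separated) coefficient
_SE_PATHOLOGY = 10.0


@dataclass
class SiteCounts:
    """Per site x observation-unit counts of a focal and explanatory species."""

    frame: pd.DataFrame  # columns: site, unit, y, one column per covariate
    focal: str
    covariates: list[str]
    unit: str  # 'day' | 'week' | 'season-total'

    @property
    def n_sites(self) -> int:
        return self.frame["site"].nunique()


@dataclass
class GlmmFit:
    """Fitted Poisson random-intercept model."""

    names: list[str]  # 'intercept' first, then covariates
    beta: np.ndarray
    se: np.ndarray
    sigma2: float
    loglik: float
    converged: bool
    grad_norm: float
    n_obs: int
    n_sites: int
    messages: list[str] = field(default_factory=list)

    @property
    def z(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.beta, "se": self.se, "z": self.z, "p": self.p},
            index=pd.Index(self.names, name="term"),
        )


def aggregate_site_counts(
    events: list[DetectionEvent],
    focal: str,
    explanatory: list[str],
    effort: EffortLedger,
    season: str | None = None,
    unit: str = "day",
) -> SiteCounts:
    """Count focal and explanatory detections per camera site x observation unit.

    ``unit`` is ``'day'`` (one row per site x active date), ``'week'`` (ISO
    week) or ``'season-total'`` (one row per site).  Zero rows are kept for
    every unit with effort; events of species not listed are ignored; with
    ``season`` given, only dates in that season contribute.
    """
    if unit not in ("day", "week", "season-total"):
        raise ValueError(f"unknown unit {unit!r}")
    species_of_interest = {focal, *explanatory}

    def unit_of(d: dt.date):
        if unit == "day":
            return d.isoformat()
        if unit == "week":
            iso = d.isocalendar()
            return f"{iso.year}-W{iso.week:02d}"
        return "total"

    rows: dict[tuple[str, str], dict[str, int]] = {}
    for cam, ivs in effort.entries.items():
        for s, e in ivs:
            for i in range((e - s).days + 1):
                d = s + dt.timedelta(days=i)
                if season is not None and season_of(d) != season:
                    continue
                key = (cam, unit_of(d))
                rows.setdefault(key, {sp: 0 for sp in species_of_interest})
    if not rows:
        logger.warning("no effort in season %r: empty table", season)
    dropped = 0
    for ev in events:
        if ev.species not in species_of_interest:
            continue
        d = ev.timestamp.date()
        if season is not None and season_of(d) != season:
            continue
        key = (ev.camera_id, unit_of(d))
        if key not in rows:
            dropped += 1
            continue
        rows[key][ev.species] += 1
    if dropped:
        logger.warning("%d events outside effort ignored", dropped)

    recs = [
        {"site": cam, "unit": u, "y": counts[focal],
         **{sp: counts[sp] for sp in explanatory}}
        for (cam, u), counts in sorted(rows.items())
    ]
    frame = pd.DataFrame(recs, columns=["site", "unit", "y", *explanatory])
    return SiteCounts(frame=frame, focal=focal, covariates=list(explanatory), unit=unit)


# ---------------------------------------------------------------------------
# marginal likelihood


def _site_modes(
    eta_fixed: np.ndarray,
    y_sums: np.ndarray,
    site_idx: np.ndarray,
    n_sites: int,
    sigma2: float,
    u0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Newton solve for all sites' conditional modes simultaneously.

    Returns (u_hat, curvature) where curvature_i = -d2h/du2 at the mode =
    sum_j mu_ij + 1/sigma2.  The per-site objective is strictly concave, so
    damped Newton converges from any start.
    """
    u = np.zeros(n_sites) if u0 is None else u0.copy()
    for _ in range(100):
        mu_sums = np.bincount(site_idx, weights=np.exp(eta_fixed + u[site_idx]),
                              minlength=n_sites)
        grad = y_sums - mu_sums - u / sigma2
        if np.max(np.abs(grad)) < _MODE_TOL:
            break
        hess = -mu_sums - 1.0 / sigma2
        step = -grad / hess
        # step-halve any site whose objective would not improve (rare; the
        # exponential can overshoot for large steps)
        step = np.clip(step, -5.0, 5.0)
        u = u + step
    mu_sums = np.bincount(site_idx, weights=np.exp(eta_fixed + u[site_idx]),
                          minlength=n_sites)
    return u, mu_sums + 1.0 / sigma2


def _prep(y: np.ndarray, X: np.ndarray, sites: np.ndarray):
    uniq, site_idx = np.unique(sites, return_inverse=True)
    n_sites = uniq.size
    y_sums = np.bincount(site_idx, weights=y, minlength=n_sites)
    return site_idx, n_sites, y_sums


def glmm_marginal_loglik(
    beta: np.ndarray,
    sigma2: float,
    y: np.ndarray,
    X: np.ndarray,
    sites: np.ndarray,
    method: str = "laplace",
    n_quad: int = 21,
    u0: np.ndarray | None = None,
) -> float:
    """Marginal log-likelihood of the Poisson random-intercept model.

    ``method='laplace'`` evaluates the Laplace approximation;
    ``method='quadrature'`` the adaptive Gauss--Hermite rule with ``n_quad``
    nodes recentred at each site's mode (the oracle).  ``sigma2 = 0``
    collapses both to the plain Poisson log-likelihood, exactly.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    beta = np.asarray(beta, float)
    eta_fixed = X @ beta
    const = float(np.sum(y * eta_fixed) - np.sum(gammaln(y + 1)))
    if sigma2 == 0.0:
        return const - float(np.sum(np.exp(eta_fixed)))

    site_idx, n_sites, y_sums = _prep(y, X, sites)
    u_hat, curv = _site_modes(eta_fixed, y_sums, site_idx, n_sites, sigma2, u0)

    def h_per_site(u_by_site: np.ndarray) -> np.ndarray:
        """h_i(u_i) = conditional Poisson loglik + Normal(0, sigma2) log-density,
        minus the beta-only part already in ``const`` (added back by caller)."""
        mu_sums = np.bincount(site_idx, weights=np.exp(eta_fixed + u_by_site[site_idx]),
                              minlength=n_sites)
        return (
            y_sums * u_by_site
            - mu_sums
            - u_by_site**2 / (2.0 * sigma2)
            - 0.5 * math.log(2.0 * math.pi * sigma2)
        )

    if method == "laplace":
        h_hat = h_per_site(u_hat)
        return const + float(np.sum(h_hat + 0.5 * np.log(2.0 * np.pi / curv)))
    if method == "quadrature":
        nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
        tau = 1.0 / np.sqrt(curv)  # adaptive scale per site
        # log integral_i = log sum_k w_k exp(h_i(u) + x_k^2) + log(sqrt(2) tau_i)
        terms = np.empty((n_quad, n_sites))
        for k, (x_k, w_k) in enumerate(zip(nodes, weights)):
            u_k = u_hat + math.sqrt(2.0) * tau * x_k
            terms[k] = h_per_site(u_k) + x_k**2 + math.log(w_k)
        per_site = logsumexp(terms, axis=0) + np.log(math.sqrt(2.0) * tau)
        return const + float(np.sum(per_site))
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# fitting


def fit_poisson_glmm(
    data: SiteCounts | pd.DataFrame,
    covariates: list[str] | None = None,
    method: str = "laplace",
) -> GlmmFit:
    """Maximize the (Laplace) marginal likelihood of the random-intercept model.

    ``data`` is a :class:`SiteCounts` or a data frame with columns ``site``,
    ``y`` and the covariates.  Initialization: beta from the fixed-effects
    Poisson GLM, sigma2 = 0.1; optimization is quasi-Newton on
    (beta, log sigma2).  Requires >= 5 sites and a full-rank design.
    """
    if isinstance(data, SiteCounts):
        frame = data.frame
        covariates = data.covariates if covariates is None else covariates
    else:
        frame = data
        if covariates is None:
            covariates = [c for c in frame.columns if c not in ("site", "unit", "y")]
    y = frame["y"].to_numpy(float)
    X = np.column_stack([np.ones(len(frame))] +
                        [frame[c].to_numpy(float) for c in covariates])
    sites = frame["site"].to_numpy()
    names = ["intercept", *covariates]

    n_sites = len(np.unique(sites))
    if n_sites < 5:
        raise ValueError(f"need >= 5 sites, got {n_sites}")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient")

    messages: list[str] = []
    for c in covariates:
        if (frame[c].to_numpy() == 0).all():
            messages.append(f"covariate {c!r} is all zero: coefficient unidentified")

    # fixed-effects Poisson GLM start values
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit(maxiter=200)
    beta0 = np.asarray(glm.params, float)
    beta0 = np.clip(beta0, -20.0, 20.0)  # separation can push the GLM to the rail

    site_idx, n_sites_, y_sums = _prep(y, X, sites)
    warm_u = {"u": np.zeros(n_sites_)}

    def negloglik(theta: np.ndarray) -> float:
        beta, sigma2 = theta[:-1], math.exp(theta[-1])
        eta_fixed = X @ beta
        u_hat, curv = _site_modes(eta_fixed, y_sums, site_idx, n_sites_, sigma2,
                                  warm_u["u"])
        warm_u["u"] = u_hat
        mu_sums = np.bincount(site_idx, weights=np.exp(eta_fixed + u_hat[site_idx]),
                              minlength=n_sites_)
        const = float(np.sum(y * eta_fixed) - np.sum(gammaln(y + 1)))
        h_hat = (y_sums * u_hat - mu_sums - u_hat**2 / (2.0 * sigma2)
                 - 0.5 * math.log(2.0 * math.pi * sigma2))
        ll = const + float(np.sum(h_hat + 0.5 * np.log(2.0 * np.pi / curv)))
        return -ll

    theta0 = np.append(beta0, math.log(0.1))
    # log sigma2 is bounded below so that a zero-variance fit terminates
    # cleanly at the boundary instead of drifting toward -infinity
    bounds = [(None, None)] * len(beta0) + [(math.log(1e-8), math.log(1e3))]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = minimize(negloglik, theta0, method="L-BFGS-B", bounds=bounds,
                       options={"gtol": _GRAD_TOL, "ftol": 1e-12, "maxiter": 500})
    theta = res.x
    beta_hat, sigma2_hat = theta[:-1], math.exp(theta[-1])
    grad_norm = float(np.max(np.abs(res.jac[:-1])))  # beta block; the variance
    # gradient is judged by the optimizer itself (it may sit on the boundary)
    converged = bool(res.success) or grad_norm < 1e-4
    if not converged:
        messages.append(f"optimizer did not converge: {res.message}")

    # observed information from a central-difference Hessian of the marginal
    # log-likelihood over (beta, log sigma2); SEs for beta from its block
    p = len(beta_hat)
    se = np.full(p, np.nan)
    at_boundary = theta[-1] <= math.log(1e-8) + 1e-6
    if not at_boundary:
        hess = _fd_hessian(negloglik, theta)
        try:
            cov = np.linalg.inv(hess)
            diag = np.diag(cov)[:p]
            with np.errstate(invalid="ignore"):
                se = np.sqrt(np.where(diag > 0, diag, np.nan))
        except np.linalg.LinAlgError:
            messages.append("singular information matrix: SEs unavailable")
    if np.any(~np.isfinite(se)):
        # fall back to the beta-block information at fixed variance
        hess_b = _fd_hessian(lambda b: negloglik(np.append(b, theta[-1])), beta_hat)
        try:
            diag = np.diag(np.linalg.inv(hess_b))
            bad = ~np.isfinite(se)
            with np.errstate(invalid="ignore"):
                se[bad] = np.sqrt(np.where(diag > 0, diag, np.nan))[bad]
        except np.linalg.LinAlgError:
            pass
    for nm, s in zip(names, se):
        if np.isfinite(s) and s > _SE_PATHOLOGY:
            messages.append(
                f"coefficient {nm!r}: SE {s:.1f} indicates separation "
                "(covariate never co-occurs with positive responses)")
    for m in messages:
        logger.warning(m)
    return GlmmFit(names=names, beta=beta_hat, se=se, sigma2=float(sigma2_hat),
                   loglik=float(-res.fun), converged=converged,
                   grad_norm=grad_norm, n_obs=len(y), n_sites=n_sites_,
                   messages=messages)


def _fd_hessian(fun, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian; symmetrized."""
    x = np.asarray(x, float)
    n = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    hess = np.empty((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                xp, xm = x.copy(), x.copy()
                xp[i] += h[i]
                xm[i] -= h[i]
                hess[i, i] = (fun(xp) - 2.0 * f0 + fun(xm)) / h[i] ** 2
            else:
                xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
                xpp[[i, j]] += [h[i], h[j]]
                xpm[i] += h[i]
                xpm[j] -= h[j]
                xmp[i] -= h[i]
                xmp[j] += h[j]
                xmm[[i, j]] -= [h[i], h[j]]
                hess[i, j] = hess[j, i] = (
                    fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)
                ) / (4.0 * h[i] * h[j])
    return hess
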