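import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dielclass as dc

from conftest import make_events


def simulate_glmm(seed, n_sites=50, n_units=30, beta0=-2.0, beta1=0.8, sigma2=0.5):
    """Draw from the model itself: site intercepts, Poisson covariate, Poisson response."""
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, math.sqrt(sigma2), n_sites)
    x = rng.poisson(1.0, (n_sites, n_units)).astype(float)
    y = rng.poisson(np.exp(beta0 + beta1 * x + u[:, None]))
    return pd.DataFrame({
        "site": np.repeat(np.arange(n_sites), n_units),
        "y": y.ravel(),
        "x": x.ravel(),
    })


@pytest.fixture(scope="module")
def ten_site_fixture():
    return simulate_glmm(seed=42, n_sites=10, n_units=20)


def design_of(frame, covariates=("x",)):
    X = np.column_stack([np.ones(len(frame))] + [frame[c].to_numpy(float) for c in covariates])
    return frame["y"].to_numpy(float), X, frame["site"].to_numpy()


class TestAggregateSiteCounts:
    EFFORT = dc.EffortLedger({f"C{i}": [(dt.date(2013, 5, 1), dt.date(2013, 5, 3))]
                              for i in range(1, 6)})
    EVENTS = make_events([
        ("C1", "hare", "2013-05-01 22:00"),
        ("C1", "hare", "2013-05-01 23:00"),
        ("C1", "marten", "2013-05-01 21:00"),
        ("C2", "fox", "2013-05-02 03:00"),
        ("C1", "deer", "2013-05-01 12:00"),  # not listed: ignored
    ])

    def test_direct_daily_counts(self):
        sc = dc.aggregate_site_counts(self.EVENTS, "hare", ["marten", "fox"], self.EFFORT)
        row = sc.frame.set_index(["site", "unit"]).loc[("C1", "2013-05-01")]
        assert (row["y"], row["marten"], row["fox"]) == (2, 1, 0)
        # zeros kept: 5 sites x 3 days
        assert len(sc.frame) == 15

    def test_season_total_collapses_to_per_site_sums(self):
        sc = dc.aggregate_site_counts(self.EVENTS, "hare", ["marten", "fox"],
                                      self.EFFORT, unit="season-total")
        assert len(sc.frame) == 5
        assert sc.frame.set_index("site")["y"]["C1"] == 2
        assert sc.frame["y"].sum() == 2

    def test_unknown_unit_rejected(self):
        with pytest.raises(ValueError):
            dc.aggregate_site_counts(self.EVENTS, "hare", [], self.EFFORT, unit="month")

    def test_out_of_season_events_excluded(self):
        sc = dc.aggregate_site_counts(self.EVENTS, "hare", ["marten"], self.EFFORT,
                                      season="winter")
        assert sc.frame.empty


class TestMarginalLoglik:
    def test_sigma_zero_is_plain_poisson(self, ten_site_fixture):
        y, X, sites = design_of(ten_site_fixture)
        beta = np.array([-2.0, 0.5])
        ll = dc.glmm_marginal_loglik(beta, 0.0, y, X, sites)
        mu = np.exp(X @ beta)
        assert ll == pytest.approx(stats.poisson.logpmf(y, mu).sum(), rel=1e-12)

    def test_laplace_close_to_quadrature(self, ten_site_fixture):
        y, X, sites = design_of(ten_site_fixture)
        beta = np.array([-2.0, 0.7])
        for s2 in (0.1, 0.5, 2.0):
            lap = dc.glmm_marginal_loglik(beta, s2, y, X, sites, "laplace")
            agq = dc.glmm_marginal_loglik(beta, s2, y, X, sites, "quadrature")
            assert abs(lap - agq) / abs(agq) < 1e-3

    def test_loglik_peaks_at_the_optimum(self, ten_site_fixture):
        fit = dc.fit_poisson_glmm(ten_site_fixture, covariates=["x"])
        y, X, sites = design_of(ten_site_fixture)
        ll_hat = dc.glmm_marginal_loglik(fit.beta, fit.sigma2, y, X, sites)
        for delta in ([0.05, 0], [0, 0.05], [-0.05, 0.05]):
            assert dc.glmm_marginal_loglik(fit.beta + delta, fit.sigma2, y, X, sites) < ll_hat

    def test_negative_variance_rejected(self, ten_site_fixture):
        y, X, sites = design_of(ten_site_fixture)
        with pytest.raises(ValueError):
            dc.glmm_marginal_loglik(np.array([0.0, 0.0]), -1.0, y, X, sites)


class TestFitPoissonGlmm:
    def test_intercept_only_no_heterogeneity_is_log_mean(self):
        rng = np.random.default_rng(3)
        frame = pd.DataFrame({
            "site": np.repeat(np.arange(20), 25),
            "y": rng.poisson(1.5, 500),
        })
        fit = dc.fit_poisson_glmm(frame, covariates=[])
        # planted sigma2 = 0: the variance collapses and beta0 -> log(mean)
        assert fit.sigma2 < 0.02
        assert fit.beta[0] == pytest.approx(math.log(frame["y"].mean()), abs=0.02)

    def test_collapses_to_poisson_glm_when_variance_vanishes(self):
        rng = np.random.default_rng(4)
        x = rng.poisson(1.0, 600).astype(float)
        frame = pd.DataFrame({
            "site": np.repeat(np.arange(20), 30),
            "y": rng.poisson(np.exp(-1.0 + 0.5 * x)),
            "x": x,
        })
        import statsmodels.api as sm
        from scipy.optimize import minimize

        X = np.column_stack([np.ones(len(frame)), x])
        y, sites = frame["y"].to_numpy(float), frame["site"].to_numpy()
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        # the sigma2 -> 0 limit: maximizing the marginal likelihood with the
        # variance pinned at the boundary recovers the plain Poisson GLM
        res = minimize(
            lambda b: -dc.glmm_marginal_loglik(b, 1e-10, y, X, sites),
            np.zeros(2), method="BFGS", options={"gtol": 1e-10},
        )
        assert np.allclose(res.x, glm.params, atol=1e-4)
        # and the free fit on zero-heterogeneity data sits close to the GLM,
        # with a near-zero variance estimate
        fit = dc.fit_poisson_glmm(frame, covariates=["x"])
        assert fit.sigma2 < 0.01
        assert np.allclose(fit.beta, glm.params, atol=0.01)

    def test_parameter_recovery(self):
        frame = simulate_glmm(seed=7)
        fit = dc.fit_poisson_glmm(frame, covariates=["x"])
        assert fit.converged
        assert fit.beta[0] == pytest.approx(-2.0, abs=3 * 0.13)
        assert fit.beta[1] == pytest.approx(0.8, abs=3 * 0.04)
        assert fit.sigma2 == pytest.approx(0.5, abs=0.35)

    def test_wald_z_and_p_consistent(self):
        fit = dc.fit_poisson_glmm(simulate_glmm(seed=9, n_sites=15, n_units=15),
                                  covariates=["x"])
        assert np.all(np.sign(fit.z) == np.sign(fit.beta))
        assert np.allclose(fit.p, 2 * stats.norm.sf(np.abs(fit.z)))

    def test_all_zero_covariate_flagged_as_separation(self):
        frame = simulate_glmm(seed=11, n_sites=12, n_units=10, beta1=0.0)
        frame["ghost"] = 0.0
        frame.loc[frame.index[:5], "ghost"] = 1.0  # present only where y happens to be 0
        frame.loc[frame.index[:5], "y"] = 0
        fit = dc.fit_poisson_glmm(frame, covariates=["x", "ghost"])
        ghost_se = fit.se[fit.names.index("ghost")]
        assert (not np.isfinite(ghost_se)) or ghost_se > 5 or fit.messages

    def test_too_few_sites_rejected(self):
        frame = simulate_glmm(seed=1, n_sites=3, n_units=10)
        with pytest.raises(ValueError, match="sites"):
            dc.fit_poisson_glmm(frame, covariates=["x"])

    def test_rank_deficient_design_rejected(self):
        frame = simulate_glmm(seed=2, n_sites=8, n_units=10)
        frame["x2"] = 2.0 * frame["x"]
        with pytest.raises(ValueError, match="rank"):
            dc.fit_poisson_glmm(frame, covariates=["x", "x2"])
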