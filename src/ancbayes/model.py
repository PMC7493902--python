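"""Survey-weighted random-intercept logistic regression.

The model for woman i in cluster j is

    logit P(y_ij = 1 | u_j) = x_ij' beta + u_j,   u_j ~ Normal(0, sigma_u^2),

with survey weights entering as a pseudo-likelihood: each woman's
log-likelihood contribution is multiplied by her normalised weight (weights
rescaled to sum to the sample size) inside the cluster-level integral.

Estimation is statsmodels-style:

* :class:`MultilevelLogit` holds the data and the marginal weighted
  log-likelihood, computed by adaptive Gauss-Hermite quadrature (nodes
  centred and scaled at each cluster's conditional mode).
* :meth:`MultilevelLogit.fit` maximises it, returning
  :class:`MultilevelLogitResults` (coefficients, sigma_u^2, log-likelihood,
  AIC/BIC, latent-scale ICC).
* :meth:`MultilevelLogit.fit_bayes` samples the posterior under independent
  normal priors on beta (a :class:`~ancbayes.priors.PriorSpec`) and a
  half-normal prior on sigma_u, using random-walk Metropolis on the
  quadrature-integrated marginal posterior with a Laplace-approximation
  proposal.  Chains start from jittered maximum-likelihood estimates.
* :func:`exact_grid_posterior` is a deterministic quadrature oracle for tiny
  models (at most two free parameters), used to validate the sampler.
"""

from __future__ import annotations

import logging
import warnings

from functools import lru_cache

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize

import statsmodels.api as sm

from .priors import PriorSpec
from .terms import build_design

__all__ = ["MultilevelLogit", "MultilevelLogitResults", "BayesianResults",
           "exact_grid_posterior"]

log = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))


@lru_cache(maxsize=8)
def _gh_nodes(nodes: int):
    t, om = hermgauss(nodes)
    return t, np.log(om) + t ** 2


class MultilevelLogit:
    """Random-intercept logistic model for clustered, weighted survey data."""

    def __init__(self, endog, exog, groups, weights=None, exog_names=None):
        y = np.asarray(endog, dtype=float)
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if not np.all(np.isin(y, (0.0, 1.0))):
            raise ValueError("outcome must be binary 0/1")
        if y.min() == y.max():
            raise ValueError("outcome has a single class; model not estimable")
        codes, uniques = pd.factorize(np.asarray(groups))
        if len(uniques) < 2:
            raise ValueError("need at least two clusters")
        w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")
        # store rows sorted by cluster so per-cluster sums can use reduceat
        order = np.argsort(codes, kind="stable")
        self.endog = y[order]
        self.exog = X[order]
        self.group_codes = codes[order]
        self.n_groups = len(uniques)
        self._group_starts = np.searchsorted(self.group_codes,
                                             np.arange(self.n_groups))
        self.weights = (w * (len(y) / w.sum()))[order]   # pseudo-likelihood normalisation
        self.exog_names = list(exog_names) if exog_names is not None else \
            [f"x{i}" for i in range(X.shape[1])]
        if len(self.exog_names) != X.shape[1]:
            raise ValueError("exog_names length mismatch")
        self.nobs = len(y)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str, terms,
                       cluster_col: str = "cluster_id", weight_col: str = "weight"):
        """Build the model from a derived analysis table and a term list."""
        X, names = build_design(df, terms)
        weights = df[weight_col].to_numpy(dtype=float) if weight_col in df.columns else None
        return cls(df[outcome].to_numpy(dtype=float), X, df[cluster_col].to_numpy(),
                   weights=weights, exog_names=names)

    # ----- marginal likelihood -------------------------------------------

    def _cluster_modes(self, eta_fix: np.ndarray, sigma_u: float,
                       tol: float = 1e-10, max_iter: int = 60):
        """Per-cluster modes of the integrand and their negative curvatures.

        Newton iteration from u = 0; the integrand is log-concave in u so
        this is globally convergent (steps damped to +-4 for safety).
        """
        c = self.group_codes
        w, y = self.weights, self.endog
        u = np.zeros(self.n_groups)
        inv_s2 = 1.0 / (sigma_u * sigma_u)
        for _ in range(max_iter):
            eta = eta_fix + u[c]
            p = 1.0 / (1.0 + np.exp(-eta))
            grad = np.bincount(c, w * (y - p), minlength=self.n_groups) - u * inv_s2
            hess = np.bincount(c, w * p * (1.0 - p), minlength=self.n_groups) + inv_s2
            step = grad / hess
            np.clip(step, -4.0, 4.0, out=step)
            u += step
            if np.max(np.abs(step)) < tol:
                break
        eta = eta_fix + u[c]
        p = 1.0 / (1.0 + np.exp(-eta))
        curv = np.bincount(c, w * p * (1.0 - p), minlength=self.n_groups) + inv_s2
        return u, curv

    def loglike(self, beta, sigma_u, nodes: int = 9) -> float:
        """Weighted marginal log-likelihood, adaptive Gauss-Hermite."""
        beta = np.asarray(beta, dtype=float)
        eta_fix = self.exog @ beta
        w, y, c = self.weights, self.endog, self.group_codes
        if sigma_u < 1e-10:
            ll = w * (y * eta_fix - np.logaddexp(0.0, eta_fix))
            return float(ll.sum())
        u_hat, curv = self._cluster_modes(eta_fix, sigma_u)
        tau = 1.0 / np.sqrt(curv)
        t, log_om_t2 = _gh_nodes(nodes)
        # candidate points: (J, K)
        U = u_hat[:, None] + np.sqrt(2.0) * tau[:, None] * t[None, :]
        eta = eta_fix[:, None] + U[c, :]
        ll_rows = w[:, None] * (y[:, None] * eta - np.logaddexp(0.0, eta))
        g = np.add.reduceat(ll_rows, self._group_starts, axis=0)
        g += -0.5 * U * U / (sigma_u * sigma_u) - np.log(sigma_u) - 0.5 * _LOG_2PI
        g += log_om_t2[None, :]
        gmax = g.max(axis=1)
        ll_j = gmax + np.log(np.exp(g - gmax[:, None]).sum(axis=1))
        ll_j += 0.5 * np.log(2.0) + np.log(tau)
        return float(ll_j.sum())

    # ----- maximum likelihood --------------------------------------------

    def _start_params(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(self.endog, self.exog, family=sm.families.Binomial(),
                         var_weights=self.weights).fit(maxiter=200)
        return np.asarray(glm.params, dtype=float)

    def fit(self, fix_sigma_u: float | None = None, nodes: int = 9,
            start_params=None, maxiter: int = 500) -> "MultilevelLogitResults":
        """Maximise the weighted marginal likelihood.

        ``fix_sigma_u`` pins the random-intercept SD (0 gives ordinary
        weighted logistic regression).  Complete separation is reported via
        a warning and the ``separation_suspected`` flag, never silently
        "fixed".
        """
        p = self.exog.shape[1]
        beta0 = np.asarray(start_params, dtype=float) if start_params is not None \
            else self._start_params()
        if fix_sigma_u is None:
            theta0 = np.append(beta0, 0.5)
            bounds = [(None, None)] * p + [(0.0, None)]

            def nll(theta):
                return -self.loglike(theta[:p], theta[p], nodes=nodes)
        else:
            if fix_sigma_u < 0:
                raise ValueError("sigma_u must be non-negative")
            theta0 = beta0
            bounds = [(None, None)] * p

            def nll(theta):
                return -self.loglike(theta, fix_sigma_u, nodes=nodes)

        res = optimize.minimize(nll, theta0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": maxiter, "ftol": 1e-12,
                                         "gtol": 1e-8})
        beta_hat = res.x[:p]
        sigma_hat = float(res.x[p]) if fix_sigma_u is None else float(fix_sigma_u)
        separation = bool(np.any(np.abs(beta_hat) > 15.0))
        if separation:
            warnings.warn("complete or quasi-complete separation suspected: "
                          "some |coefficient| > 15 on the logit scale",
                          RuntimeWarning, stacklevel=2)
        return MultilevelLogitResults(
            model=self, params=beta_hat, sigma_u=sigma_hat, llf=-float(res.fun),
            converged=bool(res.success), separation_suspected=separation,
            optimizer_result=res, sigma_u_fixed=fix_sigma_u is not None)

    # ----- Bayesian fit ----------------------------------------------------

    def _log_posterior_factory(self, prior_mean, prior_var, sigma_u_prior_scale,
                               nodes, fix_sigma_u=None):
        p = self.exog.shape[1]
        s2 = 2.0 * sigma_u_prior_scale ** 2

        def log_post(theta):
            sigma = theta[p] if fix_sigma_u is None else fix_sigma_u
            if sigma < 0.0:
                return -np.inf
            lp = -0.5 * np.sum((theta[:p] - prior_mean) ** 2 / prior_var)
            if fix_sigma_u is None:
                lp -= sigma * sigma / s2    # half-normal on sigma_u
            return lp + self.loglike(theta[:p], sigma, nodes=nodes)

        return log_post

    def fit_bayes(self, prior: PriorSpec, n_chains: int = 3, n_burnin: int = 5000,
                  n_kept: int = 10000, seed: int = 0, nodes: int = 7,
                  sigma_u_prior_scale: float = 5.0, ml_results=None,
                  thin: int = 1, fix_sigma_u: float | None = None) -> "BayesianResults":
        """Posterior sampling by random-walk Metropolis on (beta, sigma_u).

        The proposal is a fixed multivariate normal whose covariance is the
        Laplace approximation at the ML fit scaled by 2.38^2/d; its overall
        scale is tuned toward 23% acceptance during burn-in only, so the kept
        draws come from a valid fixed-kernel chain.
        """
        if n_chains < 1 or n_burnin < 0 or n_kept < 1:
            raise ValueError("chain settings must be positive")
        p = self.exog.shape[1]
        prior_mean, prior_var = prior.moments(self.exog_names)
        if ml_results is None:
            ml_results = self.fit(nodes=nodes, fix_sigma_u=fix_sigma_u)
        d = p + (1 if fix_sigma_u is None else 0)
        if fix_sigma_u is None:
            theta_hat = np.append(ml_results.params, max(ml_results.sigma_u, 0.05))
            cov = ml_results.cov_params_approx()
        else:
            theta_hat = np.asarray(ml_results.params, dtype=float)
            cov = ml_results.cov_params_approx()[:p, :p]
        scale = 2.38 / np.sqrt(d)
        chol = np.linalg.cholesky(cov * scale ** 2)
        log_post = self._log_posterior_factory(prior_mean, prior_var,
                                               sigma_u_prior_scale, nodes,
                                               fix_sigma_u=fix_sigma_u)

        root = np.random.SeedSequence(seed)
        chains = np.empty((n_chains, n_kept, d))
        accept = np.empty(n_chains)
        for ci, ss in enumerate(root.spawn(n_chains)):
            rng = np.random.default_rng(ss)
            theta = theta_hat + 0.1 * chol @ rng.standard_normal(d)
            if fix_sigma_u is None:
                theta[p] = abs(theta[p])
            lp = log_post(theta)
            step = 1.0
            n_acc_tune = 0
            for it in range(n_burnin):
                prop = theta + step * chol @ rng.standard_normal(d)
                lp_prop = log_post(prop)
                if np.log(rng.random()) < lp_prop - lp:
                    theta, lp = prop, lp_prop
                    n_acc_tune += 1
                if (it + 1) % 200 == 0:        # burn-in-only scale tuning
                    rate = n_acc_tune / 200.0
                    step *= np.exp(rate - 0.234)
                    n_acc_tune = 0
            n_acc = 0
            total = n_kept * thin
            kept = 0
            for it in range(total):
                prop = theta + step * chol @ rng.standard_normal(d)
                lp_prop = log_post(prop)
                if np.log(rng.random()) < lp_prop - lp:
                    theta, lp = prop, lp_prop
                    n_acc += 1
                if (it + 1) % thin == 0:
                    chains[ci, kept] = theta
                    kept += 1
            accept[ci] = n_acc / total
        log.info("MCMC finished: %d chains x %d draws, acceptance %s",
                 n_chains, n_kept, np.round(accept, 3))
        names = self.exog_names + (["sigma_u"] if fix_sigma_u is None else [])
        return BayesianResults(model=self, chains=chains, param_names=names,
                               prior=prior, seed=seed, acceptance=accept,
                               n_burnin=n_burnin, ml_results=ml_results,
                               fixed_sigma_u=fix_sigma_u)


class MultilevelLogitResults:
    """Maximum-likelihood fit: estimates, information criteria, latent ICC."""

    def __init__(self, model, params, sigma_u, llf, converged,
                 separation_suspected, optimizer_result=None, sigma_u_fixed=False):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.sigma_u = float(sigma_u)
        self.sigma_u2 = float(sigma_u) ** 2
        self.llf = float(llf)
        self.converged = converged
        self.separation_suspected = separation_suspected
        self.sigma_u_fixed = sigma_u_fixed
        self._opt = optimizer_result
        # variance parameter counts toward k unless it was pinned
        self.k_params = len(self.params) + (0 if sigma_u_fixed else 1)
        self.nobs = model.nobs

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.k_params

    @property
    def bic(self) -> float:
        return -2.0 * self.llf + self.k_params * np.log(self.nobs)

    @property
    def icc(self) -> float:
        from .diagnostics import icc_latent
        return icc_latent(self.sigma_u2)

    def params_dict(self) -> dict[str, float]:
        return dict(zip(self.model.exog_names, self.params))

    def cov_params_approx(self, rel_step: float = 1e-4) -> np.ndarray:
        """Laplace covariance of (beta, sigma_u) by finite-difference Hessian.

        Used as the Metropolis proposal covariance; eigenvalues are clipped
        so the result is always a usable positive-definite matrix even when
        sigma_u sits on the boundary.
        """
        p = len(self.params)
        theta = np.append(self.params, max(self.sigma_u, 0.05))

        def nll(th):
            return -self.model.loglike(th[:p], max(th[p], 0.0))

        d = p + 1
        h = rel_step * np.maximum(np.abs(theta), 1.0)
        H = np.empty((d, d))
        f0 = nll(theta)
        fp = np.empty(d)
        fm = np.empty(d)
        for i in range(d):
            e = np.zeros(d); e[i] = h[i]
            fp[i] = nll(theta + e)
            fm[i] = nll(theta - e)
            H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h[i] ** 2
        for i in range(d):
            for j in range(i + 1, d):
                ei = np.zeros(d); ei[i] = h[i]
                ej = np.zeros(d); ej[j] = h[j]
                fpp = nll(theta + ei + ej)
                fmm = nll(theta - ei - ej)
                H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + 2.0 * f0
                                     - fm[i] - fm[j] + fmm) / (2.0 * h[i] * h[j])
        H = 0.5 * (H + H.T)
        evals, evecs = np.linalg.eigh(H)
        evals = np.clip(evals, 1e-6, None)
        cov = (evecs / evals) @ evecs.T
        sd = np.sqrt(np.diag(cov))
        clip = np.clip(sd, 1e-3, 5.0) / sd
        return cov * np.outer(clip, clip)

    def bse(self) -> np.ndarray:
        """Approximate standard errors of the fixed effects."""
        return np.sqrt(np.diag(self.cov_params_approx())[:len(self.params)])

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame({"coef": self.params,
                           "odds_ratio": np.exp(self.params)},
                          index=self.model.exog_names)
        df.loc["sigma_u^2", "coef"] = self.sigma_u2
        return df

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<MultilevelLogitResults llf={self.llf:.3f} "
                f"sigma_u2={self.sigma_u2:.4f} k={self.k_params} n={self.nobs}>")


class BayesianResults:
    """Posterior draws and their survey-report summaries."""

    def __init__(self, model, chains, param_names, prior, seed, acceptance,
                 n_burnin, ml_results=None, fixed_sigma_u=None):
        chains = np.asarray(chains, dtype=float)
        if chains.ndim != 3 or chains.shape[1] == 0:
            raise ValueError("chains must be (n_chains, n_draws, n_params) and non-empty")
        self.model = model
        self.chains = chains
        self.param_names = list(param_names)
        self.prior = prior
        self.seed = seed
        self.acceptance = np.asarray(acceptance, dtype=float)
        self.n_burnin = n_burnin
        self.ml_results = ml_results
        self.fixed_sigma_u = fixed_sigma_u

    @property
    def n_chains(self) -> int:
        return self.chains.shape[0]

    @property
    def n_kept(self) -> int:
        return self.chains.shape[1]

    def pooled(self, name: str) -> np.ndarray:
        idx = self.param_names.index(name)
        return self.chains[:, :, idx].reshape(-1)

    def posterior_mean(self) -> dict[str, float]:
        means = self.chains.reshape(-1, self.chains.shape[2]).mean(axis=0)
        return dict(zip(self.param_names, means))

    def posterior_sd(self) -> dict[str, float]:
        sds = self.chains.reshape(-1, self.chains.shape[2]).std(axis=0, ddof=1)
        return dict(zip(self.param_names, sds))

    @property
    def sigma_u2_mean(self) -> float:
        if self.fixed_sigma_u is not None:
            return float(self.fixed_sigma_u) ** 2
        return float(np.mean(self.pooled("sigma_u") ** 2))

    @property
    def icc(self) -> float:
        from .diagnostics import icc_latent
        return icc_latent(self.sigma_u2_mean)

    def gelman_rubin(self) -> dict[str, float]:
        from .diagnostics import gelman_rubin
        return {name: gelman_rubin(self.chains[:, :, i])
                for i, name in enumerate(self.param_names)}

    def converged(self, threshold: float = 1.1) -> bool:
        return max(self.gelman_rubin().values()) < threshold

    def odds_ratios(self) -> pd.DataFrame:
        """OR point estimates (mean of exp(beta)) with equal-tailed 95%
        credible intervals from the pooled draws."""
        rows = []
        for i, name in enumerate(self.param_names):
            if name == "sigma_u":
                continue
            draws = np.exp(self.chains[:, :, i].reshape(-1))
            lo, hi = np.percentile(draws, [2.5, 97.5])
            rows.append({"term": name, "or": float(draws.mean()),
                         "or_lower": float(lo), "or_upper": float(hi)})
        return pd.DataFrame(rows).set_index("term")

    def summary(self) -> pd.DataFrame:
        """Posterior mean/SD of beta alongside OR and credible interval."""
        means = self.posterior_mean()
        sds = self.posterior_sd()
        ors = self.odds_ratios()
        rows = []
        for name in self.param_names:
            row = {"term": name, "mean": means[name], "sd": sds[name]}
            if name in ors.index:
                row.update({"or": ors.loc[name, "or"],
                            "or_lower": ors.loc[name, "or_lower"],
                            "or_upper": ors.loc[name, "or_upper"]})
            rows.append(row)
        return pd.DataFrame(rows).set_index("term")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<BayesianResults {self.n_chains} chains x {self.n_kept} draws, "
                f"{len(self.param_names)} params, seed={self.seed}>")


def summarize(results: BayesianResults) -> pd.DataFrame:
    """Module-level alias for :meth:`BayesianResults.summary`."""
    return results.summary()


def exact_grid_posterior(model: MultilevelLogit, prior: PriorSpec, free,
                         fixed=None, sigma_u: float = 0.0,
                         sigma_u_prior_scale: float = 5.0,
                         n_points: int = 4001, bounds=None):
    """Deterministic trapezoid-grid posterior for tiny models.

    ``free`` names at most two free parameters (coefficient names and/or
    ``"sigma_u"``); all other coefficients are pinned at ``fixed`` (default
    0) and sigma_u at ``sigma_u``.  ``n_points`` is the grid size per free
    dimension.  Returns ``(moments, tol)`` where ``moments`` maps each free
    parameter to ``(mean, sd)`` and ``tol`` is a grid-halving error estimate
    on the means.
    """
    free = list(free)
    if len(free) == 0 or len(free) > 2:
        raise ValueError("exact_grid_posterior supports 1 or 2 free parameters")
    if model.nobs > 200:
        raise ValueError("grid oracle is restricted to <= 200 observations")
    fixed = dict(fixed or {})
    names = model.exog_names
    prior_mean, prior_var = prior.moments(names)

    if bounds is None:
        bounds = {}
    if len(free) == 2:
        n_points = min(n_points, 401)
    grids = []
    for f in free:
        lo, hi = bounds.get(f, (0.0, 5.0) if f == "sigma_u" else (-10.0, 10.0))
        grids.append(np.linspace(lo, hi, n_points | 1))

    def log_post_at(values):
        beta = np.array([fixed.get(nm, 0.0) for nm in names], dtype=float)
        s = sigma_u
        for f, v in zip(free, values):
            if f == "sigma_u":
                s = v
            else:
                beta[names.index(f)] = v
        lp = -0.5 * np.sum((beta - prior_mean) ** 2 / prior_var)
        if s < 0:
            return -np.inf
        lp -= s * s / (2.0 * sigma_u_prior_scale ** 2)
        return lp + model.loglike(beta, s)

    def moments_on(grids_):
        if len(free) == 1:
            g = grids_[0]
            lp = np.array([log_post_at((v,)) for v in g])
            lp -= lp.max()
            dens = np.exp(lp)
            Z = np.trapezoid(dens, g)
            mean = np.trapezoid(g * dens, g) / Z
            var = np.trapezoid((g - mean) ** 2 * dens, g) / Z
            return {free[0]: (float(mean), float(np.sqrt(var)))}
        g1, g2 = grids_
        lp = np.array([[log_post_at((a, b)) for b in g2] for a in g1])
        lp -= lp.max()
        dens = np.exp(lp)
        Z = np.trapezoid(np.trapezoid(dens, g2, axis=1), g1)
        out = {}
        m1 = np.trapezoid(np.trapezoid(dens * g1[:, None], g2, axis=1), g1) / Z
        v1 = np.trapezoid(np.trapezoid(dens * (g1[:, None] - m1) ** 2, g2, axis=1), g1) / Z
        out[free[0]] = (float(m1), float(np.sqrt(v1)))
        m2 = np.trapezoid(np.trapezoid(dens * g2[None, :], g2, axis=1), g1) / Z
        v2 = np.trapezoid(np.trapezoid(dens * (g2[None, :] - m2) ** 2, g2, axis=1), g1) / Z
        out[free[1]] = (float(m2), float(np.sqrt(v2)))
        return out

    full = moments_on(grids)
    half = moments_on([g[::2] for g in grids])
    tol = max(abs(full[f][0] - half[f][0]) for f in free)
    return full, tol
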