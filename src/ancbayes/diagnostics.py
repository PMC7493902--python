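"""Convergence, variance-decomposition and model-comparison diagnostics.

* ``icc_latent`` — intra-class correlation on the latent logistic scale,
  sigma_u^2 / (sigma_u^2 + pi^2/3): the share of unexplained outcome
  variation attributable to clusters, using the standard latent-threshold
  residual variance pi^2/3 of the logistic distribution.
* ``gelman_rubin`` — the potential scale reduction factor Rc comparing
  between- and within-chain variance, with the usual finite-sample
  correction; chains with Rc < 1.1 for every parameter are flagged
  converged.
* ``model_sequence`` — the null / M1 / M2 / M3 ladder: cluster-intercept
  only, individual+household factors, community factors only, and all
  factors, tabulating AIC, BIC (from the maximum-likelihood fit), latent
  ICC, and the worst Gelman-Rubin Rc of the Bayesian fit.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .model import MultilevelLogit
from .priors import PriorSpec, noninformative_prior
from .terms import COMMUNITY_TERMS, INDIVIDUAL_TERMS, coefficient_names

__all__ = ["icc_latent", "gelman_rubin", "model_sequence", "MODEL_TERMS",
           "LATENT_RESIDUAL_VARIANCE"]

log = logging.getLogger(__name__)

LATENT_RESIDUAL_VARIANCE = np.pi ** 2 / 3.0

MODEL_TERMS: dict[str, tuple[str, ...]] = {
    "M0": (),
    "M1": INDIVIDUAL_TERMS,
    "M2": COMMUNITY_TERMS,
    "M3": INDIVIDUAL_TERMS + COMMUNITY_TERMS,
}


def icc_latent(sigma_u2: float) -> float:
    """Latent-scale intra-class correlation of the multilevel logit model."""
    if sigma_u2 < 0:
        raise ValueError("variance must be non-negative")
    return float(sigma_u2 / (sigma_u2 + LATENT_RESIDUAL_VARIANCE))


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor Rc for one parameter.

    ``chains`` is (n_chains, n_draws) with at least two chains of length at
    least ten draws each.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 10:
        raise ValueError("need >= 2 chains of length >= 10")
    m, n = x.shape
    within = x.var(axis=1, ddof=1)
    if np.all(within == 0.0):
        raise ValueError("zero within-chain variance in every chain")
    W = within.mean()
    B_over_n = x.mean(axis=1).var(ddof=1)
    v_hat = (n - 1) / n * W + (1.0 + 1.0 / m) * B_over_n
    return float(np.sqrt(v_hat / W))


def _subset_prior(prior: PriorSpec | None, names) -> PriorSpec:
    """Restrict a prior to a submodel, padding missing terms with the vague prior."""
    if prior is None:
        return noninformative_prior(names)
    means, variances = {}, {}
    for nm in names:
        if nm in prior.means:
            means[nm] = prior.means[nm]
            variances[nm] = prior.variances[nm]
        else:
            means[nm], variances[nm] = 0.0, 10_000.0
    return PriorSpec(means, variances, provenance=prior.provenance,
                     source_waves=prior.source_waves)


def model_sequence(df: pd.DataFrame, prior: PriorSpec | None = None,
                   outcomes=("y_any", "y_four"), run_mcmc: bool = True,
                   mcmc_settings: dict | None = None, rc_threshold: float = 1.1,
                   seed: int = 0) -> pd.DataFrame:
    """Fit the M0/M1/M2/M3 ladder for each outcome and tabulate diagnostics.

    Per-row failures are caught and flagged (partial table allowed).  The
    preferred model per outcome is the smallest-AIC converged fit, ties
    broken by BIC; with ``run_mcmc=False`` convergence is not assessed and
    preference uses AIC/BIC alone.
    """
    settings = {"n_chains": 3, "n_burnin": 400, "n_kept": 1200}
    settings.update(mcmc_settings or {})
    rows = []
    for outcome in outcomes:
        for mi, (label, terms) in enumerate(MODEL_TERMS.items()):
            rec = {"outcome": outcome, "model": label, "error": ""}
            try:
                model = MultilevelLogit.from_dataframe(df, outcome, list(terms))
                ml = model.fit()
                rec.update({"aic": ml.aic, "bic": ml.bic, "icc": ml.icc,
                            "sigma_u2": ml.sigma_u2, "llf": ml.llf,
                            "k": ml.k_params})
                if run_mcmc:
                    sub = _subset_prior(prior, coefficient_names(list(terms)))
                    bayes = model.fit_bayes(sub, seed=seed * 17 + mi,
                                            ml_results=ml, **settings)
                    rc = max(bayes.gelman_rubin().values())
                    rec["max_rc"] = rc
                    rec["converged"] = bool(rc < rc_threshold)
                    rec["icc_bayes"] = bayes.icc
            except Exception as exc:   # keep the remaining ladder rows
                rec["error"] = f"{type(exc).__name__}: {exc}"
                log.warning("model %s/%s failed: %s", outcome, label, exc)
            rows.append(rec)
    table = pd.DataFrame(rows)
    prefs = {}
    for outcome in outcomes:
        sub = table[(table["outcome"] == outcome) & (table["error"] == "")]
        if run_mcmc and "converged" in sub.columns:
            ok = sub[sub["converged"].fillna(False)]
            sub = ok if len(ok) else sub
        if len(sub):
            best = sub.sort_values(["aic", "bic"]).iloc[0]
            prefs[outcome] = best["model"]
    table.attrs["preferred"] = prefs
    return table
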