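"""Survey-weighted descriptives and design-based confounder screening.

``weighted_prevalence`` reports weighted proportions with 95% confidence
intervals computed on the logit scale using a design-effect-adjusted
effective sample size (cluster-linearised variance), so intervals behave
sensibly near 0 and 100%.

``rao_scott_chisq`` is the Rao-Scott second-order (Satterthwaite) corrected
chi-square test of independence for complex survey data: the Pearson
statistic computed from weighted proportions is referenced against a
chi-square whose scale and degrees of freedom are adjusted by the eigenvalues
of the estimated design-effects matrix.  The cluster covariance uses
denominator ``n_clusters`` so that with equal weights and one unit per
cluster the test reduces exactly to the classical Pearson chi-square.

Candidate confounders are retained when either outcome's screening p-value is
at or below the threshold (0.20, the usual purposeful-selection cut); the
exposure of interest is always retained.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["weighted_prevalence", "rao_scott_chisq", "select_confounders",
           "screen_wave", "prevalence_table"]


def _cluster_cov(indicators: np.ndarray, wnorm: np.ndarray,
                 cluster_ids) -> np.ndarray:
    """Linearised covariance of weighted proportion estimates.

    ``indicators`` is (n, K); ``wnorm`` sums to 1.  Cluster totals of the
    weighted residuals are accumulated and their outer-product sum taken with
    denominator n_clusters (no finite-cluster factor; see module docstring).
    """
    p_hat = wnorm @ indicators
    resid = wnorm[:, None] * (indicators - p_hat)
    codes, _ = pd.factorize(np.asarray(cluster_ids))
    z = np.zeros((codes.max() + 1, indicators.shape[1]))
    np.add.at(z, codes, resid)
    return z.T @ z


def weighted_prevalence(values, weights, cluster_ids=None):
    """Weighted prevalence (percent) of a binary indicator with a 95% CI.

    Returns ``(estimate, lower, upper)`` on the 0-100 scale.  The CI is a
    logit-scale Wald interval using the design-based variance; with equal
    weights and no clustering the point estimate is the sample proportion.
    """
    y = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if y.shape != w.shape:
        raise ValueError("values and weights differ in length")
    if not np.any(w > 0):
        raise ValueError("all weights are zero")
    if cluster_ids is None:
        cluster_ids = np.arange(len(y))
    wnorm = w / w.sum()
    p = float(wnorm @ y)
    if p < 1e-12 or p > 1.0 - 1e-12:
        # degenerate: no variation, interval collapses onto the boundary
        p = round(p)
        return 100.0 * p, 100.0 * p, 100.0 * p
    var = float(_cluster_cov(y[:, None], wnorm, cluster_ids)[0, 0])
    var = max(var, 1e-300)
    # logit-scale interval with SE transformed by the delta method
    se_logit = np.sqrt(var) / (p * (1.0 - p))
    lo = 1.0 / (1.0 + np.exp(-(np.log(p / (1 - p)) - 1.959963984540054 * se_logit)))
    hi = 1.0 / (1.0 + np.exp(-(np.log(p / (1 - p)) + 1.959963984540054 * se_logit)))
    return 100.0 * p, 100.0 * lo, 100.0 * hi


def prevalence_table(df: pd.DataFrame, variable: str, weight_col: str = "weight",
                     cluster_col: str = "cluster_id") -> pd.DataFrame:
    """Per-category weighted prevalence (percent) with 95% CIs."""
    rows = []
    vals = df[variable].astype(str)
    for level in pd.unique(vals):
        est, lo, hi = weighted_prevalence((vals == level).to_numpy(dtype=float),
                                          df[weight_col].to_numpy(dtype=float),
                                          df[cluster_col].to_numpy())
        rows.append({"variable": variable, "category": level,
                     "prevalence_pct": est, "ci_lower": lo, "ci_upper": hi})
    return pd.DataFrame(rows)


def rao_scott_chisq(variable, outcome, weights, cluster_ids):
    """Rao-Scott second-order corrected chi-square test of independence.

    Returns ``(p_value, statistic, df)`` where ``statistic`` is the corrected
    chi-square and ``df`` its Satterthwaite degrees of freedom.
    """
    v = np.asarray(variable).astype(str)
    y = np.asarray(outcome).astype(str)
    w = np.asarray(weights, dtype=float)
    rows = pd.unique(v)
    cols = pd.unique(y)
    R, C = len(rows), len(cols)
    if R < 2 or C < 2:
        raise ValueError("variable and outcome must each have >= 2 observed categories")
    n = len(v)
    wnorm = w / w.sum()
    ind = np.zeros((n, R * C))
    r_idx = pd.Categorical(v, categories=rows).codes
    c_idx = pd.Categorical(y, categories=cols).codes
    ind[np.arange(n), r_idx * C + c_idx] = 1.0
    p_hat = wnorm @ ind                      # weighted cell proportions
    P = p_hat.reshape(R, C)
    pr, pc = P.sum(axis=1), P.sum(axis=0)
    expected = np.outer(pr, pc)
    x2 = n * float(((P - expected) ** 2 / expected).sum())
    d = (R - 1) * (C - 1)
    if x2 == 0.0:
        return 1.0, 0.0, float(d)

    V_hat = _cluster_cov(ind, wnorm, cluster_ids)
    V0 = (np.diag(p_hat) - np.outer(p_hat, p_hat)) / n

    # Jacobian of the independence residuals g_rc = p_rc - p_r. p_.c
    # (first R-1 rows x C-1 cols) with respect to the full cell vector
    Jrows = []
    for r in range(R - 1):
        for c in range(C - 1):
            row = np.zeros(R * C)
            for uu in range(R):
                for vv in range(C):
                    row[uu * C + vv] = ((uu == r) * (vv == c)
                                        - (uu == r) * pc[c]
                                        - (vv == c) * pr[r])
            Jrows.append(row)
    J = np.asarray(Jrows)
    V0_g = J @ V0 @ J.T
    V_g = J @ V_hat @ J.T
    delta = np.linalg.solve(V0_g, V_g)
    eig = np.real(np.linalg.eigvals(delta))
    eig = np.clip(eig, 1e-12, None)
    dbar = eig.mean()
    a2 = eig.var() / dbar ** 2               # squared CV of the eigenvalues
    x2_rs = x2 / (dbar * (1.0 + a2))
    df_rs = d / (1.0 + a2)
    return float(stats.chi2.sf(x2_rs, df_rs)), float(x2_rs), float(df_rs)


def select_confounders(screening: pd.DataFrame, threshold: float = 0.20,
                       exposure: str = "intention") -> list[str]:
    """Variables with p <= threshold for at least one outcome; exposure always kept.

    ``screening`` needs columns ``variable`` and ``p_value`` (one row per
    variable x outcome).
    """
    selected = []
    for var, grp in screening.groupby("variable", sort=False):
        if var == exposure or (grp["p_value"] <= threshold).any():
            selected.append(var)
    if exposure not in selected:
        selected.insert(0, exposure)
    return selected


def screen_wave(df: pd.DataFrame, candidates, outcomes=("y_any", "y_four"),
                weight_col: str = "weight", cluster_col: str = "cluster_id",
                threshold: float = 0.20):
    """Run the bivariate screen for every candidate against both outcomes.

    Returns ``(screening_table, selected)``.
    """
    w = df[weight_col].to_numpy(dtype=float)
    cl = df[cluster_col].to_numpy()
    recs = []
    for var in candidates:
        values = df[var]
        if values.dtype.kind == "f" and var == "anc_quality":
            # continuous candidate: screened on a median split
            values = np.where(values > values.median(), "high", "low")
        for outcome in outcomes:
            p, x2, dfree = rao_scott_chisq(values, df[outcome], w, cl)
            recs.append({"variable": var, "outcome": outcome,
                         "p_value": p, "statistic": x2, "df": dfree})
    table = pd.DataFrame(recs)
    return table, select_confounders(table, threshold=threshold)
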