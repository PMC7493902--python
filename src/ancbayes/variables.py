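"""Derivation of analysis variables from raw woman-level survey records.

Implements the coding rules of the analysis: dichotomised skilled
antenatal-care (ANC) outcomes, the three-category mass-media exposure index,
age / parity categorisation, and cluster-aggregated community variables
(literacy, poverty, uptake of four or more skilled ANC visits).  A woman's own
responses contribute to her cluster's community aggregates (leave-self-in).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: raw columns a woman record must carry before derivation
RAW_COLUMNS = [
    "woman_id", "cluster_id", "weight", "birth_within_3y", "anc_visits",
    "anc_provider_skilled", "intention", "age_at_delivery_years", "education",
    "husband_education", "children_ever_born", "husband_occupation",
    "newspaper_weekly", "radio_weekly", "tv_weekly", "wealth_quintile",
    "residence", "region", "anc_quality",
]

#: covariates required complete for the complete-case analysis set
_COVARIATES = [
    "age_at_delivery_years", "education", "husband_education",
    "children_ever_born", "husband_occupation", "newspaper_weekly",
    "radio_weekly", "tv_weekly", "wealth_quintile", "residence", "region",
    "anc_quality",
]


def eligibility_filter(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep women eligible for analysis; tally exclusions by reason.

    A woman is eligible if she gave birth within the 3 years preceding the
    survey, reported her pregnancy intention, and answered the ANC questions.
    Reasons are assigned in that order, one per excluded row.
    """
    df = records
    no_birth = ~df["birth_within_3y"].astype("boolean").fillna(False).to_numpy(dtype=bool)
    missing_intention = (~no_birth) & (
        df["intention"].isna() | (df["intention"].astype(str).str.strip() == "")
    ).to_numpy(dtype=bool)
    missing_anc = (~no_birth) & (~missing_intention) & (
        df["anc_visits"].isna() | df["anc_provider_skilled"].isna()
    ).to_numpy(dtype=bool)
    keep = ~(no_birth | missing_intention | missing_anc)
    tally = {
        "no_recent_birth": int(no_birth.sum()),
        "missing_intention": int(missing_intention.sum()),
        "missing_anc_response": int(missing_anc.sum()),
    }
    return df.loc[keep].copy(), tally


def code_outcomes(anc_visits, anc_provider_skilled):
    """Dichotomise ANC uptake: (at least one skilled visit, at least four).

    Visits to unskilled providers count as zero skilled visits, so both
    outcomes are 0 whenever the provider was not skilled.  Accepts scalars or
    arrays; returns ``(y_any, y_four)`` of the same shape.
    """
    visits = np.asarray(anc_visits)
    if np.any(visits < 0):
        raise ValueError("negative ANC visit count")
    skilled = np.asarray(anc_provider_skilled).astype(bool)
    skilled_visits = np.where(skilled, visits, 0)
    y_any = (skilled_visits >= 1).astype(int)
    y_four = (skilled_visits >= 4).astype(int)
    if np.isscalar(anc_visits) or visits.ndim == 0:
        return int(y_any), int(y_four)
    return y_any, y_four


def media_exposure_index(newspaper_weekly, radio_weekly, tv_weekly):
    """Three-level mass-media exposure index.

    ``not_exposed`` if none of newspaper / radio / television is accessed at
    least once a week, ``high`` if all three are, ``moderate`` otherwise.
    """
    news = np.asarray(newspaper_weekly).astype(bool)
    radio = np.asarray(radio_weekly).astype(bool)
    tv = np.asarray(tv_weekly).astype(bool)
    count = news.astype(int) + radio.astype(int) + tv.astype(int)
    out = np.where(count == 0, "not_exposed", np.where(count == 3, "high", "moderate"))
    if out.ndim == 0:
        return str(out)
    return out


def community_poverty(cluster_wealth_quintiles) -> str:
    """Community poverty category from the cluster's household quintiles.

    Clusters containing only households in the top three quintiles are
    ``middle_to_richest``; otherwise the share p of households in the bottom
    two quintiles maps to low (p <= 25%), moderate (25% < p <= 50%) or
    high (p > 50%).
    """
    q = pd.Series(list(cluster_wealth_quintiles), dtype=str)
    if len(q) == 0:
        raise ValueError("empty cluster")
    poor = q.isin(["poorest", "poorer"])
    if not poor.any():
        return "middle_to_richest"
    share = poor.mean()
    if share <= 0.25:
        return "low"
    if share <= 0.50:
        return "moderate"
    return "high"


def community_literacy(cluster_literacy_flags) -> str:
    """Community literacy category: low (<=25%), moderate (25-50%], high (>50%)."""
    flags = np.asarray(list(cluster_literacy_flags), dtype=float)
    if flags.size == 0:
        raise ValueError("empty cluster")
    share = flags.mean()
    if share <= 0.25:
        return "low"
    if share <= 0.50:
        return "moderate"
    return "high"


def community_anc4(cluster_y_four_values) -> str:
    """Community uptake of four or more skilled visits: high iff mean > 50%."""
    vals = np.asarray(list(cluster_y_four_values), dtype=float)
    if vals.size == 0:
        raise ValueError("empty cluster")
    return "high" if vals.mean() > 0.5 else "low"


def _age_category(age_years) -> np.ndarray:
    age = np.asarray(age_years, dtype=float)
    return np.where(age <= 19, "le19", np.where(age <= 34, "20_34", "ge35"))


def derive(records: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Full derivation: eligibility, outcomes, indices, community aggregates.

    Returns the derived complete-case analysis table and an audit dict with
    the exclusion tallies.  Community variables use all eligible women in a
    cluster and are therefore identical for every woman of a cluster.
    """
    eligible, tally = eligibility_filter(records)
    missing_cov = eligible[_COVARIATES].isna().any(axis=1)
    tally["missing_covariate"] = int(missing_cov.sum())
    df = eligible.loc[~missing_cov].copy()
    audit = {"n_input": int(len(records)), "n_analysis": int(len(df)),
             "exclusions": tally}
    if tally["missing_covariate"]:
        log.info("complete-case exclusion: %d rows with missing covariates",
                 tally["missing_covariate"])
    if len(df) == 0:
        return df, audit

    y_any, y_four = code_outcomes(df["anc_visits"].to_numpy(dtype=float),
                                  df["anc_provider_skilled"])
    df["y_any"] = y_any
    df["y_four"] = y_four
    df["age_cat"] = _age_category(df["age_at_delivery_years"])
    df["children_cat"] = np.where(df["children_ever_born"].astype(float) <= 2,
                                  "le2", "gt2")
    df["media_index"] = media_exposure_index(df["newspaper_weekly"],
                                             df["radio_weekly"],
                                             df["tv_weekly"])
    df["literate"] = (df["education"].astype(str) != "none").astype(int)

    grp = df.groupby("cluster_id")
    pov = grp["wealth_quintile"].apply(community_poverty)
    lit = grp["literate"].apply(community_literacy)
    a4 = grp["y_four"].apply(community_anc4)
    df["community_poverty"] = df["cluster_id"].map(pov)
    df["community_literacy"] = df["cluster_id"].map(lit)
    df["community_anc4"] = df["cluster_id"].map(a4)
    log.info("derived %d analysis rows from %d records (exclusions: %s)",
             len(df), len(records), tally)
    return df, audit
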