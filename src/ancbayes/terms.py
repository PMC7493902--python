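"""Analysis-variable registry and design-matrix construction.

Every categorical variable used anywhere in the pipeline is declared here
once, with its category levels ordered so that the reference category (the
"(ref)" row of the published-style odds-ratio table) comes first.  Design
matrices are plain treatment-coded dummies against that reference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: name -> ordered levels, reference first.  ``None`` marks a continuous term.
TERMS: dict[str, tuple[str, ...] | None] = {
    "intention": ("wanted", "mistimed", "unwanted"),
    "education": ("none", "primary", "secondary", "higher"),
    "husband_education": ("none", "primary", "secondary", "higher"),
    "age_cat": ("le19", "20_34", "ge35"),
    "children_cat": ("le2", "gt2"),
    "husband_occupation": ("agricultural", "labourer", "service", "business", "other"),
    "media_index": ("not_exposed", "moderate", "high"),
    "wealth_quintile": ("poorest", "poorer", "middle", "richer", "richest"),
    "residence": ("urban", "rural"),
    "region": ("barishal", "chattogram", "dhaka", "khulna", "rajshahi", "rangpur", "sylhet"),
    "community_literacy": ("low", "moderate", "high"),
    "community_poverty": ("high", "moderate", "low", "middle_to_richest"),
    "community_anc4": ("high", "low"),
    "anc_quality": None,
}

#: individual- and household-level factors (modelled together: households
#: contribute on average about one analysed woman each, so a separate
#: household level is not identifiable and is collapsed into the woman level).
INDIVIDUAL_TERMS: tuple[str, ...] = (
    "intention",
    "education",
    "husband_education",
    "age_cat",
    "children_cat",
    "husband_occupation",
    "media_index",
    "wealth_quintile",
    "anc_quality",
)

#: community-level factors (constant within a sampling cluster).
COMMUNITY_TERMS: tuple[str, ...] = (
    "residence",
    "region",
    "community_literacy",
    "community_poverty",
    "community_anc4",
)

OUTCOMES: tuple[str, ...] = ("y_any", "y_four")


def is_categorical(term: str) -> bool:
    if term not in TERMS:
        raise KeyError(f"unknown analysis term {term!r}")
    return TERMS[term] is not None


def coefficient_names(terms: list[str] | tuple[str, ...]) -> list[str]:
    """Design-matrix column names (intercept first) for a list of terms."""
    names = ["Intercept"]
    for term in terms:
        levels = TERMS.get(term, KeyError)
        if levels is KeyError:
            raise KeyError(f"unknown analysis term {term!r}")
        if levels is None:
            names.append(term)
        else:
            names.extend(f"{term}[{lev}]" for lev in levels[1:])
    return names


def build_design(df: pd.DataFrame, terms: list[str] | tuple[str, ...]):
    """Treatment-coded design matrix with intercept.

    Returns ``(X, names)`` where ``X`` is a float ndarray of shape
    ``(len(df), k)`` and ``names`` the matching coefficient names.  Unknown
    category values raise ``ValueError``.
    """
    cols = [np.ones(len(df))]
    names = ["Intercept"]
    for term in terms:
        if term not in df.columns:
            raise ValueError(f"data is missing model variable {term!r}")
        levels = TERMS.get(term)
        if not is_categorical(term):
            cols.append(pd.to_numeric(df[term]).to_numpy(dtype=float))
            names.append(term)
            continue
        values = df[term].astype(str)
        bad = set(values.unique()) - set(levels)
        if bad:
            raise ValueError(f"unknown level(s) {sorted(bad)} for term {term!r}")
        for lev in levels[1:]:
            cols.append((values == lev).to_numpy(dtype=float))
            names.append(f"{term}[{lev}]")
    return np.column_stack(cols), names
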