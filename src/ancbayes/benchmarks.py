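"""Published benchmark estimates for the BDHS 2014 pregnancy-intention
analysis.

The real BDHS microdata are restricted-access, so these published headline
numbers serve as narrative anchors: the pipeline's synthetic runs are
calibrated to the same design (600 clusters, ~30 households each, ~4,493
eligible women) and its outputs are reported in the same shape.  Internal
consistency of the published numbers themselves (unintended = mistimed +
unwanted; each "X% lower odds" statement = 100*(1 - aOR)) is asserted in the
acceptance suite.
"""

from __future__ import annotations

#: weighted prevalence of pregnancy intention, percent (eligible women, 2014)
PREVALENCE_PCT = {
    "wanted": 74.1,
    "mistimed": 15.1,
    "unwanted": 10.9,
    "unintended": 26.0,
}

#: adjusted odds ratios (final, fully adjusted model), by outcome
ADJUSTED_OR = {
    "y_any": {"mistimed": 0.59, "unwanted": 0.67},     # >=1 skilled visit
    "y_four": {"mistimed": 0.73, "unwanted": 0.69},    # >=4 skilled visits
}

#: the "X% lower odds" statements as printed (integers, percent)
PCT_LOWER_ODDS = {
    "y_any": {"mistimed": 41, "unwanted": 33},
    "y_four": {"mistimed": 27, "unwanted": 31},
}

#: null-model and final-model intra-class correlations as printed
ICC_REPORTED = {
    "y_any": {"null": 0.32, "final": 1.70e-17},
    "y_four": {"null": 0.72, "final": 0.60},
}

#: design constants of the survey rounds
DESIGN = {"n_clusters": 600, "households_per_cluster": 30,
          "n_eligible_2014": 4493, "years": (2004, 2007, 2011, 2014)}


def percent_lower_odds(adjusted_or: float) -> float:
    """Convert an adjusted odds ratio below 1 to 'percent lower odds'."""
    return 100.0 * (1.0 - adjusted_or)
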