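"""Historical-data prior elicitation for the multilevel logistic model.

The elicitation follows the moment rule used in the analysis: fit the model
to each earlier survey wave under vague Normal(0, 10000) priors, then set
each coefficient's informative prior to an independent normal whose mean is
the average of the wave-specific posterior means and whose standard
deviation is the across-wave sample standard deviation of those means.  When
the waves happen to agree almost exactly the across-wave SD can collapse, so
it is floored at the average within-wave posterior SD — the prior can be as
sharp as the historical fits themselves, never degenerate.

Coefficients in the target formula that no historical wave could estimate
(for example a category unobserved in an old round) fall back to the vague
Normal(0, 10000) prior, with a logged warning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PriorSpec", "noninformative_prior", "fit_historical_wave",
           "combine_priors", "NONINFORMATIVE_VARIANCE"]

log = logging.getLogger(__name__)

NONINFORMATIVE_VARIANCE = 10_000.0


@dataclass
class PriorSpec:
    """Independent normal priors, one per fixed-effect coefficient."""

    means: dict[str, float]
    variances: dict[str, float]
    provenance: str = "noninformative"          # or "elicited"
    source_waves: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.means) != set(self.variances):
            raise ValueError("prior means and variances name different coefficients")
        for name, var in self.variances.items():
            if not var > 0:
                raise ValueError(f"prior variance for {name!r} must be positive")

    @property
    def coefficients(self) -> list[str]:
        return list(self.means)

    def moments(self, coefficient_names) -> tuple[np.ndarray, np.ndarray]:
        """Mean and variance vectors aligned with a model's coefficients."""
        missing = [c for c in coefficient_names if c not in self.means]
        if missing:
            raise ValueError(f"prior does not cover coefficients {missing}")
        mean = np.array([self.means[c] for c in coefficient_names])
        var = np.array([self.variances[c] for c in coefficient_names])
        return mean, var

    def to_json(self) -> str:
        return json.dumps({"means": self.means, "variances": self.variances,
                           "provenance": self.provenance,
                           "source_waves": self.source_waves},
                          indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PriorSpec":
        return cls(**json.loads(text))


def noninformative_prior(coefficient_names) -> PriorSpec:
    """Vague Normal(0, 10000) prior for every coefficient in the formula."""
    names = list(coefficient_names)
    if not names:
        raise ValueError("formula has no coefficients")
    return PriorSpec(means={c: 0.0 for c in names},
                     variances={c: NONINFORMATIVE_VARIANCE for c in names},
                     provenance="noninformative")


def fit_historical_wave(derived_df, outcome: str, terms, seed: int = 0,
                        n_chains: int = 3, n_burnin: int = 500,
                        n_kept: int = 1500, **fit_kwargs) -> dict[str, tuple[float, float]]:
    """Vague-prior Bayesian fit to one earlier wave.

    Returns ``{coefficient: (posterior mean, posterior SD)}`` for the fixed
    effects of the requested formula.
    """
    from .model import MultilevelLogit
    from .terms import coefficient_names

    model = MultilevelLogit.from_dataframe(derived_df, outcome, terms)
    prior = noninformative_prior(coefficient_names(terms))
    res = model.fit_bayes(prior, n_chains=n_chains, n_burnin=n_burnin,
                          n_kept=n_kept, seed=seed, **fit_kwargs)
    means = res.posterior_mean()
    sds = res.posterior_sd()
    return {name: (means[name], sds[name]) for name in model.exog_names}


def combine_priors(wave_posteriors, source_waves=None,
                   target_coefficients=None) -> PriorSpec:
    """Moment-combine per-wave posteriors into the informative prior.

    ``wave_posteriors`` is an ordered collection of
    ``{coefficient: (mean, sd)}`` mappings with identical coefficient sets.
    Per coefficient: prior mean = average of wave means; prior SD = sample SD
    (n-1 denominator) of wave means, floored at the average wave posterior
    SD; prior variance = SD^2.  Target coefficients absent from the
    historical fits fall back to Normal(0, 10000).
    """
    posteriors = list(wave_posteriors)
    if len(posteriors) < 2:
        raise ValueError("need at least two historical waves to combine")
    common = set(posteriors[0])
    for post in posteriors[1:]:
        if set(post) != common:
            raise ValueError("historical waves report different coefficient sets")
    targets = list(target_coefficients) if target_coefficients is not None \
        else list(posteriors[0])
    means, variances = {}, {}
    for coef in targets:
        if coef not in common:
            log.warning("coefficient %r absent from historical fits; "
                        "falling back to Normal(0, 10000)", coef)
            means[coef] = 0.0
            variances[coef] = NONINFORMATIVE_VARIANCE
            continue
        m = np.array([post[coef][0] for post in posteriors])
        s = np.array([post[coef][1] for post in posteriors])
        sd = max(float(np.std(m, ddof=1)), float(np.mean(s)))
        means[coef] = float(np.mean(m))
        variances[coef] = sd * sd
    return PriorSpec(means=means, variances=variances, provenance="elicited",
                     source_waves=list(source_waves or []))
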