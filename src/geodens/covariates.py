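"""Registry of dissemination-area-level census covariates.

Each covariate carries the raw unit it is generated and stored in, the
plausible distributional anchors used by the synthetic generator (median and
quartiles typical of a mixed rural/urban Canadian metropolitan region), and
the scaling applied before the covariate enters a regression model
(population density per 100 persons/km^2, income per Can $1000, everything
else unscaled).
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class CovariateSpec:
    name: str
    unit: str
    median: float
    q1: float
    q3: float
    #: generate on the log scale (heavy right skew, e.g. population density)
    log_scale: bool = False
    lower: float | None = None
    upper: float | None = None
    #: divide by this before the covariate enters a model
    model_scale: float = 1.0


REGISTRY: dict[str, CovariateSpec] = {
    s.name: s
    for s in (
        CovariateSpec(
            "population_density", "persons/km^2", 331.6, 59.2, 1807.0,
            log_scale=True, lower=1.0, upper=20000.0, model_scale=100.0,
        ),
        CovariateSpec("pct_male", "%", 49.3, 48.6, 50.5, lower=0.0, upper=100.0),
        CovariateSpec("avg_age_male", "years", 41.1, 38.2, 44.1, lower=18.0, upper=80.0),
        CovariateSpec(
            "median_income_male", "Can$", 48567.0, 42816.0, 55826.0,
            lower=0.0, model_scale=1000.0,
        ),
        CovariateSpec("pct_not_married", "%", 35.4, 30.9, 40.5, lower=0.0, upper=100.0),
        CovariateSpec("pct_postsecondary", "%", 57.6, 48.9, 62.0, lower=0.0, upper=100.0),
        CovariateSpec("pct_unemployed", "%", 5.1, 3.4, 6.1, lower=0.0, upper=100.0),
        CovariateSpec("pct_below_lico", "%", 7.0, 4.9, 11.1, lower=0.0, upper=100.0),
        CovariateSpec("pct_immigrants", "%", 27.2, 18.4, 38.8, lower=0.0, upper=100.0),
        CovariateSpec("pct_visible_minority", "%", 26.0, 12.4, 46.8, lower=0.0, upper=100.0),
        CovariateSpec("avg_household_size", "persons", 2.8, 2.6, 3.0, lower=1.0, upper=6.0),
    )
}

COVARIATE_NAMES: tuple[str, ...] = tuple(REGISTRY)

#: square kilometres per square (statute) mile
KM2_PER_MI2 = 2.589988110336


def scale_to_model(name: str, value):
    """Raw-unit covariate value -> regression-scale value."""
    return value / REGISTRY[name].model_scale


def default_beta() -> dict[str, float]:
    """Default true coefficient vector for the synthetic intensity model.

    Coefficients are on the regression scale (log incidence-rate ratios per
    scaled covariate unit) and reproduce effect sizes typical of ecological
    models of geosocial-app user density: strong negative household-size and
    moderate marital/education/immigration effects. Covariates with no
    configured effect are zero. The intercept is calibrated so that the
    median synthetic campaign (2-mile grid, 1-mile radius, ~256 locations)
    counts on the order of two thousand profiles — the yield scale of a
    metropolitan evening counting campaign — with most of the total
    intensity contributed by the dense downtown tail of the
    population-density field.
    """
    beta = {name: 0.0 for name in COVARIATE_NAMES}
    beta["population_density"] = math.log(1.03)
    beta["avg_age_male"] = math.log(0.93)
    beta["median_income_male"] = math.log(0.96)
    beta["pct_below_lico"] = math.log(0.93)
    beta["pct_postsecondary"] = math.log(1.06)
    beta["pct_immigrants"] = math.log(1.04)
    beta["pct_not_married"] = math.log(1.08)
    beta["avg_household_size"] = math.log(0.26)
    return {"intercept": 0.1, **beta}
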