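"""Repeated-trials (capture-recapture) model of illegal border crossings.

Each would-be crosser makes attempts until either entering successfully or
giving up after an apprehension.  Per attempt the crosser is apprehended
with probability ``p``; an apprehended crosser abandons further attempts
with probability ``d`` (the deterrence rate), otherwise tries again.  All
of an individual's attempts resolve within the calendar year of the first
attempt.

Writing q = p*(1-d) for the per-attempt probability of being caught and
retrying, the absorbing chain over n individuals gives

* apprehension events per person    E[K] = p / (1 - q)
* probability of eventual entry     P(enter) = (1-p) / (1 - q)
* re-apprehension events per person E[K] - P(K >= 1) = p*q / (1 - q)

so the share of apprehension events that are *recidivist* events
(apprehensions of someone already caught earlier in the year) is exactly
R/A = q = p*(1-d), giving the estimator  p = (R/A) / (1-d),  and the
number of successful entrants is  S = A * (1-p) / p  regardless of d.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .core_io import AnnualInputSeries, ParameterSet

__all__ = [
    "RateSource",
    "CrossingEstimate",
    "estimate_apprehension_probability",
    "successful_crossers",
    "crossers_series",
]


class RateSource(str, Enum):
    """Provenance of a year's apprehension rate."""

    ASSUMED_EARLY = "assumed_early"
    DHS_PUBLISHED = "dhs_published"
    RECIDIVISM_ESTIMATED = "recidivism_estimated"


@dataclass(frozen=True)
class CrossingEstimate:
    year: int
    apprehension_rate: float
    successful_crossers: float
    source: RateSource

    def __post_init__(self) -> None:
        if not 0.0 < self.apprehension_rate <= 1.0:
            raise ValueError(f"apprehension rate must lie in (0, 1], got {self.apprehension_rate}")
        if self.successful_crossers < 0:
            raise ValueError("successful crossers must be non-negative")


def estimate_apprehension_probability(
    apprehensions: float, recidivist: float, deterrence: float
) -> float:
    """Estimate the per-attempt apprehension probability from annual tallies.

    ``p = (R/A) / (1-d)``: the recidivist share of apprehension events equals
    p*(1-d) in the repeated-trials model, so dividing by the retry
    probability recovers p.
    """
    if apprehensions <= 0:
        raise ValueError("apprehensions must be positive")
    if not 0 <= recidivist <= apprehensions:
        raise ValueError("recidivist apprehensions must lie in [0, apprehensions]")
    if not 0 <= deterrence < 1:
        raise ValueError("deterrence must lie in [0, 1)")
    p = (recidivist / apprehensions) / (1.0 - deterrence)
    if p > 1.0:
        raise ValueError(
            f"inconsistent inputs: implied apprehension probability {p:.3f} > 1"
        )
    return p


def successful_crossers(apprehensions: float, apprehension_rate: float) -> float:
    """Number of individuals who eventually enter, from apprehension events.

    Each eventual entrant generates on average ``p/(1-p)`` of the year's
    apprehension events, hence ``S = A * (1-p) / p``.  Independent of the
    deterrence rate: deterred individuals' apprehensions are part of A, and
    the ratio of entries to apprehensions depends only on p.
    """
    if apprehensions < 0:
        raise ValueError("apprehensions must be non-negative")
    if not 0.0 < apprehension_rate <= 1.0:
        raise ValueError("apprehension rate must lie in (0, 1]")
    return apprehensions * (1.0 - apprehension_rate) / apprehension_rate


def crossers_series(
    inputs: AnnualInputSeries, params: ParameterSet, dhs_last_year: int = 2015
) -> list[CrossingEstimate]:
    """Annual successful-crosser counts over the whole input horizon.

    Rate choice per year: 1990-2004 use the assumed early rate; years with a
    published DHS apprehension-rate estimate use it directly; other years
    fall back to the recidivism-based estimator, or carry the last published
    DHS rate forward when recidivism inputs are also absent (the 2016 case).
    """
    out: list[CrossingEstimate] = []
    last_dhs: float | None = None
    for year in inputs.years:
        year = int(year)
        a = inputs.value("apprehensions", year)
        if year <= 2004:
            p, source = params.apprehension_rate_early, RateSource.ASSUMED_EARLY
        elif inputs.has_value("dhs_apprehension_rate", year):
            p, source = inputs.value("dhs_apprehension_rate", year), RateSource.DHS_PUBLISHED
            last_dhs = p
        elif inputs.has_value("recidivist_apprehensions", year) and inputs.has_value(
            "deterrence_rate", year
        ):
            p = estimate_apprehension_probability(
                a,
                inputs.value("recidivist_apprehensions", year),
                inputs.value("deterrence_rate", year),
            )
            source = RateSource.RECIDIVISM_ESTIMATED
        elif last_dhs is not None:
            p, source = last_dhs, RateSource.DHS_PUBLISHED
        elif a == 0:
            # no apprehensions and no rate information: nothing to infer,
            # and the entry count is zero for any rate
            p, source = 1.0, RateSource.RECIDIVISM_ESTIMATED
        else:
            raise ValueError(f"no usable apprehension rate for year {year}")
        if p <= 0:
            raise ValueError(f"no usable apprehension rate for year {year}")
        out.append(
            CrossingEstimate(
                year=year,
                apprehension_rate=p,
                successful_crossers=successful_crossers(a, p),
                source=source,
            )
        )
    return out


def crosser_inflows(
    inputs: AnnualInputSeries, params: ParameterSet
) -> np.ndarray:
    """Vector of expected crosser entries aligned with ``inputs.years``."""
    return np.array([c.successful_crossers for c in crossers_series(inputs, params)])
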