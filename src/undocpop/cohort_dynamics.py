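"""Duration-banded survival of entry cohorts.

Every entrant belongs to a cohort identified by entry year and entry
channel (visa overstayer, border crosser, or a pre-existing "initial"
stock).  A cohort's retention probability -- the chance a member is still
present and undocumented in a given year -- decays multiplicatively each
year through four outflows:

* voluntary emigration, at a duration-banded annual rate (first year /
  years 2-10 / beyond 10), with the first-year rate channel-specific;
* mortality, at a single age-adjusted annual rate;
* deportation and change of status (incl. DACA), taken as observed annual
  counts and converted to a single pooled rate shared by all cohorts.

Within a year the three factors compound in the fixed order
emigration -> mortality -> administrative; the product is order-invariant
but the order is fixed so intermediate stocks are reproducible.

Convention: a cohort entering year t has duration 1 in year t and faces
its first-year emigration rate in that same year (entry at start of year).
"Initial" cohorts represent already-present survivor stocks: they are
created with entry year t0-1 so that in their first simulated year t0 they
have duration 2, i.e. they start in the 2-10-year emigration band and
never face the first-year rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .border_inflow import crossers_series
from .core_io import AnnualInputSeries, ParameterSet
from .overstay_inflow import overstayers_series

__all__ = [
    "Cohort",
    "CohortLedger",
    "emigration_rate",
    "allocate_administrative_outflows",
    "advance_ledger",
]

CHANNELS = ("overstay", "crosser", "initial")


def emigration_rate(
    duration: int, channel: str, params: ParameterSet, entry_year: int
) -> float:
    """Annual voluntary-emigration fraction for a cohort-year.

    duration 1 -> channel-specific first-year rate; 2-10 -> mid rate;
    >10 -> late rate.  Initial stocks are survivor pools and are assigned
    the mid-band rate if a duration of 1 is ever requested for them.
    """
    if channel not in CHANNELS:
        raise ValueError(f"unknown entry channel {channel!r}")
    if duration < 1:
        raise ValueError("duration must be >= 1")
    if duration == 1:
        if channel == "overstay":
            return params.e1_overstay
        if channel == "crosser":
            return params.e1_crosser(entry_year)
        return params.e_mid
    if duration <= 10:
        return params.e_mid
    return params.e_late


def allocate_administrative_outflows(
    deportations: float, adjustments: float, cohort_stocks: np.ndarray
) -> np.ndarray:
    """Per-cohort administrative outflow rates (deportation + status change).

    The observed counts are pooled and divided by the total stock, so every
    cohort faces the same rate and absolute outflows are proportional to
    cohort size.  If the counts exceed the stock the rate is clamped at 1
    and a warning is emitted (inconsistent inputs).
    """
    cohort_stocks = np.asarray(cohort_stocks, dtype=float)
    total = float(cohort_stocks.sum())
    if total <= 0:
        raise ValueError("total stock must be positive")
    outflow = float(deportations) + float(adjustments)
    if outflow < 0:
        raise ValueError("administrative outflows must be non-negative")
    rate = outflow / total
    if rate > 1.0:
        warnings.warn(
            f"administrative outflows ({outflow:.0f}) exceed total stock "
            f"({total:.0f}); clamping rate to 1",
            stacklevel=2,
        )
        rate = 1.0
    return np.full(cohort_stocks.shape, rate)


@dataclass
class Cohort:
    entry_year: int
    channel: str
    expected_entries: float  # lambda_c
    retention: float = 1.0  # q_{c, current year}

    def duration_in(self, year: int) -> int:
        return year - self.entry_year + 1

    @property
    def expected_stock(self) -> float:
        return self.expected_entries * self.retention


@dataclass
class CohortLedger:
    """Per-cohort expected entries and retention, valid as of ``year``."""

    year: int
    cohorts: list[Cohort] = field(default_factory=list)

    @classmethod
    def initial(cls, params: ParameterSet, start_year: int) -> "CohortLedger":
        """Ledger holding only the pre-existing stock, valid at start_year-1."""
        return cls(
            year=start_year - 1,
            cohorts=[
                Cohort(
                    entry_year=start_year - 1,
                    channel="initial",
                    expected_entries=params.initial_population_mean,
                )
            ],
        )

    def expected_stock(self, channel: str | None = None) -> float:
        return sum(
            c.expected_stock
            for c in self.cohorts
            if channel is None or c.channel == channel
        )

    def stocks(self) -> np.ndarray:
        return np.array([c.expected_stock for c in self.cohorts])


def advance_ledger(
    ledger: CohortLedger,
    year: int,
    inputs: AnnualInputSeries,
    params: ParameterSet,
) -> CohortLedger:
    """Advance the ledger one year: decay existing cohorts, append new ones.

    New cohorts for ``year`` are sized by the inflow models (repeated-trials
    border crossers; visa overstayers) and face their first-year emigration
    rate immediately.  The administrative rate for ``year`` is computed from
    the post-emigration, post-mortality stock.
    """
    if year != ledger.year + 1:
        raise ValueError(f"ledger is valid at {ledger.year}; cannot advance to {year}")
    m = params.mortality
    cohorts = [replace(c) for c in ledger.cohorts]
    for c in cohorts:
        e = emigration_rate(c.duration_in(year), c.channel, params, c.entry_year)
        c.retention *= (1.0 - e) * (1.0 - m)

    if year in inputs.frame.index:
        crossers = {c.year: c.successful_crossers for c in crossers_series(inputs, params)}
        overstays = {
            o.year: o.new_overstayers
            for o in overstayers_series(inputs, params.overstay_multiplier)
        }
        for channel, entries in (("crosser", crossers[year]), ("overstay", overstays[year])):
            e1 = emigration_rate(1, channel, params, year)
            cohorts.append(
                Cohort(
                    entry_year=year,
                    channel=channel,
                    expected_entries=entries,
                    retention=(1.0 - e1) * (1.0 - m),
                )
            )
        deportations = inputs.value("deportations", year)
        adjustments = inputs.value("status_adjustments", year)
    else:
        deportations = adjustments = 0.0

    stocks = np.array([c.expected_stock for c in cohorts])
    if deportations + adjustments > 0:
        rates = allocate_administrative_outflows(deportations, adjustments, stocks)
        for c, a in zip(cohorts, rates):
            c.retention *= 1.0 - a
    return CohortLedger(year=year, cohorts=cohorts)
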