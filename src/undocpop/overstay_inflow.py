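"""Annual inflows of visa overstayers.

The overstay rate is the 2016 measured fraction of nonimmigrant visas
issued whose holders remain in the country beyond one year of visa
expiration; the conservative model applies that single rate to every year
of the horizon.  First-year attrition of counted overstayers is handled
downstream by the cohort dynamics, never here, so the rate is applied as a
plain product with no extra within-module adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import AnnualInputSeries

__all__ = ["OverstayEstimate", "overstayers_series", "overstay_inflows"]


@dataclass(frozen=True)
class OverstayEstimate:
    year: int
    new_overstayers: float

    def __post_init__(self) -> None:
        if self.new_overstayers < 0:
            raise ValueError("new overstayers must be non-negative")


def overstayers_series(
    inputs: AnnualInputSeries, multiplier: float = 1.0
) -> list[OverstayEstimate]:
    """New (>1 year) overstayers per year: visas_issued * rate * multiplier."""
    if multiplier < 0:
        raise ValueError("multiplier must be non-negative")
    rate = inputs.overstay_rate_2016 * multiplier
    if rate > 1.0:
        raise ValueError(f"effective overstay rate {rate:.3f} exceeds 1")
    return [
        OverstayEstimate(year=int(y), new_overstayers=inputs.value("visas_issued", int(y)) * rate)
        for y in inputs.years
    ]


def overstay_inflows(inputs: AnnualInputSeries, multiplier: float = 1.0) -> np.ndarray:
    """Vector of expected overstayer entries aligned with ``inputs.years``."""
    return np.array([o.new_overstayers for o in overstayers_series(inputs, multiplier)])
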