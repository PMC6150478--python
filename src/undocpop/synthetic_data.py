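"""Synthetic DHS-like annual input series and the agent-based crossing oracle.

The generator emits an input table with the statistical shape of the real
government series -- border apprehensions on the order of 10^5-10^6/yr
with a declining-then-flat trend, nonimmigrant visas ~10^7/yr, deportations
~10^5/yr rising over time, published apprehension-rate estimates from 2005
rising from ~0.35 past 0.5 -- with recidivist apprehensions constructed to
be exactly consistent with the repeated-trials model at an embedded true
apprehension rate, so the capture-recapture estimator can be validated
end-to-end against known truth.

The agent oracle simulates the crossing process individual by individual
(attempt; enter with prob 1-p; else apprehended, give up with prob d,
retry otherwise) and tallies apprehension events, recidivist apprehension
events (events involving an individual already apprehended that year) and
successful entries.  It is the independent arbiter for the closed forms in
:mod:`undocpop.border_inflow`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .core_io import AnnualInputSeries

__all__ = ["SynthConfig", "generate_inputs", "agent_crossing_oracle", "OracleTally"]


@dataclass
class SynthConfig:
    """Knobs for the synthetic input generator."""

    seed: int = 0
    horizon: tuple[int, int] = (1990, 2016)
    apprehension_level: float = 1.2e6  # early-1990s scale, persons/yr
    visa_level: float = 7.0e6
    deportation_level: float = 2.0e5
    overstay_rate_2016: float = 0.06
    true_rate_early: float = 0.30  # embedded true apprehension rate pre-2005
    dhs_rate_2005: float = 0.35
    dhs_rate_2015: float = 0.55
    noise_sd: float = 0.05  # lognormal jitter on counts


def _trend(start: float, end: float, n: int) -> np.ndarray:
    return np.linspace(start, end, n)


def generate_inputs(config: SynthConfig) -> AnnualInputSeries:
    """Generate a validated synthetic annual input series."""
    rng = np.random.default_rng(config.seed)
    y0, y1 = config.horizon
    years = np.arange(y0, y1 + 1)
    n = len(years)

    jitter = lambda size: np.exp(rng.normal(0.0, config.noise_sd, size))

    # apprehensions: roughly flat-high through 2000, then declining to ~35%.
    shape = np.where(
        years <= 2000,
        1.0,
        np.maximum(0.35, 1.0 - 0.065 * (years - 2000)),
    )
    apprehensions = np.round(config.apprehension_level * shape * jitter(n))

    # embedded true apprehension rate: early plateau, then the published rise.
    frac = np.clip((years - 2005) / (2015 - 2005), 0.0, 1.0)
    true_rate = np.where(
        years < 2005,
        config.true_rate_early,
        config.dhs_rate_2005 + (config.dhs_rate_2015 - config.dhs_rate_2005) * frac,
    )

    deterrence = np.where(years >= 2005, 0.30 + 0.02 * (years - 2005), np.nan)
    recidivist = np.where(
        years >= 2005, np.round(apprehensions * true_rate * (1.0 - deterrence)), np.nan
    )
    dhs_rate = np.where((years >= 2005) & (years <= 2015), true_rate, np.nan)

    visas = np.round(config.visa_level * _trend(0.85, 1.45, n) * jitter(n))
    deportations = np.round(config.deportation_level * _trend(0.2, 1.8, n) * jitter(n))
    adjustments = np.round(0.4 * config.deportation_level * _trend(0.5, 1.0, n) * jitter(n))

    frame = pd.DataFrame(
        {
            "apprehensions": apprehensions,
            "recidivist_apprehensions": recidivist,
            "deterrence_rate": deterrence,
            "dhs_apprehension_rate": dhs_rate,
            "visas_issued": visas,
            "deportations": deportations,
            "status_adjustments": adjustments,
        },
        index=pd.Index(years, name="year"),
    )
    return AnnualInputSeries(frame=frame, overstay_rate_2016=config.overstay_rate_2016)


class OracleTally(NamedTuple):
    apprehensions: int
    recidivist_apprehensions: int
    successful_entries: int
    deterred: int


def agent_crossing_oracle(
    n_individuals: int,
    p: float,
    d: float,
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> OracleTally:
    """Simulate the repeated-trials crossing process to absorption.

    Each individual attempts until entering or giving up; every
    apprehension event is tallied, and events involving an individual
    already apprehended earlier count as recidivist apprehensions.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError("p must lie in (0, 1]")
    if not 0.0 <= d <= 1.0:
        raise ValueError("d must lie in [0, 1]")

    active = np.ones(n_individuals, dtype=bool)
    caught_before = np.zeros(n_individuals, dtype=bool)
    apprehensions = recidivist = entries = deterred = 0

    for _ in range(max_attempts):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        caught = rng.random(idx.size) < p
        entries += int((~caught).sum())
        active[idx[~caught]] = False

        caught_idx = idx[caught]
        apprehensions += caught_idx.size
        recidivist += int(caught_before[caught_idx].sum())
        caught_before[caught_idx] = True

        gives_up = rng.random(caught_idx.size) < d
        deterred += int(gives_up.sum())
        active[caught_idx[gives_up]] = False
    else:
        raise RuntimeError(
            f"attempt cap {max_attempts} reached with {int(active.sum())} individuals unresolved"
        )

    return OracleTally(apprehensions, recidivist, entries, deterred)
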