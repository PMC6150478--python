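"""Deterministic runs: conservative estimate, calibrated scenario, and
overstay-rate calibration.

The conservative run uses parameter values chosen to understate inflows
and overstate outflows (early apprehension rate 0.39, first-year
emigration 0.40, years 2-10 at 0.04/yr, beyond 10 at 0.01/yr, mortality
0.007, overstay multiplier 1), so the resulting trajectory is a defensible
lower bound within the model's assumptions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .cohort_dynamics import CohortLedger, advance_ledger
from .core_io import AnnualInputSeries, ParameterSet, PopulationTrajectory

__all__ = [
    "ScenarioSpec",
    "conservative_trajectory",
    "scenario_trajectory",
    "calibrate_overstay_multiplier",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """A calibrated net-inflow period preceding the forward simulation.

    The model's own inflow/outflow bookkeeping is suspended over ``period``;
    the stock instead grows linearly by ``net_inflow_per_year``, and the
    pooled stock at the period's end seeds the forward run as a single
    survivor cohort in the 2-10-year emigration band.
    """

    net_inflow_per_year: float = 0.5e6
    period: tuple[int, int] = (1990, 1998)
    initial_population: float = 3.5e6

    @property
    def pooled_start(self) -> float:
        """Stock at the end of the period: N0 + inflow x years in period."""
        n_years = self.period[1] - self.period[0] + 1
        return self.initial_population + self.net_inflow_per_year * n_years

    @property
    def resume_year(self) -> int:
        return self.period[1] + 1


def conservative_trajectory(
    inputs: AnnualInputSeries, params: ParameterSet | None = None
) -> PopulationTrajectory:
    """Deterministic expected-value run over the whole input horizon.

    Returns the yearly expected population with its decomposition into the
    surviving initial stock, border-crosser stock and overstayer stock.
    """
    if params is None:
        params = ParameterSet.conservative()
    required = ["apprehensions", "visas_issued", "deportations", "status_adjustments"]
    for col in required:
        if inputs.frame[col].isna().any():
            raise ValueError(f"input column {col!r} has missing values")

    ledger = CohortLedger.initial(params, inputs.start_year)
    years, pop, init_s, cross_s, over_s = [], [], [], [], []
    for year in inputs.years:
        ledger = advance_ledger(ledger, int(year), inputs, params)
        years.append(int(year))
        init_s.append(ledger.expected_stock("initial"))
        cross_s.append(ledger.expected_stock("crosser"))
        over_s.append(ledger.expected_stock("overstay"))
        pop.append(init_s[-1] + cross_s[-1] + over_s[-1])
    return PopulationTrajectory(
        years=np.array(years),
        population=np.array(pop),
        overstayer_stock=np.array(over_s),
        crosser_stock=np.array(cross_s),
        initial_stock=np.array(init_s),
    )


def scenario_trajectory(
    inputs: AnnualInputSeries,
    spec: ScenarioSpec,
    mode: str = "conservative",
    params: ParameterSet | None = None,
    trials: int = 100_000,
    seed: int = 0,
):
    """Run the calibrated-period scenario.

    ``mode='conservative'`` returns a deterministic
    :class:`PopulationTrajectory`; ``mode='simulation'`` returns a
    :class:`~undocpop.monte_carlo.SimulationResult` over ``trials`` trials.
    """
    if spec.period[0] < inputs.start_year or spec.period[1] >= inputs.end_year:
        raise ValueError("scenario period must start within and end before the input range")

    if mode == "simulation":
        from .monte_carlo import run_simulation

        return run_simulation(inputs, trials=trials, seed=seed, scenario=spec)
    if mode != "conservative":
        raise ValueError(f"unknown mode {mode!r}")

    if params is None:
        params = ParameterSet.conservative()

    years, pop, init_s, cross_s, over_s = [], [], [], [], []
    for k, year in enumerate(range(spec.period[0], spec.period[1] + 1)):
        years.append(year)
        level = spec.initial_population + spec.net_inflow_per_year * (k + 1)
        pop.append(level)
        init_s.append(level)
        cross_s.append(0.0)
        over_s.append(0.0)

    pooled = ParameterSet(
        apprehension_rate_early=params.apprehension_rate_early,
        overstay_multiplier=params.overstay_multiplier,
        e1_overstay=params.e1_overstay,
        e1_crosser_by_cohort=dict(params.e1_crosser_by_cohort),
        e_mid=params.e_mid,
        e_late=params.e_late,
        mortality=params.mortality,
        initial_population_mean=spec.pooled_start,
    )
    ledger = CohortLedger.initial(pooled, spec.resume_year)
    for year in range(spec.resume_year, inputs.end_year + 1):
        ledger = advance_ledger(ledger, year, inputs, pooled)
        years.append(year)
        init_s.append(ledger.expected_stock("initial"))
        cross_s.append(ledger.expected_stock("crosser"))
        over_s.append(ledger.expected_stock("overstay"))
        pop.append(init_s[-1] + cross_s[-1] + over_s[-1])
    return PopulationTrajectory(
        years=np.array(years),
        population=np.array(pop),
        overstayer_stock=np.array(over_s),
        crosser_stock=np.array(cross_s),
        initial_stock=np.array(init_s),
    )


def calibrate_overstay_multiplier(
    inputs: AnnualInputSeries,
    target_stock: float,
    target_year: int,
    k_max: float | None = None,
    rtol: float = 1e-6,
) -> float:
    """Multiplier k on the overstay rate matching a target overstayer stock.

    Finds k such that the conservative run with overstay multiplier k has
    an overstayer sub-population of ``target_stock`` in ``target_year``.
    The stock is monotone (nearly linear) in k, so a bracketing root-finder
    converges quickly.
    """
    if target_stock <= 0:
        raise ValueError("target stock must be positive")
    rate = inputs.overstay_rate_2016
    if k_max is None:
        k_max = 1.0 / rate if rate > 0 else np.inf
    if not np.isfinite(k_max):
        raise ValueError("overstay rate is zero; no multiplier can reach the target")

    def residual(k: float) -> float:
        params = ParameterSet(overstay_multiplier=k)
        traj = conservative_trajectory(inputs, params)
        idx = int(np.searchsorted(traj.years, target_year))
        return float(traj.overstayer_stock[idx]) - target_stock

    lo = 1e-9
    if residual(k_max) < 0:
        raise ValueError(
            f"target overstayer stock {target_stock:.3g} unreachable for k <= {k_max:.3g}"
        )
    return float(brentq(residual, lo, k_max, rtol=rtol))
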