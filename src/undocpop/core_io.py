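"""Shared data model and file I/O for the stock-flow population model.

The model is driven by a single annual input table (1990-2016 by default)
holding the observed series: southwest-border apprehensions, recidivist
apprehensions, deterrence-rate estimates, DHS apprehension-rate estimates,
nonimmigrant visas issued, deportations (removals) and changes of legal
status (including DACA).  A single scalar -- the 2016 visa-overstay rate --
rides along with the table because it applies to every year of the series.

Counts are persons per year; every rate is a fraction in [0, 1].
Missing observations (e.g. recidivist apprehensions before 2005) are
explicit NaN, never silently zero-filled.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AnnualInputSeries",
    "ParameterSet",
    "PopulationTrajectory",
    "SchemaError",
    "ValidationError",
    "read_annual_inputs",
    "write_trajectory",
    "read_trajectory",
    "load_us_inputs",
]

INPUT_COLUMNS = [
    "year",
    "apprehensions",
    "recidivist_apprehensions",
    "deterrence_rate",
    "dhs_apprehension_rate",
    "visas_issued",
    "deportations",
    "status_adjustments",
]

_COUNT_COLUMNS = [
    "apprehensions",
    "recidivist_apprehensions",
    "visas_issued",
    "deportations",
    "status_adjustments",
]
_RATE_COLUMNS = ["deterrence_rate", "dhs_apprehension_rate"]


class SchemaError(ValueError):
    """Input table does not have the expected columns."""


class ValidationError(ValueError):
    """Input values violate a model invariant."""


@dataclass
class AnnualInputSeries:
    """Year-indexed observed counts and rates driving the model.

    Parameters
    ----------
    frame
        DataFrame indexed by calendar year with the columns of
        :data:`INPUT_COLUMNS` (minus ``year``, which is the index).
    overstay_rate_2016
        Fraction of visas issued whose holders overstay beyond one year,
        measured for 2016 and applied (optionally scaled) to every year.
    """

    frame: pd.DataFrame
    overstay_rate_2016: float

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors -------------------------------------------------------
    @property
    def years(self) -> np.ndarray:
        return self.frame.index.to_numpy()

    @property
    def start_year(self) -> int:
        return int(self.frame.index.min())

    @property
    def end_year(self) -> int:
        return int(self.frame.index.max())

    def column(self, name: str) -> pd.Series:
        return self.frame[name]

    def value(self, name: str, year: int) -> float:
        return float(self.frame.at[year, name])

    def has_value(self, name: str, year: int) -> bool:
        return year in self.frame.index and not pd.isna(self.frame.at[year, name])

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        missing = [c for c in INPUT_COLUMNS if c != "year" and c not in self.frame.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")

        years = self.frame.index.to_numpy()
        if len(years) == 0:
            raise ValidationError("input series is empty")
        if not np.array_equal(years, np.arange(years.min(), years.max() + 1)):
            raise ValidationError("years must form a contiguous range")

        for col in _COUNT_COLUMNS:
            vals = self.frame[col]
            bad = vals.dropna() < 0
            if bad.any():
                year = int(bad.idxmax())
                raise ValidationError(f"negative count in column {col!r} at year {year}")
        for col in _RATE_COLUMNS:
            vals = self.frame[col].dropna()
            bad = (vals < 0) | (vals > 1)
            if bad.any():
                year = int(bad.idxmax())
                raise ValidationError(
                    f"rate outside [0, 1] in column {col!r} at year {year}"
                )
        if not 0.0 <= self.overstay_rate_2016 <= 1.0:
            raise ValidationError("overstay_rate_2016 must lie in [0, 1]")

        both = self.frame[["apprehensions", "recidivist_apprehensions"]].dropna()
        bad = both["recidivist_apprehensions"] > both["apprehensions"]
        if bad.any():
            year = int(bad.idxmax())
            raise ValidationError(
                f"recidivist apprehensions exceed apprehensions at year {year}"
            )

    # -- equality (NaN-aware) --------------------------------------------
    def equals(self, other: "AnnualInputSeries") -> bool:
        return (
            np.isclose(self.overstay_rate_2016, other.overstay_rate_2016)
            and self.frame.shape == other.frame.shape
            and bool(
                self.frame.sort_index(axis=1)
                .round(9)
                .equals(other.frame.sort_index(axis=1).round(9))
            )
        )


@dataclass
class ParameterSet:
    """One complete assignment of the model's uncertain rates.

    The conservative preset deliberately understates inflows (high early
    apprehension rate) and overstates outflows (high emigration rates).

    ``e1_crosser_by_cohort`` maps entry year -> first-year voluntary
    emigration fraction for illegal border crossers; in deterministic runs
    every cohort shares the scalar ``e1_overstay`` value unless overridden.
    """

    apprehension_rate_early: float = 0.39
    overstay_multiplier: float = 1.0
    e1_overstay: float = 0.40
    e1_crosser_by_cohort: Mapping[int, float] = field(default_factory=dict)
    e_mid: float = 0.04
    e_late: float = 0.01
    mortality: float = 0.007
    initial_population_mean: float = 3.5e6
    correlation: float = -0.5

    def __post_init__(self) -> None:
        for name in ("apprehension_rate_early", "e1_overstay", "e_mid", "e_late", "mortality"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.overstay_multiplier <= 0:
            raise ValidationError("overstay_multiplier must be positive")
        for year, v in dict(self.e1_crosser_by_cohort).items():
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"e1_crosser_by_cohort[{year}]={v} outside [0, 1]")

    def e1_crosser(self, entry_year: int) -> float:
        """First-year emigration rate for a crosser cohort (falls back to e1_overstay)."""
        return float(dict(self.e1_crosser_by_cohort).get(entry_year, self.e1_overstay))

    @classmethod
    def conservative(cls) -> "ParameterSet":
        """The deterministic conservative preset."""
        return cls()


@dataclass
class PopulationTrajectory:
    """Year -> population estimate, optionally decomposed by entry channel.

    ``population`` holds expected values for deterministic runs and sampled
    integers for stochastic trials.  When present, the three decomposition
    arrays sum to ``population``.
    """

    years: np.ndarray
    population: np.ndarray
    overstayer_stock: np.ndarray | None = None
    crosser_stock: np.ndarray | None = None
    initial_stock: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.population = np.asarray(self.population, dtype=float)
        if self.years.shape != self.population.shape:
            raise ValidationError("years and population must have equal length")
        if np.any(self.population < 0):
            raise ValidationError("population must be non-negative")
        if self.has_decomposition:
            total = self.overstayer_stock + self.crosser_stock + self.initial_stock
            if not np.allclose(total, self.population, rtol=1e-9, atol=1e-6):
                raise ValidationError("decomposition does not sum to population")

    @property
    def has_decomposition(self) -> bool:
        return (
            self.overstayer_stock is not None
            and self.crosser_stock is not None
            and self.initial_stock is not None
        )

    def value(self, year: int) -> float:
        idx = int(np.searchsorted(self.years, year))
        if idx >= len(self.years) or self.years[idx] != year:
            raise KeyError(f"year {year} not in trajectory")
        return float(self.population[idx])

    def to_frame(self) -> pd.DataFrame:
        data = {"year": self.years, "population": self.population}
        if self.has_decomposition:
            data["overstayer_stock"] = self.overstayer_stock
            data["crosser_stock"] = self.crosser_stock
            data["initial_stock"] = self.initial_stock
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_annual_inputs(
    path: str | Path,
    overstay_rate_2016: float | None = None,
    config_path: str | Path | None = None,
) -> AnnualInputSeries:
    """Read and validate the annual input CSV.

    The overstay-rate scalar lives outside the table; pass it directly or
    point ``config_path`` at a YAML file with an ``overstay_rate_2016`` key.
    """
    frame = pd.read_csv(path)
    missing = [c for c in INPUT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    frame = frame.set_index("year").sort_index()

    if overstay_rate_2016 is None:
        if config_path is None:
            raise SchemaError(
                "overstay_rate_2016 must be given directly or via config_path"
            )
        with open(config_path) as fh:
            cfg = yaml.safe_load(fh) or {}
        if "overstay_rate_2016" not in cfg:
            raise SchemaError("config file lacks key 'overstay_rate_2016'")
        overstay_rate_2016 = float(cfg["overstay_rate_2016"])

    return AnnualInputSeries(frame=frame, overstay_rate_2016=overstay_rate_2016)


def write_annual_inputs(series: AnnualInputSeries, path: str | Path) -> None:
    """Write the annual input table back to CSV (scalar rate not included)."""
    series.frame.reset_index().to_csv(path, index=False)


def write_trajectory(trajectory: PopulationTrajectory, path: str | Path) -> None:
    """Write a population trajectory as CSV (year, population [, decomposition])."""
    if len(trajectory.years) == 0:
        raise ValidationError("refusing to write an empty trajectory")
    trajectory.to_frame().to_csv(path, index=False)


def read_trajectory(path: str | Path) -> PopulationTrajectory:
    frame = pd.read_csv(path)
    kwargs = {}
    if {"overstayer_stock", "crosser_stock", "initial_stock"} <= set(frame.columns):
        kwargs = {
            "overstayer_stock": frame["overstayer_stock"].to_numpy(),
            "crosser_stock": frame["crosser_stock"].to_numpy(),
            "initial_stock": frame["initial_stock"].to_numpy(),
        }
    return PopulationTrajectory(
        years=frame["year"].to_numpy(),
        population=frame["population"].to_numpy(),
        **kwargs,
    )


def load_us_inputs() -> AnnualInputSeries:
    """Load the bundled 1990-2016 U.S. input series.

    This table is a *synthetic* stand-in reconstructed from publicly
    documented magnitudes of the underlying government series (southwest
    border apprehensions, DHS apprehension-rate estimates, nonimmigrant
    visas issued, removals, status adjustments including DACA); it is not a
    transcription of any single official release.
    """
    pkg = importlib.resources.files("undocpop") / "data"
    with importlib.resources.as_file(pkg / "us_1990_2016_synthetic.csv") as csv_path, \
            importlib.resources.as_file(pkg / "us_config_synthetic.yaml") as cfg_path:
        return read_annual_inputs(csv_path, config_path=cfg_path)
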