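"""Quadrature uncertainty budget for the film dosimetry chain.

Components are relative standard uncertainties in percent, grouped by
origin (film scanner, film, source), combined in quadrature as
uncorrelated Type-B terms with no coverage factor.  The calibration-
curve-fitting component depends on the analysis scenario: restricting
each channel to its appropriate dose range gives 3.8%, using every
channel over the full dose range gives 7.8%.  The film-orientation
component is tabulated but excluded by default, since all films are
scanned in one orientation.

The default budget ships as a CSV fixture; totals are reported unrounded
(the tabulated bounds 8.05% and 10.54% print as 8.0-10.5 at one decimal).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "UncertaintyComponent",
    "UncertaintyBudget",
    "quadrature_total",
    "budget_report",
    "default_budget",
    "CALIBRATION_FIT_SCENARIOS",
]

#: Calibration-curve-fitting uncertainty (%) per analysis scenario.
CALIBRATION_FIT_SCENARIOS = {"appropriate_channel": 3.8, "all_channels": 7.8}

_CALIBRATION_NAME = "Film calibration curve fitting"


@dataclass(frozen=True)
class UncertaintyComponent:
    name: str
    group: str
    value_pct: float
    included: bool = True

    def __post_init__(self) -> None:
        if self.value_pct < 0:
            raise ValueError(f"{self.name}: uncertainty must be >= 0")
        if self.group not in ("film scanner", "film", "source"):
            raise ValueError(f"{self.name}: unknown group {self.group!r}")

    @property
    def is_calibration_fit(self) -> bool:
        return self.name == _CALIBRATION_NAME


@dataclass
class UncertaintyBudget:
    """Named percentage components plus the calibration-fit scenario.

    ``calibration_fit_scenario`` is either a scenario name or an explicit
    percentage within the scenario bounds [3.8, 7.8].
    """

    components: list[UncertaintyComponent]
    calibration_fit_scenario: str | float = "all_channels"

    def __post_init__(self) -> None:
        n_cal = sum(c.is_calibration_fit for c in self.components)
        if n_cal != 1:
            raise ValueError(
                f"budget must contain exactly one calibration-curve-fitting "
                f"component, found {n_cal}"
            )
        self._resolve_scenario(self.calibration_fit_scenario)

    @staticmethod
    def _resolve_scenario(scenario) -> float:
        if isinstance(scenario, str):
            try:
                return CALIBRATION_FIT_SCENARIOS[scenario]
            except KeyError:
                raise ValueError(
                    f"unknown scenario {scenario!r}; choose from "
                    f"{sorted(CALIBRATION_FIT_SCENARIOS)} or give a value"
                ) from None
        value = float(scenario)
        lo = min(CALIBRATION_FIT_SCENARIOS.values())
        hi = max(CALIBRATION_FIT_SCENARIOS.values())
        if not lo <= value <= hi:
            raise ValueError(
                f"explicit calibration-fit value must lie in [{lo}, {hi}]"
            )
        return value

    def resolved_components(self, scenario=None) -> list[UncertaintyComponent]:
        scenario = scenario if scenario is not None else self.calibration_fit_scenario
        cal_value = self._resolve_scenario(scenario)
        out = []
        for c in self.components:
            if c.is_calibration_fit:
                c = replace(c, value_pct=cal_value)
            out.append(c)
        return out

    def total(self, scenario=None) -> float:
        """Quadrature sum (%) of the included components."""
        comps = [c for c in self.resolved_components(scenario) if c.included]
        if not comps:
            raise ValueError("no included components")
        return float(np.sqrt(sum(c.value_pct**2 for c in comps)))

    # -- I/O --------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "name": c.name,
                    "group": c.group,
                    "percent": c.value_pct,
                    "included": c.included,
                }
                for c in self.components
            ]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kwargs) -> "UncertaintyBudget":
        comps = [
            UncertaintyComponent(
                name=row["name"],
                group=row["group"],
                value_pct=float(row["percent"]),
                included=bool(row["included"]),
            )
            for _, row in df.iterrows()
        ]
        return cls(components=comps, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "UncertaintyBudget":
        return cls.from_frame(pd.read_csv(path), **kwargs)

    @classmethod
    def from_json(cls, path, **kwargs) -> "UncertaintyBudget":
        return cls.from_frame(
            pd.DataFrame(json.loads(Path(path).read_text())), **kwargs
        )


def quadrature_total(budget: UncertaintyBudget, scenario=None) -> float:
    """Total uncertainty (%) for a budget (module-level convenience)."""
    return budget.total(scenario)


def budget_report(budget: UncertaintyBudget) -> tuple[pd.DataFrame, str]:
    """Component table plus the scenario total range, e.g. '8.0-10.5'.

    The range spans the appropriate-channel and all-channel calibration
    scenarios, formatted to one decimal (unrounded inputs).
    """
    df = budget.to_frame()
    totals = sorted(
        budget.total(name) for name in CALIBRATION_FIT_SCENARIOS
    )
    range_str = f"{totals[0]:.1f}–{totals[1]:.1f}"
    return df, range_str


def default_budget(**kwargs) -> UncertaintyBudget:
    """The shipped dose-uncertainty budget fixture."""
    with resources.files("ebfilm.data").joinpath("uncertainty_budget.csv").open() as fh:
        return UncertaintyBudget.from_csv(fh, **kwargs)
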