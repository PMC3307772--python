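"""Threshold-based control policies and the annual control step.

A policy treats, each year, every forested cell whose occupancy strictly
exceeds its threshold ("exceeded" -> strict comparison, so the immediate
policy with threshold 0 treats any positive occupancy). Treatment resets
occupancy to zero and the maturity clock; treated cells can be re-invaded
later. Detection and treatment are assumed perfect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .economics import CostLedger, CostParams, control_cost, search_cost
from .landscape import NEVER, Landscape
from .spread import SpreadState

__all__ = ["Policy", "apply_control", "NAMED_THRESHOLDS"]

#: Named policies: no control, and control above 60 / 25 / 0 percent.
NAMED_THRESHOLDS: dict[str, Optional[float]] = {
    "NC": None,
    "LC": 60.0,
    "MC": 25.0,
    "HC": 0.0,
}


@dataclass(frozen=True)
class Policy:
    """A control threshold (percent occupancy), or no control at all."""

    name: str = "custom"
    threshold: Optional[float] = None  # None == never treat

    def __post_init__(self) -> None:
        if self.threshold is not None and not 0.0 <= self.threshold < 100.0:
            raise ValueError(f"threshold must be in [0, 100), got {self.threshold}")
        if self.name == "NC" and self.threshold is not None:
            raise ValueError("NC policy must have no threshold")

    @classmethod
    def named(cls, name: str) -> "Policy":
        try:
            return cls(name=name, threshold=NAMED_THRESHOLDS[name])
        except KeyError as exc:
            raise ValueError(
                f"unknown policy {name!r}; expected one of {sorted(NAMED_THRESHOLDS)}"
            ) from exc

    @classmethod
    def from_config(cls, cfg: Union[str, float, dict, None]) -> "Policy":
        """Accepts "MC", {"name": "MC"}, {"threshold": 5}, a bare number, or None (NC)."""
        if cfg is None:
            return cls.named("NC")
        if isinstance(cfg, str):
            return cls.named(cfg)
        if isinstance(cfg, (int, float)):
            return cls(name=f"theta={cfg:g}", threshold=float(cfg))
        if isinstance(cfg, dict):
            if "name" in cfg and cfg.get("threshold") is None:
                return cls.named(cfg["name"])
            if "threshold" in cfg:
                thr = cfg["threshold"]
                return cls(name=cfg.get("name", f"theta={thr:g}"), threshold=float(thr))
        raise ValueError(f"cannot build a policy from {cfg!r}")

    @property
    def is_no_control(self) -> bool:
        return self.threshold is None


def apply_control(
    state: SpreadState,
    landscape: Landscape,
    policy: Policy,
    year: int,
    ledger: Optional[CostLedger],
    cost_params: CostParams,
) -> SpreadState:
    """Treat every cell whose occupancy strictly exceeds the threshold.

    Records that year's search and control spend in ``ledger`` (if given),
    zeroes treated occupancies, and resets their maturity clocks. Returns a
    new state; with a no-control policy the input state is returned as-is.
    """
    if policy.is_no_control:
        return state
    occ = state.occupancy
    treated = landscape.forested & (occ > policy.threshold)
    if not treated.any():
        return state
    occ_treated = occ[treated]
    search = search_cost(occ_treated, cost_params)
    cells = _ArrayCells(landscape.area_ha[treated])
    control = control_cost(cells, occ_treated, cost_params.control_a, cost_params.control_b)
    if ledger is not None:
        ledger.add_treatment(year, treated, np.atleast_1d(search), np.atleast_1d(control))
    new = state.copy()
    new.occupancy[treated] = 0.0
    new.colonized_year[treated] = NEVER
    return new


class _ArrayCells:
    """Array stand-in with the attribute surface the cost functions need."""

    __slots__ = ("area_ha",)

    def __init__(self, area_ha: np.ndarray):
        self.area_ha = area_ha
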