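"""Damage, search, and control cost functions plus present-value accounting.

Embeds the published productivity lookup (class code -> kg/ha/yr), the
timber-class harvest shares and stumpage prices used for the weighted
market price, and the control-cost brackets from which the exponential
unit-cost curve is fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .landscape import PRODUCTIVITY_KG_BY_CLASS

__all__ = [
    "KG_PER_SHORT_TON",
    "M3_PER_SHORT_TON",
    "SEARCH_RATE_PER_HA",
    "SEARCH_MAX_DEFAULT",
    "CONTROL_BRACKET_POINTS",
    "TIMBER_CLASSES",
    "TimberTables",
    "DEFAULT_TABLES",
    "weighted_market_price",
    "CostParams",
    "ControlFit",
    "fit_control_curve",
    "damage_cost",
    "search_cost",
    "control_cost",
    "unit_control_cost",
    "CostLedger",
    "present_value",
    "expected_total_cost",
]

KG_PER_SHORT_TON = 907.18
M3_PER_SHORT_TON = 3.02

#: Search rate: $8/acre converted to $/ha (8 / 0.404686, 2 dp).
SEARCH_RATE_PER_HA = 19.77

#: Canonical full-plot search cost: the per-hectare rate over a 2,428 ha
#: cell, rounded to the nearest $1,000.
SEARCH_MAX_DEFAULT = 48_000.0

#: Contractor bracket endpoints (percent invaded, $/ha) used to calibrate
#: the exponential control unit-cost curve.
CONTROL_BRACKET_POINTS: tuple[tuple[float, float], ...] = (
    (1.0, 111.0),
    (25.0, 210.0),
    (60.0, 457.0),
    (100.0, 1446.0),
)

#: Timber class -> (harvest share %, stumpage price $/kg).
TIMBER_CLASSES: dict[str, tuple[float, float]] = {
    "pine_sawtimber": (34.63, 0.0405),
    "pine_chip_n_saw": (18.02, 0.0245),
    "pine_pulpwood": (25.51, 0.0077),
    "mixed_hardwood_sawtimber": (9.58, 0.0223),
    "mixed_hardwood_pulpwood": (12.26, 0.0065),
}


@dataclass(frozen=True)
class TimberTables:
    """Embedded productivity and timber-class constants."""

    productivity_kg: dict[int, float] = field(
        default_factory=lambda: dict(PRODUCTIVITY_KG_BY_CLASS)
    )
    timber_classes: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(TIMBER_CLASSES)
    )
    kg_per_short_ton: float = KG_PER_SHORT_TON
    m3_per_short_ton: float = M3_PER_SHORT_TON

    def __post_init__(self) -> None:
        shares = [s for s, _ in self.timber_classes.values()]
        if abs(sum(shares) - 100.0) > 0.01:
            raise ValueError(f"harvest shares must sum to 100 +- 0.01, got {sum(shares)}")
        if any(p < 0 for _, p in self.timber_classes.values()):
            raise ValueError("stumpage prices must be >= 0")
        codes = sorted(self.productivity_kg)
        values = [self.productivity_kg[c] for c in codes]
        if any(later >= earlier for earlier, later in zip(values[:-1], values[1:])):
            raise ValueError("productivity must be strictly decreasing in class code")


DEFAULT_TABLES = TimberTables()


def weighted_market_price(tables: TimberTables = DEFAULT_TABLES) -> float:
    """Harvest-share-weighted mean stumpage price ($/kg), rounded to 4 dp."""
    return round(
        sum(share / 100.0 * price for share, price in tables.timber_classes.values()), 4
    )


class ControlFit(NamedTuple):
    a: float  # $/ha at 0% invaded
    b: float  # per percent invaded
    log_rmse: float


def fit_control_curve(points: Sequence[tuple[float, float]]) -> ControlFit:
    """Least-squares fit of ln(cost) = ln(a) + b * percent.

    ``points`` are (percent invaded, $/ha) calibration pairs; two points
    determine the line exactly, three or more give a least-squares fit.
    Returns (a, b, in-sample log-RMSE).
    """
    if len(points) < 2:
        raise ValueError("need at least 2 calibration points (3+ for an overdetermined fit)")
    pct = np.array([p for p, _ in points], dtype=float)
    cost = np.array([c for _, c in points], dtype=float)
    if np.any(cost <= 0):
        raise ValueError("calibration costs must be positive")
    b, ln_a = np.polyfit(pct, np.log(cost), 1)
    resid = np.log(cost) - (ln_a + b * pct)
    return ControlFit(a=float(np.exp(ln_a)), b=float(b), log_rmse=float(np.sqrt(np.mean(resid**2))))


@dataclass
class CostParams:
    """All economic constants for a run.

    ``control_a`` / ``control_b`` default to the log-linear fit of the
    embedded contractor brackets; pass explicit values to override.
    """

    discount_rate: float = 0.05
    harvest_cycle: int = 20
    search_max: float = SEARCH_MAX_DEFAULT
    search_kink_pct: float = 1.0
    search_form: str = "inverse"  # inverse | linear | exponential
    search_floor: float = 0.0
    control_a: Optional[float] = None
    control_b: Optional[float] = None
    control_brackets: tuple[tuple[float, float], ...] = CONTROL_BRACKET_POINTS
    control_fit: ControlFit = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.discount_rate < 1.0:
            raise ValueError(f"discount_rate must be in (0, 1), got {self.discount_rate}")
        if self.harvest_cycle < 1:
            raise ValueError("harvest_cycle must be >= 1")
        if self.search_max <= 0:
            raise ValueError("search_max must be positive")
        if self.search_form not in {"inverse", "linear", "exponential"}:
            raise ValueError(f"unknown search_form {self.search_form!r}")
        self.control_fit = fit_control_curve(self.control_brackets)
        if self.control_a is None:
            self.control_a = self.control_fit.a
        if self.control_b is None:
            self.control_b = self.control_fit.b
        if self.control_a <= 0 or self.control_b < 0:
            raise ValueError("control curve must have a > 0 and b >= 0")


# -- per-cell cost functions ------------------------------------------


def damage_cost(cell, occupancy_pct: float) -> float:
    """Annual timber value lost: invaded ha * productivity * price.

    ``cell`` needs ``area_ha``, ``productivity_kg`` and ``market_price``
    attributes (a Cell or any array-backed stand-in).
    """
    occ = np.asarray(occupancy_pct, dtype=float)
    if np.any((occ < 0.0) | (occ > 100.0)):
        raise ValueError("occupancy_pct outside [0, 100]")
    out = occ / 100.0 * np.asarray(cell.area_ha) * np.asarray(cell.productivity_kg) * np.asarray(
        cell.market_price
    )
    return float(out) if out.ndim == 0 else out


def search_cost(occupancy_pct, params: CostParams):
    """Cost of delineating an invasion in one cell before treatment.

    Decreasing in invasion extent; equal to ``search_max`` at or below the
    kink (default 1% occupancy). The default form is inverse-proportional,
    continuous at the kink; "linear" and "exponential" alternatives share
    the same anchor and endpoint.
    """
    occ = np.asarray(occupancy_pct, dtype=float)
    if np.any(occ <= 0.0):
        raise ValueError("search_cost is defined for occupancy > 0 only")
    kink = params.search_kink_pct
    if params.search_form == "inverse":
        above = params.search_max * kink / occ
    elif params.search_form == "linear":
        above = params.search_max * (100.0 - occ) / (100.0 - kink)
    else:  # exponential decay, matched to the inverse form's 100% endpoint
        k = math.log(100.0 / kink) / (100.0 - kink)
        above = params.search_max * np.exp(-k * (occ - kink))
    out = np.maximum(np.where(occ <= kink, params.search_max, above), params.search_floor)
    return float(out) if out.ndim == 0 else out


def unit_control_cost(occupancy_pct, a: float, b: float):
    """Exponential treatment cost per invaded hectare: a * exp(b * pct)."""
    occ = np.asarray(occupancy_pct, dtype=float)
    out = a * np.exp(b * occ)
    return float(out) if out.ndim == 0 else out


def control_cost(cell, occupancy_pct, a: float, b: float):
    """Treatment cost for one cell: unit cost ($/ha) times invaded hectares."""
    occ = np.asarray(occupancy_pct, dtype=float)
    if np.any(occ <= 0.0):
        raise ValueError("control_cost is defined for occupancy > 0 only")
    out = unit_control_cost(occ, a, b) * occ / 100.0 * np.asarray(cell.area_ha)
    return float(out) if out.ndim == 0 else out


# -- ledger and discounting -------------------------------------------


class CostLedger:
    """Per-cell, per-year nominal damage/search/control records.

    Row index t = year - first_year; the discount factor for row t is
    (1 + rho)^-t, so first-year costs are undiscounted.
    """

    COMPONENTS = ("damage", "search", "control")

    def __init__(self, n_years: int, n_cells: int, first_year: int = 1,
                 cell_ids: Optional[np.ndarray] = None):
        self.n_years = int(n_years)
        self.n_cells = int(n_cells)
        self.first_year = int(first_year)
        self.cell_ids = (
            np.arange(n_cells, dtype=np.int64) if cell_ids is None else np.asarray(cell_ids)
        )
        self.damage = np.zeros((n_years, n_cells))
        self.search = np.zeros((n_years, n_cells))
        self.control = np.zeros((n_years, n_cells))

    def _row(self, year: int) -> int:
        t = year - self.first_year
        if not 0 <= t < self.n_years:
            raise IndexError(f"year {year} outside ledger range")
        return t

    def add_damage(self, year: int, values: np.ndarray) -> None:
        if np.any(np.asarray(values) < 0):
            raise ValueError("ledger entries must be >= 0")
        self.damage[self._row(year)] += values

    def add_treatment(self, year: int, mask: np.ndarray, search: np.ndarray,
                      control: np.ndarray) -> None:
        """Record search + control spend for the treated cells of one year."""
        if np.any(np.asarray(search) < 0) or np.any(np.asarray(control) < 0):
            raise ValueError("ledger entries must be >= 0")
        t = self._row(year)
        self.search[t, mask] += search
        self.control[t, mask] += control

    def nominal_by_year(self) -> dict[str, np.ndarray]:
        return {c: getattr(self, c).sum(axis=1) for c in self.COMPONENTS}

    def discount_factors(self, rho: float) -> np.ndarray:
        return (1.0 + rho) ** -np.arange(self.n_years, dtype=float)

    def discounted_components(self, rho: float) -> dict[str, float]:
        f = self.discount_factors(rho)
        return {c: float(f @ getattr(self, c).sum(axis=1)) for c in self.COMPONENTS}

    def to_frame(self, rho: Optional[float] = None) -> pd.DataFrame:
        """Tidy export: cell_id, year, damage, search, control, discount_factor."""
        years = self.first_year + np.arange(self.n_years)
        idx_year = np.repeat(years, self.n_cells)
        idx_cell = np.tile(self.cell_ids, self.n_years)
        df = pd.DataFrame(
            {
                "cell_id": idx_cell,
                "year": idx_year,
                "damage": self.damage.ravel(),
                "search": self.search.ravel(),
                "control": self.control.ravel(),
            }
        )
        if rho is not None:
            df["discount_factor"] = np.repeat(self.discount_factors(rho), self.n_cells)
        return df


def present_value(ledger: CostLedger, rho: float) -> float:
    """Discounted total cost: sum over cells and years of (D+S+C)/(1+rho)^t."""
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    f = ledger.discount_factors(rho)
    total = ledger.damage + ledger.search + ledger.control
    return float(f @ total.sum(axis=1))


def expected_total_cost(ledgers: Iterable[CostLedger], rho: float) -> tuple[float, float]:
    """Replicate mean and standard error of the discounted total cost."""
    pvs = np.array([present_value(ledger, rho) for ledger in ledgers])
    if pvs.size < 2:
        return float(pvs.mean()), 0.0
    return float(pvs.mean()), float(pvs.std(ddof=1) / math.sqrt(pvs.size))
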