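"""Monte Carlo engine: yearly replicate loop, scenario summaries, and the
control-threshold sweep with common random numbers.

Year loop (per replicate): dispersal/growth step -> damage accrual on the
post-spread, pre-control occupancy -> control decision and search+control
accrual. Invaded area is recorded post-control (end-of-year state).
Discounting uses t = 0 for the first simulated year.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .economics import CostLedger, CostParams, damage_cost
from .landscape import DEFAULT_CUTOFF_M, Landscape, build_neighbor_index
from .management import Policy, apply_control
from .spread import DEFAULT_X_COLONIZE, KernelParams, SpreadState, step_year

__all__ = [
    "RunConfig",
    "Trajectory",
    "MonteCarloResult",
    "SweepResult",
    "run_replicate",
    "run_monte_carlo",
    "threshold_sweep",
]

SeedLike = Union[int, Sequence[int]]


@dataclass
class RunConfig:
    """Everything needed to reproduce a simulation run."""

    years: int = 20
    replicates: int = 240
    seed: int = 0
    policy: Policy = field(default_factory=lambda: Policy.named("NC"))
    kernel: KernelParams = field(default_factory=KernelParams)
    cost: CostParams = field(default_factory=CostParams)
    x_colonize: float = DEFAULT_X_COLONIZE
    cutoff_m: float = DEFAULT_CUTOFF_M
    snapshot_years: tuple[int, ...] = ()
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        """Build from the JSON run-config schema (see README)."""
        known = {"years", "replicates", "seed", "policy", "spread", "economics",
                 "snapshot_years", "out_dir"}
        unknown = set(cfg) - known - {"synthetic"}
        if unknown:
            raise ValueError(f"unknown config key: {sorted(unknown)[0]!r}")
        spread_cfg = dict(cfg.get("spread", {}))
        x_col = spread_cfg.pop("x_colonize", DEFAULT_X_COLONIZE)
        cutoff = spread_cfg.pop("cutoff_m", DEFAULT_CUTOFF_M)
        try:
            kernel = KernelParams(**spread_cfg)
        except TypeError as exc:
            raise ValueError(f"bad 'spread' config: {exc}") from exc
        try:
            cost = CostParams(**cfg.get("economics", {}))
        except TypeError as exc:
            raise ValueError(f"bad 'economics' config: {exc}") from exc
        return cls(
            years=int(cfg.get("years", 20)),
            replicates=int(cfg.get("replicates", 240)),
            seed=int(cfg.get("seed", 0)),
            policy=Policy.from_config(cfg.get("policy")),
            kernel=kernel,
            cost=cost,
            x_colonize=float(x_col),
            cutoff_m=float(cutoff),
            snapshot_years=tuple(cfg.get("snapshot_years", ())),
            out_dir=cfg.get("out_dir"),
        )


@dataclass
class Trajectory:
    """Per-year totals for one replicate.

    Component arrays hold *nominal* dollars per simulated year (index 0 is
    year 1); discounting is applied on demand so one trajectory can be
    re-discounted at any rate.
    """

    years: np.ndarray
    invaded_ha: np.ndarray
    damage: np.ndarray
    search: np.ndarray
    control: np.ndarray
    discount_rate: float = 0.05
    snapshots: dict[int, np.ndarray] = field(default_factory=dict)
    ledger: Optional[CostLedger] = None

    def discount_factors(self, rho: Optional[float] = None) -> np.ndarray:
        rho = self.discount_rate if rho is None else rho
        return (1.0 + rho) ** -np.arange(self.years.size, dtype=float)

    def pv_components(self, rho: Optional[float] = None) -> dict[str, float]:
        f = self.discount_factors(rho)
        return {
            "damage": float(f @ self.damage),
            "search": float(f @ self.search),
            "control": float(f @ self.control),
        }

    def total_pv(self, rho: Optional[float] = None) -> float:
        return sum(self.pv_components(rho).values())

    def cumulative_pv(self, rho: Optional[float] = None) -> np.ndarray:
        f = self.discount_factors(rho)
        return np.cumsum(f * (self.damage + self.search + self.control))

    def to_frame(self, replicate: int = 0) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate": replicate,
                "year": self.years,
                "invaded_ha": self.invaded_ha,
                "damage": self.damage,
                "search": self.search,
                "control": self.control,
                "total_pv": self.cumulative_pv(),
            }
        )


def _year_rng(seed: SeedLike, year: int) -> np.random.Generator:
    # per-year substream from the replicate seed: trajectories never depend
    # on how many draws earlier years consumed
    parts = [seed] if isinstance(seed, (int, np.integer)) else list(seed)
    return np.random.default_rng([int(p) for p in parts] + [year])


def run_replicate(landscape: Landscape, config: RunConfig, seed: SeedLike,
                  keep_ledger: bool = False) -> Trajectory:
    """Run one replicate; deterministic given (landscape, config, seed)."""
    if landscape.neighbors is None or landscape.neighbors.cutoff_m != config.cutoff_m:
        build_neighbor_index(landscape, config.cutoff_m)
    n, Y = len(landscape), config.years
    state = SpreadState.from_landscape(landscape, year=0)
    ledger = CostLedger(Y, n, first_year=1, cell_ids=landscape.cell_id)
    invaded_ha = np.zeros(Y)
    snapshots: dict[int, np.ndarray] = {}
    for year in range(1, Y + 1):
        rng = _year_rng(seed, year)
        state = step_year(state, landscape, config.kernel, rng, x_colonize=config.x_colonize)
        ledger.add_damage(year, damage_cost(landscape, state.occupancy))
        state = apply_control(state, landscape, config.policy, year, ledger, config.cost)
        invaded_ha[year - 1] = landscape.invaded_area_ha(state.occupancy)
        if year in config.snapshot_years:
            snapshots[year] = state.occupancy.copy()
    nominal = ledger.nominal_by_year()
    return Trajectory(
        years=np.arange(1, Y + 1),
        invaded_ha=invaded_ha,
        damage=nominal["damage"],
        search=nominal["search"],
        control=nominal["control"],
        discount_rate=config.cost.discount_rate,
        snapshots=snapshots,
        ledger=ledger if keep_ledger else None,
    )


def replicate_seeds(root_seed: int, replicates: int) -> list[tuple[int, int]]:
    """Replicate seed tuples derived from the root seed only, so threshold
    sweeps can reuse them as common random numbers across policies."""
    return [(int(root_seed), rep) for rep in range(replicates)]


@dataclass
class MonteCarloResult:
    """Replicate trajectories plus per-year mean +- SE summaries."""

    policy: Policy
    trajectories: list[Trajectory]
    discount_rate: float

    @property
    def years(self) -> np.ndarray:
        return self.trajectories[0].years

    def _stack(self, attr: str) -> np.ndarray:
        return np.stack([getattr(t, attr) for t in self.trajectories])

    @staticmethod
    def _mean_se(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mean = arr.mean(axis=0)
        if arr.shape[0] < 2:
            return mean, np.zeros_like(mean)
        return mean, arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])

    def invaded_ha_summary(self) -> tuple[np.ndarray, np.ndarray]:
        return self._mean_se(self._stack("invaded_ha"))

    def cumulative_pv_summary(self, rho: Optional[float] = None) -> tuple[np.ndarray, np.ndarray]:
        return self._mean_se(np.stack([t.cumulative_pv(rho) for t in self.trajectories]))

    def total_pv(self, rho: Optional[float] = None) -> tuple[float, float]:
        totals = np.array([t.total_pv(rho) for t in self.trajectories])
        m, s = self._mean_se(totals[:, None])
        return float(m[0]), float(s[0])

    def pv_component_means(self, rho: Optional[float] = None) -> dict[str, float]:
        comps = [t.pv_components(rho) for t in self.trajectories]
        return {k: float(np.mean([c[k] for c in comps])) for k in ("damage", "search", "control")}

    def summary_frame(self) -> pd.DataFrame:
        inv_m, inv_se = self.invaded_ha_summary()
        pv_m, pv_se = self.cumulative_pv_summary()
        return pd.DataFrame(
            {
                "year": self.years,
                "mean_invaded_ha": inv_m,
                "se_invaded_ha": inv_se,
                "mean_total_pv": pv_m,
                "se_total_pv": pv_se,
            }
        )

    def trajectory_frame(self) -> pd.DataFrame:
        return pd.concat(
            [t.to_frame(replicate=i) for i, t in enumerate(self.trajectories)],
            ignore_index=True,
        )


def run_monte_carlo(landscape: Landscape, config: RunConfig) -> MonteCarloResult:
    """Run ``config.replicates`` seeded replicates and summarize them."""
    seeds = replicate_seeds(config.seed, config.replicates)
    trajectories = [run_replicate(landscape, config, s) for s in seeds]
    return MonteCarloResult(
        policy=config.policy,
        trajectories=trajectories,
        discount_rate=config.cost.discount_rate,
    )


@dataclass
class SweepResult:
    """Expected total cost (and components) as a function of the threshold."""

    table: pd.DataFrame  # threshold, mean/se total, component means
    results: dict[object, MonteCarloResult]

    @property
    def argmin_threshold(self) -> Optional[float]:
        """Cost-minimizing numeric threshold; ties break toward larger
        thresholds (less intervention)."""
        numeric = self.table[self.table["threshold"].notna()]
        if numeric.empty:
            return None
        best = numeric["mean_total_pv"].min()
        return float(numeric.loc[numeric["mean_total_pv"] == best, "threshold"].max())


def threshold_sweep(
    landscape: Landscape,
    config: RunConfig,
    thresholds: Sequence[Optional[float]],
) -> SweepResult:
    """One Monte Carlo run per threshold with common random numbers.

    ``None`` entries mean no control. Replicate seeds depend only on the
    root seed, so every threshold sees identical colonization randomness.
    """
    if len(thresholds) < 1:
        raise ValueError("need at least one threshold")
    rows = []
    results: dict[object, MonteCarloResult] = {}
    for theta in thresholds:
        policy = Policy.from_config(theta)
        mc = run_monte_carlo(landscape, replace(config, policy=policy))
        mean_pv, se_pv = mc.total_pv()
        comps = mc.pv_component_means()
        rows.append(
            {
                "threshold": np.nan if theta is None else float(theta),
                "mean_total_pv": mean_pv,
                "se_total_pv": se_pv,
                "mean_damage_pv": comps["damage"],
                "mean_search_pv": comps["search"],
                "mean_control_pv": comps["control"],
            }
        )
        results[theta] = mc
    return SweepResult(table=pd.DataFrame(rows), results=results)
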