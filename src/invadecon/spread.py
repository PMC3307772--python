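"""Annual occupancy update: logistic within-cell growth plus lognormal
dispersal with probabilistic colonization and a 3-year maturation delay.

Each forested cell grows logistically toward a 100% carrying capacity. A
mature source (colonized at least ``MATURATION_YEARS`` ago) retains
``local_fraction`` of its annual growth increment and exports the rest,
distributed over neighboring cells by the per-cell landing mass of a
radial lognormal kernel. Uninvaded cells colonize probabilistically, with
per-source probability equal to the kernel mass landing on the cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .landscape import DEFAULT_CUTOFF_M, NEVER, Landscape, build_neighbor_index

__all__ = [
    "MATURATION_YEARS",
    "DEFAULT_X_COLONIZE",
    "CARRYING_CAPACITY",
    "KernelParams",
    "SpreadState",
    "logistic_increment",
    "kernel_cell_mass",
    "step_year",
]

#: Years after colonization before a cell can export propagules
#: (seed production starts at age 3).
MATURATION_YEARS = 3

#: Occupancy (percent) assigned to a newly colonized cell: one detectable
#: foothold in a ~2,400 ha cell.
DEFAULT_X_COLONIZE = 0.1

#: Carrying capacity on the percent-occupancy scale, identical for all cells.
CARRYING_CAPACITY = 100.0


@dataclass(frozen=True)
class KernelParams:
    """Lognormal dispersal kernel parameters.

    mu, sigma parameterize the log of dispersal distance in meters; the
    default median exp(mu) = 1,200 m matches the invasion velocity the
    calibrated model is known to produce. ``local_fraction`` is the share
    of a source's recruitment increment retained in the source cell.
    """

    mu: float = math.log(1200.0)
    sigma: float = 1.0
    local_fraction: float = 0.9

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not 0.0 <= self.local_fraction <= 1.0:
            raise ValueError(f"local_fraction must be in [0, 1], got {self.local_fraction}")


@dataclass
class SpreadState:
    """Occupancy and maturity-clock state at an integer year."""

    year: int
    occupancy: np.ndarray  # percent, shape (n_cells,)
    colonized_year: np.ndarray  # int year of latest colonization, NEVER if none

    @classmethod
    def from_landscape(cls, landscape: Landscape, year: int = 0) -> "SpreadState":
        return cls(
            year=year,
            occupancy=landscape.occupancy_pct.astype(float).copy(),
            colonized_year=landscape.colonized_year.astype(np.int64).copy(),
        )

    def copy(self) -> "SpreadState":
        return SpreadState(self.year, self.occupancy.copy(), self.colonized_year.copy())

    def mature_mask(self) -> np.ndarray:
        """Cells colonized at least MATURATION_YEARS before the current year."""
        colonized = self.colonized_year != NEVER
        return colonized & (self.year - self.colonized_year >= MATURATION_YEARS)

    def invaded_mask(self) -> np.ndarray:
        return self.occupancy > 0.0


def logistic_increment(x, r, K: float = CARRYING_CAPACITY):
    """Annual logistic growth increment r*x*(1 - x/K) on the percent scale.

    Accepts scalars or arrays; raises on occupancy outside [0, K] or r < 0.
    """
    x = np.asarray(x, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any((x < 0.0) | (x > K)):
        raise ValueError(f"occupancy outside [0, {K}]")
    if np.any(r < 0.0):
        raise ValueError("growth rate must be >= 0")
    out = r * x * (1.0 - x / K)
    return float(out) if out.ndim == 0 else out


def kernel_cell_mass(distance_m, cell_side_m: float, params: KernelParams):
    """Fraction of a source's dispersed recruitment landing in a target cell.

    Point approximation: the radial lognormal density at distance d is
    spread uniformly over the annulus of radius d, then integrated over the
    target footprint: density(d) / (2*pi*d) * cell_side^2. Summed over a
    fine global tiling these masses integrate to 1 (minus truncation loss).

    Self-dispersal is handled by ``local_fraction``, not the kernel, so
    d <= 0 is a domain error.
    """
    d = np.asarray(distance_m, dtype=float)
    if np.any(d <= 0.0):
        raise ValueError("distance_m must be > 0 (self-dispersal is local_fraction)")
    if cell_side_m <= 0:
        raise ValueError("cell_side_m must be > 0")
    log_d = np.log(d)
    dens = np.exp(-((log_d - params.mu) ** 2) / (2.0 * params.sigma**2)) / (
        d * params.sigma * math.sqrt(2.0 * math.pi)
    )
    mass = dens / (2.0 * math.pi * d) * cell_side_m**2
    return float(mass) if mass.ndim == 0 else mass


def _dispersal_matrices(
    landscape: Landscape, params: KernelParams
) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """(W, L): W[i, j] = kernel mass from source j landing on cell i;
    L[i, j] = log(1 - clip(W[i, j])) for the multi-source colonization
    probability. Cached on the landscape per (kernel, neighbor index).
    """
    if landscape.neighbors is None:
        build_neighbor_index(landscape, DEFAULT_CUTOFF_M)
    nbr = landscape.neighbors
    key = (params.mu, params.sigma, id(nbr))
    cached = landscape._kernel_cache.get(key)
    if cached is not None:
        return cached
    n = len(landscape)
    # neighbor rows are per-source lists; masses use the *target* footprint,
    # which equals the lattice spacing for every cell here
    mass = (
        kernel_cell_mass(nbr.distances, landscape.spacing_m, params)
        if nbr.distances.size
        else np.empty(0)
    )
    # rows of the neighbor index are "source s -> targets t"; W wants
    # rows = targets, so transpose the CSR built from the index
    w_src = sp.csr_matrix(
        (mass, nbr.indices.copy(), nbr.indptr.copy()), shape=(n, n)
    )  # w_src[s, t]
    W = w_src.T.tocsr()
    logq = np.log1p(-np.clip(W.data, 0.0, 1.0 - 1e-12))
    L = sp.csr_matrix((logq, W.indices.copy(), W.indptr.copy()), shape=(n, n))
    landscape._kernel_cache[key] = (W, L)
    return W, L


def step_year(
    state: SpreadState,
    landscape: Landscape,
    params: KernelParams,
    rng: np.random.Generator,
    x_colonize: float = DEFAULT_X_COLONIZE,
    K: float = CARRYING_CAPACITY,
) -> SpreadState:
    """Advance the invasion one year; returns a new state (input untouched).

    Synchronous update from the year-t state:

    1. every invaded forested cell computes its logistic increment;
    2. mature sources keep ``local_fraction`` of it and export the rest via
       the kernel; immature sources keep the whole increment and export
       nothing;
    3. already-invaded recipients add incoming mass deterministically;
    4. uninvaded forested recipients colonize with probability
       1 - prod_j (1 - p_ij) over active sources j, where p_ij is the
       kernel mass from j (clamped to [0, 1]); a colonized cell starts at
       ``x_colonize`` with its maturity clock reset;
    5. occupancies are clamped to [0, K]; non-forested cells absorb
       dispersal mass but never colonize.
    """
    W, L = _dispersal_matrices(landscape, params)
    x = state.occupancy
    forested = landscape.forested
    growth = logistic_increment(x, landscape.max_spread_rate, K)
    growth = np.where(forested, growth, 0.0)

    mature = state.mature_mask()
    exporting = mature & (x > 0.0) & (growth > 0.0) & (params.local_fraction < 1.0)

    kept = np.where(exporting, params.local_fraction * growth, growth)
    exported = np.where(exporting, (1.0 - params.local_fraction) * growth, 0.0)
    incoming = W @ exported

    invaded = state.invaded_mask()
    new_x = x + kept
    new_x[invaded] += incoming[invaded]

    # colonization of empty forested cells
    log_no_invasion = L @ exporting.astype(float)
    p_colonize = -np.expm1(log_no_invasion)
    candidates = forested & ~invaded
    draws = rng.random(len(new_x))  # full-length draw: iteration-order stable
    colonized = candidates & (draws < p_colonize)

    new_colyear = state.colonized_year.copy()
    new_x[colonized] = x_colonize
    new_colyear[colonized] = state.year + 1

    np.clip(new_x, 0.0, K, out=new_x)
    new_x[~forested] = 0.0
    return SpreadState(year=state.year + 1, occupancy=new_x, colonized_year=new_colyear)
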