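"""Domain types for lattice landscapes: cells, neighbor geometry, file I/O.

A landscape is a columnar container of square cells with projected planar
coordinates (meters). Distances are Euclidean center-to-center. The
canonical cell is a 4,927 m square (2,428 ha to the nearest hectare),
matching a national forest-inventory sampling grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Union

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "Cell",
    "Landscape",
    "NeighborIndex",
    "SchemaError",
    "ValidationError",
    "NEVER",
    "PRODUCTIVITY_KG_BY_CLASS",
    "DEFAULT_MARKET_PRICE",
    "DEFAULT_CELL_SIDE_M",
    "CANONICAL_CELL_AREA_HA",
    "DEFAULT_CUTOFF_M",
    "productivity_for_class",
    "cell_area_ha",
    "load_landscape",
    "write_landscape",
    "landscape_to_geojson",
    "build_neighbor_index",
]

#: Sentinel year meaning "never colonized".
NEVER = -(10**9)

#: Annual timber productivity (kg/ha/yr) by productivity class code.
PRODUCTIVITY_KG_BY_CLASS: dict[int, float] = {
    1: 5536.98,
    2: 4102.30,
    3: 2981.45,
    4: 2152.03,
    5: 1412.27,
    6: 739.76,
    7: 201.75,
}

#: Default volume-weighted market price of standing timber ($/kg); the
#: published rounded constant, overridable per cell via a CSV column.
DEFAULT_MARKET_PRICE = 0.0234

DEFAULT_CELL_SIDE_M = 4927.0
CANONICAL_CELL_AREA_HA = 2428.0

#: Default dispersal neighbor cutoff: ~6 cell widths; kernel mass per cell
#: beyond this is negligible at default kernel parameters.
DEFAULT_CUTOFF_M = 30_000.0

REQUIRED_COLUMNS = (
    "cell_id",
    "x_m",
    "y_m",
    "forested",
    "max_spread_rate",
    "productivity_class",
    "occupancy_pct",
)
OPTIONAL_COLUMNS = ("market_price", "area_ha")


class SchemaError(ValueError):
    """A landscape table is missing a required column."""


class ValidationError(ValueError):
    """A landscape row violates a domain invariant."""


def productivity_for_class(code: int) -> float:
    """Annual timber productivity (kg/ha/yr) for a class code in 1..7."""
    try:
        return PRODUCTIVITY_KG_BY_CLASS[int(code)]
    except (KeyError, ValueError) as exc:
        raise ValidationError(f"unknown productivity class {code!r}; expected 1..7") from exc


def cell_area_ha(side_m: float, nearest: bool = True) -> float:
    """Area (ha) of a square cell of side ``side_m`` meters.

    With ``nearest=True`` (the canonical form) the value is rounded to the
    nearest hectare: 4,927 m -> 2,428 ha.
    """
    if side_m <= 0:
        raise ValueError(f"side_m must be positive, got {side_m}")
    area = side_m * side_m / 10_000.0
    return float(round(area)) if nearest else area


@dataclass
class Cell:
    """One landscape unit carrying habitat, timber, and occupancy state."""

    cell_id: int
    x_m: float
    y_m: float
    forested: bool
    max_spread_rate: float
    productivity_class: int
    occupancy_pct: float = 0.0
    market_price: float = DEFAULT_MARKET_PRICE
    area_ha: float = CANONICAL_CELL_AREA_HA
    colonized_year: Optional[int] = None  # None == never colonized

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy_pct <= 100.0:
            raise ValidationError(
                f"cell {self.cell_id}: occupancy_pct {self.occupancy_pct} outside [0, 100]"
            )
        if self.area_ha <= 0:
            raise ValidationError(f"cell {self.cell_id}: area_ha must be positive")
        if self.max_spread_rate < 0:
            raise ValidationError(f"cell {self.cell_id}: max_spread_rate must be >= 0")
        productivity_for_class(self.productivity_class)
        if not self.forested and self.occupancy_pct != 0.0:
            raise ValidationError(
                f"cell {self.cell_id}: non-forested cell must have occupancy 0"
            )

    @property
    def productivity_kg(self) -> float:
        return productivity_for_class(self.productivity_class)


@dataclass
class NeighborIndex:
    """CSR-style per-cell neighbor lists within a cutoff radius.

    Rows are sorted by distance; a cell is never its own neighbor.
    """

    cutoff_m: float
    indptr: np.ndarray
    indices: np.ndarray
    distances: np.ndarray

    def neighbors_of(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """(neighbor indices, center-to-center distances in m) for cell ``i``."""
        lo, hi = self.indptr[i], self.indptr[i + 1]
        return self.indices[lo:hi], self.distances[lo:hi]

    @property
    def n_pairs(self) -> int:
        return int(self.indices.size)


@dataclass
class Landscape:
    """Columnar collection of cells plus pairwise-distance machinery."""

    cell_id: np.ndarray
    x_m: np.ndarray
    y_m: np.ndarray
    forested: np.ndarray
    max_spread_rate: np.ndarray
    productivity_class: np.ndarray
    productivity_kg: np.ndarray
    market_price: np.ndarray
    occupancy_pct: np.ndarray
    area_ha: np.ndarray
    colonized_year: np.ndarray
    spacing_m: float = DEFAULT_CELL_SIDE_M
    neighbors: Optional[NeighborIndex] = None
    _kernel_cache: dict = field(default_factory=dict, repr=False, compare=False)

    # -- construction -------------------------------------------------

    @classmethod
    def from_frame(cls, df: pd.DataFrame, spacing_m: Optional[float] = None) -> "Landscape":
        """Build and validate a landscape from a table with the CSV schema."""
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"missing required landscape column: {col!r}")
        cell_id = df["cell_id"].to_numpy(dtype=np.int64)
        if len(np.unique(cell_id)) != len(cell_id):
            raise ValidationError("cell_id values must be unique")
        occ = pd.to_numeric(df["occupancy_pct"], errors="coerce").fillna(0.0).to_numpy(float)
        bad = np.flatnonzero((occ < 0.0) | (occ > 100.0))
        if bad.size:
            raise ValidationError(
                f"cell {cell_id[bad[0]]}: occupancy_pct {occ[bad[0]]} outside [0, 100]"
            )
        pclass = df["productivity_class"].to_numpy(dtype=np.int64)
        if not np.isin(pclass, list(PRODUCTIVITY_KG_BY_CLASS)).all():
            bad_code = pclass[~np.isin(pclass, list(PRODUCTIVITY_KG_BY_CLASS))][0]
            raise ValidationError(f"unknown productivity class {bad_code}; expected 1..7")
        forested = df["forested"].astype(bool).to_numpy()
        if ((occ > 0) & ~forested).any():
            bad_id = cell_id[(occ > 0) & ~forested][0]
            raise ValidationError(f"cell {bad_id}: non-forested cell must have occupancy 0")
        rate = df["max_spread_rate"].to_numpy(float)
        if (rate < 0).any():
            bad_id = cell_id[rate < 0][0]
            raise ValidationError(f"cell {bad_id}: max_spread_rate must be >= 0")
        x = df["x_m"].to_numpy(float)
        y = df["y_m"].to_numpy(float)
        if spacing_m is None:
            spacing_m = _infer_spacing(x, y)
        if "market_price" in df.columns:
            price = df["market_price"].to_numpy(float)
        else:
            price = np.full(len(df), DEFAULT_MARKET_PRICE)
        if "area_ha" in df.columns:
            area = df["area_ha"].to_numpy(float)
            if (area <= 0).any():
                raise ValidationError("area_ha must be positive")
        else:
            area = np.full(len(df), cell_area_ha(spacing_m))
        if "colonized_year" in df.columns:
            colyr = df["colonized_year"].fillna(NEVER).to_numpy(dtype=np.int64)
        else:
            colyr = np.where(occ > 0, -3, NEVER).astype(np.int64)
        vkg = np.array([PRODUCTIVITY_KG_BY_CLASS[c] for c in pclass])
        return cls(
            cell_id=cell_id,
            x_m=x,
            y_m=y,
            forested=forested,
            max_spread_rate=rate,
            productivity_class=pclass,
            productivity_kg=vkg,
            market_price=price,
            occupancy_pct=occ,
            area_ha=area,
            colonized_year=colyr,
            spacing_m=float(spacing_m),
        )

    # -- accessors ----------------------------------------------------

    def __len__(self) -> int:
        return int(self.cell_id.size)

    @property
    def n_cells(self) -> int:
        return len(self)

    def cell(self, i: int) -> Cell:
        cy = int(self.colonized_year[i])
        return Cell(
            cell_id=int(self.cell_id[i]),
            x_m=float(self.x_m[i]),
            y_m=float(self.y_m[i]),
            forested=bool(self.forested[i]),
            max_spread_rate=float(self.max_spread_rate[i]),
            productivity_class=int(self.productivity_class[i]),
            occupancy_pct=float(self.occupancy_pct[i]),
            market_price=float(self.market_price[i]),
            area_ha=float(self.area_ha[i]),
            colonized_year=None if cy == NEVER else cy,
        )

    def iter_cells(self) -> Iterator[Cell]:
        return (self.cell(i) for i in range(len(self)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "x_m": self.x_m,
                "y_m": self.y_m,
                "forested": self.forested,
                "max_spread_rate": self.max_spread_rate,
                "productivity_class": self.productivity_class,
                "occupancy_pct": self.occupancy_pct,
                "market_price": self.market_price,
                "area_ha": self.area_ha,
            }
        )

    @property
    def total_area_ha(self) -> float:
        return float(self.area_ha.sum())

    def invaded_area_ha(self, occupancy: Optional[np.ndarray] = None) -> float:
        occ = self.occupancy_pct if occupancy is None else occupancy
        return float((occ / 100.0 * self.area_ha).sum())


def _infer_spacing(x: np.ndarray, y: np.ndarray) -> float:
    """Smallest positive coordinate gap, as a lattice-spacing guess."""
    if x.size < 2:
        return DEFAULT_CELL_SIDE_M
    ux = np.unique(np.diff(np.unique(x)))
    uy = np.unique(np.diff(np.unique(y)))
    gaps = np.concatenate([ux[ux > 0], uy[uy > 0]])
    return float(gaps.min()) if gaps.size else DEFAULT_CELL_SIDE_M


# -- file I/O ---------------------------------------------------------


def load_landscape(path: Union[str, Path]) -> Landscape:
    """Load a landscape from CSV (canonical) or GeoJSON.

    Productivity (kg/ha/yr) is filled from the class lookup; market price
    defaults to the embedded weighted constant unless a per-cell column is
    present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".geojson", ".json"}:
        with open(path) as fh:
            gj = json.load(fh)
        rows = [feat["properties"] for feat in gj["features"]]
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path, float_precision="round_trip")
    return Landscape.from_frame(df)


def write_landscape(landscape: Landscape, path: Union[str, Path]) -> Path:
    """Write the canonical CSV representation (round-trips exactly)."""
    path = Path(path)
    landscape.to_frame().to_csv(path, index=False)
    return path


def landscape_to_geojson(landscape: Landscape) -> dict:
    """FeatureCollection of square cell polygons mirroring the CSV columns."""
    half = landscape.spacing_m / 2.0
    features = []
    df = landscape.to_frame()
    for _, row in df.iterrows():
        x, y = row["x_m"], row["y_m"]
        ring = [
            [x - half, y - half],
            [x + half, y - half],
            [x + half, y + half],
            [x - half, y + half],
            [x - half, y - half],
        ]
        props = {k: (v.item() if isinstance(v, np.generic) else v) for k, v in row.items()}
        props["forested"] = bool(props["forested"])
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": props,
            }
        )
    return {"type": "FeatureCollection", "features": features}


# -- neighbor geometry ------------------------------------------------


def build_neighbor_index(landscape: Landscape, cutoff_m: float = DEFAULT_CUTOFF_M) -> Landscape:
    """Populate per-cell neighbor lists within ``cutoff_m`` (self excluded).

    Neighbors are sorted by distance within each cell's list. Returns the
    same landscape with ``landscape.neighbors`` set.
    """
    if cutoff_m <= 0:
        raise ValueError(f"cutoff_m must be positive, got {cutoff_m}")
    n = len(landscape)
    pts = np.column_stack([landscape.x_m, landscape.y_m])
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=cutoff_m, output_type="ndarray")
    if pairs.size:
        src = np.concatenate([pairs[:, 0], pairs[:, 1]])
        dst = np.concatenate([pairs[:, 1], pairs[:, 0]])
        d = np.hypot(pts[src, 0] - pts[dst, 0], pts[src, 1] - pts[dst, 1])
        order = np.lexsort((d, src))
        src, dst, d = src[order], dst[order], d[order]
        counts = np.bincount(src, minlength=n)
    else:
        src = dst = np.empty(0, dtype=np.int64)
        d = np.empty(0, dtype=float)
        counts = np.zeros(n, dtype=np.int64)
    indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    landscape.neighbors = NeighborIndex(
        cutoff_m=float(cutoff_m),
        indptr=indptr,
        indices=dst.astype(np.int64),
        distances=d,
    )
    landscape._kernel_cache.clear()
    return landscape
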