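import numpy as np
import pytest

from invadecon.landscape import (
    CANONICAL_CELL_AREA_HA,
    DEFAULT_CELL_SIDE_M,
    DEFAULT_MARKET_PRICE,
    NEVER,
    PRODUCTIVITY_KG_BY_CLASS,
    Landscape,
    build_neighbor_index,
)


def make_lattice(
    rows,
    cols,
    spacing=DEFAULT_CELL_SIDE_M,
    rate=0.6,
    pclass=4,
    forested=True,
    occupancy=None,
    colonized_year=None,
):
    """Homogeneous rectangular lattice for unit tests."""
    n = rows * cols
    rr, cc = np.divmod(np.arange(n), cols)
    occ = np.zeros(n) if occupancy is None else np.asarray(occupancy, dtype=float).copy()
    if colonized_year is None:
        colyr = np.where(occ > 0, -3, NEVER).astype(np.int64)
    else:
        colyr = np.asarray(colonized_year, dtype=np.int64).copy()
    return Landscape(
        cell_id=np.arange(n, dtype=np.int64),
        x_m=cc * spacing + spacing / 2.0,
        y_m=rr * spacing + spacing / 2.0,
        forested=np.full(n, forested, dtype=bool),
        max_spread_rate=np.full(n, rate, dtype=float),
        productivity_class=np.full(n, pclass, dtype=np.int64),
        productivity_kg=np.full(n, PRODUCTIVITY_KG_BY_CLASS[pclass]),
        market_price=np.full(n, DEFAULT_MARKET_PRICE),
        occupancy_pct=occ,
        area_ha=np.full(n, CANONICAL_CELL_AREA_HA),
        colonized_year=colyr,
        spacing_m=spacing,
    )


@pytest.fixture
def two_cell_landscape():
    """Two cells one lattice spacing apart; cell 0 invaded and mature."""
    land = make_lattice(1, 2, occupancy=[50.0, 0.0])
    return build_neighbor_index(land, 10_000.0)


@pytest.fixture
def grid3x3():
    return make_lattice(3, 3)
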