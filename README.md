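# invadecon

Spatially explicit, stochastic bioeconomic simulation of a woody invader
spreading across a square lattice of forest-inventory cells, coupled to
discounted damage / search / control cost accounting under threshold-based
control policies.

The model combines, per year and per cell:

- **logistic within-cell growth** of percent occupancy toward a 100%
  carrying capacity, at a per-cell maximum spread rate;
- **lognormal-kernel dispersal**: mature sources (colonized ≥ 3 years ago)
  export a share of their annual growth increment; uninvaded cells colonize
  probabilistically with per-source probability equal to the kernel mass
  landing on them;
- **economics**: annual timber-value damage on invaded hectares, a search
  cost that falls with invasion extent (anchored at $48,000 for a full-cell
  sweep at ≤ 1% occupancy), and an exponential per-hectare control cost fit
  to contractor price brackets;
- **policy**: every cell whose occupancy strictly exceeds a threshold θ is
  cleared to zero (NC = never, LC: θ=60, MC: θ=25, HC: θ=0), and can be
  re-invaded afterwards.

A synthetic landscape generator stands in for the proprietary inventory
data, so everything here runs self-contained.

## CLI

```bash
# generate a synthetic landscape (the "paper_like" preset, ~2,000 cells)
invadecon synth --rows 45 --cols 44 --seed 1 --out landscape.csv

# Monte Carlo simulation under a policy
invadecon simulate --landscape landscape.csv --config cfg.json --out run/

# threshold sweep with common random numbers, then a summary table
invadecon sweep --landscape landscape.csv --config cfg.json \
    --thresholds 0,1,2,5,10,15,25,40,60 --out sw/
invadecon report --sweep-csv sw/sweep.csv
```

Outputs: `trajectory.csv` (replicate, year, invaded_ha, damage, search,
control, total_pv), `summary.csv` (per-year mean ± SE), `sweep.csv`
(per-threshold expected cost and components), a `manifest.json`
reproducibility record, and optional GeoJSON occupancy maps
(`--geojson-maps` with `snapshot_years` in the config).

### JSON run config (all keys optional; defaults shown)

```json
{
  "years": 20,
  "replicates": 240,
  "seed": 0,
  "policy": {"name": "NC"},
  "spread": {
    "mu": 7.0900768,
    "sigma": 1.0,
    "local_fraction": 0.9,
    "x_colonize": 0.1,
    "cutoff_m": 30000
  },
  "economics": {
    "discount_rate": 0.05,
    "harvest_cycle": 20,
    "search_max": 48000,
    "search_kink_pct": 1.0,
    "search_form": "inverse",
    "search_floor": 0.0,
    "control_a": null,
    "control_b": null
  },
  "snapshot_years": []
}
```

Notes: `policy` also accepts `"MC"` or `{"threshold": 5}`; `mu` is the log
of the dispersal-distance median in meters (default median 1,200 m);
`control_a`/`control_b` default to the log-linear fit of the embedded
control-cost brackets (a ≈ 107.2 $/ha, b ≈ 0.0256 per percent);
`search_form` may be `inverse` (default), `linear`, or `exponential`.

### Landscape CSV schema

Required columns: `cell_id, x_m, y_m, forested, max_spread_rate,
productivity_class, occupancy_pct`; optional: `market_price, area_ha`.
Coordinates are projected planar meters; `productivity_class` is a code in
1..7 mapped to an embedded kg/ha/yr lookup; occupancy is percent of cell
area in [0, 100].

## Library use

```python
from invadecon import RunConfig, run_monte_carlo, threshold_sweep
from invadecon.synthetic import make_landscape, paper_like_spec

land = make_landscape(paper_like_spec(seed=1))
mc = run_monte_carlo(land, RunConfig(years=20, replicates=40, seed=1))
mean_pv, se_pv = mc.total_pv()
sweep = threshold_sweep(land, RunConfig(replicates=40, seed=1),
                        [0, 1, 2, 5, 10, 15, 25, 40, 60])
print(sweep.argmin_threshold)
```
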