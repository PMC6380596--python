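# cropgrid

Spatial downscaling of administrative crop statistics to pixel grids, with a
robustness-scenario driver and spatial-concordance scoring.

Administrative ("areal") crop statistics — harvested area, production and
yield per statistical reporting unit (SRU) — are allocated to a pixel grid by
one of two methods:

* **simple**: each crop's SRU harvested area is spread over pixels in
  proportion to each pixel's share of the SRU's cropland, with the SRU
  average yield assigned uniformly;
* **entropy**: informed priors (suitability x potential revenue x market
  access) are updated by a cross-entropy (minimum-KL) optimization subject to
  SRU totals, per-pixel cropland capacity, irrigated-area caps and optional
  suitability caps, per crop and production system (irrigated, rainfed
  high-input, rainfed low-input, rainfed subsistence).

Around the allocators sit:

* a **synthetic-landscape generator** (seeded, deterministic): nested
  contiguous admin units via balanced region growing, spatially
  autocorrelated cropland/suitability/population fields, a known ground-truth
  allocation, and SRU statistics aggregated from it at any admin level — so
  recovery experiments need no external data;
* a **scenario driver** running the baseline and eight single-toggle
  variants: simple-vs-entropy method, merged crop lists, passive
  rest-of-crops remainder, no suitability constraint, no market access, unit
  prices, and statistics degraded to ADM0/ADM1;
* **similarity scoring**: Gaussian focal pre-smoothing (default radius 1,
  sd 0.33), the bounded pixel similarity `1 - |a-b|/max(a,b)` over pixels
  where either surface is non-zero, crop-level means, harvested-area-weighted
  country scores, presence/absence shares (which can exceed 100% when an
  over-committed SRU's cropland had to be expanded), and a queen/rook
  Moran's I diagnostic.

## CLI

All commands are deterministic given `--seed` and write a `manifest.json`
with sha256 digests of every output.

```sh
# 1. generate a synthetic world (landscape, ancillary layers, truth, stats)
cropgrid simulate --rows 30 --cols 30 --adm1 3 --adm2 3 --n-crops 4 \
    --seed 1 --out data/

# 2. allocate statistics to pixels
cropgrid allocate --method entropy --stats data/stats.csv --data data/ \
    --out alloc/

# 3. run one scenario, or the full suite
cropgrid scenario --id adm0_only --data data/ --out scen/
cropgrid scenario-suite --data data/ --out suite/

# 4. score concordance (b is the baseline and provides the weights)
cropgrid compare --a suite/adm0_only --b suite/baseline --data data/ --out cmp/

# 5. every scenario vs the baseline, as a heatmap-ready long table
cropgrid report --suite suite/ --data data/ --out report/
```

Rasters travel as long-format CSV (`row,col,...`, full float precision),
tables as CSV, configuration as YAML (`EntropyConfig` keys), manifests as
JSON. Grids are row-major and 0-based; areas are hectares, production metric
tons, yields mt/ha.

## Layout

```
src/cropgrid/
  types.py       core domain types (Landscape, CropDefinition, SRU table
                 schema, EntropyConfig, AllocationResult, ...)
  synthetic.py   landscape/ancillary/truth generators, SRU aggregation
  simple.py      proportional allocator
  entropy.py     priors, cropland adjustment, cross-entropy allocator
  scenarios.py   scenario specs, crop merging, presence shares, driver
  smoothing.py   Gaussian focal kernels and masked smoothing
  similarity.py  pixel/crop/country similarity, Moran's I, compare()
  io.py          CSV/YAML/JSON readers and writers, validation, manifests
  cli.py         click command group
tests/           unit, property and acceptance suites
scripts/         acceptance report
```
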