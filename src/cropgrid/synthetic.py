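"""Synthetic landscapes, ancillary layers, ground-truth allocations and SRU
statistics.

Everything here is seeded and deterministic: identical arguments and seed give
bit-identical outputs. Admin units are grown by balanced, seeded region
growing, which guarantees a contiguous nested partition; continuous fields
(cropland, suitability, population) are Gaussian-smoothed white noise.
"""

from __future__ import annotations

import heapq

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import AllocationInfeasibleError, SizingError, UnsupportedDirectionError
from .types import (
    SYSTEMS,
    AncillaryLayers,
    CropDefinition,
    Landscape,
    TrueAllocation,
    validate_sru_table,
)

# Per-system multipliers: suitability contrast and yield advantage. Irrigated
# systems out-yield rainfed ones; subsistence trails.
_SYSTEM_SUIT = np.array([0.9, 1.0, 0.85, 0.7])
_SYSTEM_YIELD = np.array([1.5, 1.25, 0.9, 0.6])

_NEIGHBORS = ((-1, 0), (1, 0), (0, -1), (0, 1))


def _grow_regions(
    shape: tuple[int, int],
    allowed: np.ndarray,
    n_regions: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Partition ``allowed`` pixels into ``n_regions`` contiguous regions.

    Balanced multi-source growth: at each step the smallest region consumes a
    random pixel from its frontier, so regions end up contiguous, nonempty and
    of comparable size.
    """
    n_allowed = int(allowed.sum())
    if n_allowed < n_regions:
        raise SizingError(
            f"cannot host {n_regions} units on {n_allowed} available pixels"
        )
    labels = np.full(shape, -1, dtype=np.int64)
    rows, cols = np.nonzero(allowed)
    seed_idx = rng.choice(len(rows), size=n_regions, replace=False)
    frontiers: list[list] = [[] for _ in range(n_regions)]
    sizes = [0] * n_regions
    for r, idx in enumerate(seed_idx):
        i, j = int(rows[idx]), int(cols[idx])
        heapq.heappush(frontiers[r], (rng.random(), i, j))
    assigned = 0
    while assigned < n_allowed:
        # smallest region with a live frontier grows next
        order = sorted(range(n_regions), key=lambda r: (sizes[r], r))
        grew = False
        for r in order:
            while frontiers[r]:
                _, i, j = heapq.heappop(frontiers[r])
                if labels[i, j] != -1:
                    continue
                labels[i, j] = r
                sizes[r] += 1
                assigned += 1
                for di, dj in _NEIGHBORS:
                    ni, nj = i + di, j + dj
                    if (
                        0 <= ni < shape[0]
                        and 0 <= nj < shape[1]
                        and allowed[ni, nj]
                        and labels[ni, nj] == -1
                    ):
                        heapq.heappush(frontiers[r], (rng.random(), ni, nj))
                grew = True
                break
            if grew:
                break
        if not grew:  # pragma: no cover - allowed region disconnected
            raise SizingError("allowed region is disconnected; cannot partition")
    return labels


def _smooth_field(
    shape: tuple[int, int], corr_length: float, rng: np.random.Generator
) -> np.ndarray:
    """Spatially autocorrelated standard-normal-ish field."""
    noise = rng.standard_normal(shape)
    if corr_length > 0:
        noise = ndimage.gaussian_filter(noise, sigma=corr_length, mode="reflect")
    sd = noise.std()
    if sd > 0:
        noise = (noise - noise.mean()) / sd
    return noise


def generate_landscape(
    n_rows: int,
    n_cols: int,
    n_adm1: int,
    n_adm2_per_adm1: int,
    spatial_corr_length: float,
    seed: int,
    *,
    pixel_area: float = 100.0,
    mean_cropland_fraction: float = 0.45,
    zero_fraction: float = 0.1,
) -> Landscape:
    """Generate a landscape with a nested contiguous admin partition.

    ADM1 codes are ``1..n_adm1``; ADM2 codes are ``100*parent + k`` with
    ``k = 1..n_adm2_per_adm1``; ADM0 is 0 everywhere. The lowest
    ``zero_fraction`` of the cropland field is zeroed (non-cropland pixels) and
    the remainder is scaled so the grid-mean cropland fraction matches
    ``mean_cropland_fraction``.
    """
    if n_rows < 2 or n_cols < 2:
        raise SizingError("grid dimensions must be at least 2x2")
    if n_adm1 < 1 or n_adm2_per_adm1 < 1:
        raise SizingError("unit counts must be at least 1")
    if n_adm1 * n_adm2_per_adm1 > n_rows * n_cols:
        raise SizingError(
            f"grid of {n_rows * n_cols} pixels cannot host "
            f"{n_adm1 * n_adm2_per_adm1} ADM2 units"
        )
    if not 0 < mean_cropland_fraction < 1:
        raise SizingError("mean_cropland_fraction must be in (0, 1)")

    rng = np.random.default_rng(seed)
    shape = (n_rows, n_cols)
    country = np.ones(shape, dtype=bool)

    adm1 = _grow_regions(shape, country, n_adm1, rng) + 1
    adm2 = np.zeros(shape, dtype=np.int64)
    for code in range(1, n_adm1 + 1):
        mask = adm1 == code
        sub = _grow_regions(shape, mask, n_adm2_per_adm1, rng)
        adm2[mask] = 100 * code + sub[mask] + 1

    field = _smooth_field(shape, spatial_corr_length, rng)
    frac = 1.0 / (1.0 + np.exp(-field))  # logistic squash to (0, 1)
    if zero_fraction > 0:
        cut = np.quantile(frac, zero_fraction)
        frac = np.where(frac <= cut, 0.0, frac)
    # iterate a multiplicative scale so the clipped mean hits the target
    scale = mean_cropland_fraction / max(frac.mean(), 1e-12)
    for _ in range(50):
        scaled = np.clip(frac * scale, 0.0, 1.0)
        m = scaled.mean()
        if abs(m - mean_cropland_fraction) < 1e-6 or m == 0:
            break
        scale *= mean_cropland_fraction / m
    cropland = np.clip(frac * scale, 0.0, 1.0) * pixel_area

    return Landscape(
        pixel_area=float(pixel_area),
        cropland=cropland,
        admin_code={0: np.zeros(shape, dtype=np.int64), 1: adm1, 2: adm2},
        country_mask=country,
    )


def default_crops(n_crops: int, seed: int, *, with_aggregate: bool = True) -> list[CropDefinition]:
    """A seeded set of crops; the last one is a rest-of-crops aggregate."""
    rng = np.random.default_rng(seed)
    crops = []
    for c in range(n_crops):
        is_agg = with_aggregate and c == n_crops - 1
        crops.append(
            CropDefinition(
                crop_id=c + 1,
                name=f"aggregate_{c + 1}" if is_agg else f"crop_{c + 1}",
                price=float(rng.uniform(80.0, 600.0)),
                cropping_intensity=(1.0, 1.0, 1.0, 1.0),
                is_aggregate=is_agg,
            )
        )
    return crops


def generate_ancillary(
    landscape: Landscape,
    crops: list[CropDefinition],
    suitability_sharpness: float,
    seed: int,
    *,
    corr_length: float = 3.0,
    suitability_floor: float = 0.15,
) -> AncillaryLayers:
    """Suitability, potential-yield, population and irrigation layers.

    Each crop gets its own smoothed-noise suitability surface (rank-mapped to
    [0, 1] and raised to ``suitability_sharpness``; sharpness 0 therefore
    yields spatially uniform suitability). ``suitability_floor`` keeps every
    pixel marginally suitable for every crop, so statistics aggregated from a
    capacity-respecting truth stay jointly feasible under suitability caps.
    Potential yield increases with suitability within each crop.
    """
    if not crops:
        raise SizingError("need at least one crop")
    if suitability_sharpness < 0:
        raise SizingError("suitability_sharpness must be >= 0")
    landscape.validate()
    rng = np.random.default_rng(seed)
    shape = landscape.shape
    n = shape[0] * shape[1]
    n_crops = len(crops)
    n_sys = len(SYSTEMS)

    suitable = np.empty((n_crops, n_sys, *shape))
    pot_yield = np.empty((n_crops, n_sys, *shape))
    for c in range(n_crops):
        field = _smooth_field(shape, corr_length, rng)
        ranks = field.ravel().argsort().argsort().reshape(shape)
        base = ranks / max(n - 1, 1)  # uniform in [0, 1]
        # sharpness 0 -> all ones (uniform suitability)
        sf = suitability_floor + (1.0 - suitability_floor) * np.power(
            base, suitability_sharpness
        )
        base_yield = rng.uniform(1.0, 8.0)
        for s in range(n_sys):
            suitable[c, s] = sf * _SYSTEM_SUIT[s] * landscape.pixel_area
            pot_yield[c, s] = base_yield * (0.5 + sf) * _SYSTEM_YIELD[s]

    pop = _smooth_field(shape, corr_length, rng)
    pop = 50.0 * np.exp(0.5 * pop)  # lognormal-ish, strictly positive, smooth

    irr = _smooth_field(shape, corr_length, rng)
    irr_frac = np.clip(1.0 / (1.0 + np.exp(-irr)) - 0.25, 0.0, 1.0)
    irrigated = irr_frac * landscape.cropland

    return AncillaryLayers(
        crop_ids=tuple(c.crop_id for c in crops),
        suitable_area=suitable,
        potential_yield=pot_yield,
        rural_pop_density=pop,
        irrigated_area=irrigated,
    )


def generate_true_allocation(
    landscape: Landscape,
    ancillary: AncillaryLayers,
    crops: list[CropDefinition],
    concentration: float,
    seed: int,
    *,
    area_fractions: dict[int, float] | None = None,
    total_cropland_use: float = 0.8,
    noise_sd: float = 0.75,
    regional_sd: float = 0.6,
) -> TrueAllocation:
    """Ground-truth physical area per (pixel, crop, system).

    Each crop's national physical area is drawn proportionally to
    ``cropland * suitability^concentration`` times seeded lognormal pixel
    noise (sd ``noise_sd``; 0 disables it), subject to exact per-pixel
    cropland capacity (iterative water-filling). ``concentration -> 0`` with
    ``noise_sd=0`` and ``regional_sd=0`` reduces to cropland-proportional
    spreading.

    ``regional_sd`` adds lognormal crop-specialization multipliers per
    (crop, admin unit) at levels 1 and 2, emulating regional crop mixes.
    Together with the pixel noise this keeps the truth only partially
    predictable from the ancillary layers, so finer priming statistics
    genuinely carry more information.
    """
    if concentration < 0:
        raise AllocationInfeasibleError("concentration must be >= 0")
    landscape.validate()
    ancillary.validate(landscape)
    rng = np.random.default_rng(seed)
    shape = landscape.shape
    total_cropland = float(landscape.cropland.sum())

    if area_fractions is None:
        raw = rng.uniform(0.7, 1.3, size=len(crops))
        raw = raw / raw.sum() * total_cropland_use
        area_fractions = {c.crop_id: float(f) for c, f in zip(crops, raw)}
    demand = {cid: f * total_cropland for cid, f in area_fractions.items()}
    if sum(demand.values()) > total_cropland * (1 + 1e-12):
        raise AllocationInfeasibleError(
            f"total demanded area {sum(demand.values()):.1f} ha exceeds "
            f"total cropland {total_cropland:.1f} ha"
        )

    capacity = landscape.cropland.copy()
    physical = np.zeros((len(crops), len(SYSTEMS), *shape))

    # per-pixel irrigated fraction, used to split crop area across systems
    with np.errstate(divide="ignore", invalid="ignore"):
        irr_frac = np.where(
            landscape.cropland > 0,
            np.minimum(ancillary.irrigated_area / np.maximum(landscape.cropland, 1e-300), 1.0),
            0.0,
        )
    rain_split = np.array([0.5, 0.3, 0.2])

    for ci, crop in enumerate(crops):
        d = demand[crop.crop_id]
        if d <= 0:
            continue
        sf = ancillary.suitable_area[ci].mean(axis=0) / landscape.pixel_area
        weight = landscape.cropland * np.power(np.maximum(sf, 1e-12), concentration)
        if noise_sd > 0:
            weight = weight * np.exp(rng.normal(0.0, noise_sd, size=shape))
        if regional_sd > 0:
            for level in (1, 2):
                for code in landscape.units(level):
                    unit = landscape.unit_mask(level, int(code))
                    weight[unit] *= np.exp(rng.normal(0.0, regional_sd))
        alloc = np.zeros(shape)
        remaining = d
        for _ in range(200):
            open_px = (capacity - alloc) > 1e-12
            w = np.where(open_px, weight, 0.0)
            tw = w.sum()
            if remaining <= 1e-9 or tw <= 0:
                break
            step = np.minimum(remaining * w / tw, capacity - alloc)
            alloc += step
            remaining -= step.sum()
        if remaining > max(1e-6, 1e-9 * d):
            raise AllocationInfeasibleError(
                f"could not place {remaining:.3g} ha of crop {crop.crop_id}",
                crop_id=crop.crop_id,
            )
        capacity -= alloc
        physical[ci, 0] = alloc * irr_frac
        rest = alloc * (1.0 - irr_frac)
        for s in range(3):
            physical[ci, 1 + s] = rest * rain_split[s]

    return TrueAllocation(
        crop_ids=tuple(c.crop_id for c in crops),
        physical_area=physical,
        yields=ancillary.potential_yield.copy(),
    )


def truth_to_result(
    truth: TrueAllocation,
    landscape: Landscape,
    crops: list[CropDefinition],
):
    """View a ground-truth allocation as an allocation result for scoring."""
    from .types import AllocationResult

    harvested_sys = np.empty_like(truth.physical_area)
    for i, crop in enumerate(crops):
        ci = np.asarray(crop.cropping_intensity)[:, None, None]
        harvested_sys[i] = truth.physical_area[i] * ci
    harvested = harvested_sys.sum(axis=1)
    production = (harvested_sys * truth.yields).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        yield_ = np.where(harvested > 0, production / np.maximum(harvested, 1e-300), 0.0)
    return AllocationResult(
        crop_ids=truth.crop_ids,
        systems=SYSTEMS,
        physical_area=truth.physical_area.copy(),
        harvested_area=harvested,
        production=production,
        yield_=yield_,
        provenance={"method": "truth"},
        adjust_flags={},
    )


def aggregate_to_sru(
    truth: TrueAllocation,
    landscape: Landscape,
    crops: list[CropDefinition],
    level: int,
) -> pd.DataFrame:
    """Aggregate a true allocation to SRU statistics at an admin level.

    harvested = sum physical x cropping intensity; production = sum
    harvested x per-system yield; yield = production / harvested.
    """
    if level not in (0, 1, 2):
        raise UnsupportedDirectionError(f"admin level must be 0, 1 or 2, got {level}")
    codes = landscape.admin_code[level]
    rows = []
    for code in landscape.units(level):
        mask = landscape.unit_mask(level, code)
        for ci, crop in enumerate(crops):
            ci_vec = np.asarray(crop.cropping_intensity)[:, None]
            harv_sys = truth.physical_area[ci][:, mask] * ci_vec
            prod_sys = harv_sys * truth.yields[ci][:, mask]
            h = float(harv_sys.sum())
            p = float(prod_sys.sum())
            rows.append(
                {
                    "sru_id": int(code),
                    "admin_level": level,
                    "crop_id": crop.crop_id,
                    "harvested_area_ha": h,
                    "production_mt": p,
                    "yield_mt_ha": p / h if h > 0 else 0.0,
                }
            )
    table = pd.DataFrame(rows).sort_values(["sru_id", "crop_id"]).reset_index(drop=True)
    validate_sru_table(table)
    return table


def degrade_statistics(
    sru_table: pd.DataFrame,
    landscape: Landscape,
    to_level: int,
) -> pd.DataFrame:
    """Re-aggregate SRU statistics to a coarser admin level.

    Areas and production are summed, yields recomputed; country totals are
    conserved exactly. Requesting a level finer than any source row raises
    :class:`UnsupportedDirectionError`.
    """
    validate_sru_table(sru_table)
    if (sru_table["admin_level"] < to_level).any():
        raise UnsupportedDirectionError(
            f"cannot refine statistics to level {to_level}: table has coarser rows"
        )
    parents = {
        int(lvl): landscape.parent_map(int(lvl), to_level)
        for lvl in sru_table["admin_level"].unique()
    }
    work = sru_table.copy()
    work["sru_id"] = [
        parents[int(lvl)][int(sid)]
        for lvl, sid in zip(work["admin_level"], work["sru_id"])
    ]
    grouped = (
        work.groupby(["sru_id", "crop_id"], as_index=False)[
            ["harvested_area_ha", "production_mt"]
        ]
        .sum()
        .sort_values(["sru_id", "crop_id"])
        .reset_index(drop=True)
    )
    grouped["admin_level"] = to_level
    h = grouped["harvested_area_ha"]
    grouped["yield_mt_ha"] = np.where(h > 0, grouped["production_mt"] / h.where(h > 0, 1.0), 0.0)
    out = grouped[
        [
            "sru_id",
            "admin_level",
            "crop_id",
            "harvested_area_ha",
            "production_mt",
            "yield_mt_ha",
        ]
    ]
    validate_sru_table(out)
    return out
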