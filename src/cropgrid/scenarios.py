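"""Robustness scenarios: the baseline plus eight methodological variants.

Each scenario perturbs exactly one ingredient of the baseline cross-entropy
allocation: the allocation method itself, the crop list, the treatment of the
rest-of-crops aggregate, the suitability constraint, the market-access layer,
crop prices, or the admin level of the priming statistics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .entropy import allocate_cross_entropy, build_priors
from .errors import UndefinedStatisticError, ValidationError
from .simple import allocate_simple
from .synthetic import degrade_statistics
from .types import (
    PRESENCE_THRESHOLD,
    SYSTEMS,
    AllocationResult,
    AncillaryLayers,
    CropDefinition,
    EntropyConfig,
    Landscape,
    validate_sru_table,
)

SCENARIO_IDS = (
    "baseline",
    "allocation_method",
    "crop_choice",
    "remainder_allocation",
    "crop_suitability",
    "market_access",
    "crop_price",
    "adm0_only",
    "adm1_only",
)


@dataclass(frozen=True)
class ScenarioSpec:
    """One scenario toggle, plus the crop merge map where applicable."""

    scenario_id: str
    crop_merge_map: dict[int, list[int]] | None = None
    notes: str = ""

    def __post_init__(self):
        if self.scenario_id not in SCENARIO_IDS:
            raise ValidationError(f"unknown scenario {self.scenario_id!r}")
        if (self.scenario_id == "crop_choice") != (self.crop_merge_map is not None):
            raise ValidationError(
                "crop_merge_map is required exactly when scenario is crop_choice"
            )


def merge_crops(
    crops: list[CropDefinition],
    sru_table: pd.DataFrame,
    crop_merge_map: dict[int, list[int]],
) -> tuple[list[CropDefinition], pd.DataFrame]:
    """Merge crops into aggregates; areas/production sum, prices and
    cropping intensities are harvested-area weighted, yields recomputed.

    ``crop_merge_map`` maps each new aggregate id to the member crop ids.
    Unmapped crops pass through unchanged.
    """
    validate_sru_table(sru_table)
    member_of: dict[int, int] = {}
    for gid, members in crop_merge_map.items():
        for m in members:
            if m in member_of:
                raise ValidationError(f"crop {m} mapped to two aggregates")
            member_of[m] = gid
    by_id = {c.crop_id: c for c in crops}
    for m in member_of:
        if m not in by_id:
            raise ValidationError(f"merge map references unknown crop {m}")

    country = sru_table.groupby("crop_id")["harvested_area_ha"].sum()
    new_crops: list[CropDefinition] = []
    for crop in crops:
        if crop.crop_id not in member_of:
            new_crops.append(crop)
    for gid, members in sorted(crop_merge_map.items()):
        w = np.array([max(country.get(m, 0.0), 0.0) for m in members])
        if w.sum() == 0:
            w = np.ones(len(members))
        w = w / w.sum()
        price = float(sum(wi * by_id[m].price for wi, m in zip(w, members)))
        ci = tuple(
            float(sum(wi * by_id[m].cropping_intensity[s] for wi, m in zip(w, members)))
            for s in range(len(SYSTEMS))
        )
        name = "+".join(by_id[m].name for m in members)
        new_crops.append(
            CropDefinition(
                crop_id=gid,
                name=name,
                price=price,
                cropping_intensity=ci,
                is_aggregate=len(members) > 1,
            )
        )
    new_crops.sort(key=lambda c: c.crop_id)

    work = sru_table.copy()
    work["crop_id"] = [member_of.get(int(c), int(c)) for c in work["crop_id"]]
    merged = (
        work.groupby(["sru_id", "admin_level", "crop_id"], as_index=False)[
            ["harvested_area_ha", "production_mt"]
        ]
        .sum()
        .sort_values(["sru_id", "crop_id"])
        .reset_index(drop=True)
    )
    h = merged["harvested_area_ha"]
    merged["yield_mt_ha"] = np.where(
        h > 0, merged["production_mt"] / h.where(h > 0, 1.0), 0.0
    )
    merged = merged[
        [
            "sru_id",
            "admin_level",
            "crop_id",
            "harvested_area_ha",
            "production_mt",
            "yield_mt_ha",
        ]
    ]
    validate_sru_table(merged)
    return new_crops, merged


def merge_ancillary(
    ancillary: AncillaryLayers,
    sru_table: pd.DataFrame,
    crop_merge_map: dict[int, list[int]],
    new_crop_ids: tuple[int, ...],
) -> AncillaryLayers:
    """Harvested-area-weighted merge of suitability and potential yield."""
    country = sru_table.groupby("crop_id")["harvested_area_ha"].sum()
    n_sys = len(SYSTEMS)
    shape = ancillary.rural_pop_density.shape
    suit = np.empty((len(new_crop_ids), n_sys, *shape))
    pyld = np.empty((len(new_crop_ids), n_sys, *shape))
    for i, cid in enumerate(new_crop_ids):
        members = crop_merge_map.get(cid, [cid])
        w = np.array([max(country.get(m, 0.0), 0.0) for m in members])
        if w.sum() == 0:
            w = np.ones(len(members))
        w = w / w.sum()
        idx = [ancillary.crop_index(m) for m in members]
        suit[i] = np.tensordot(w, ancillary.suitable_area[idx], axes=1)
        pyld[i] = np.tensordot(w, ancillary.potential_yield[idx], axes=1)
    return AncillaryLayers(
        crop_ids=tuple(new_crop_ids),
        suitable_area=suit,
        potential_yield=pyld,
        rural_pop_density=ancillary.rural_pop_density,
        irrigated_area=ancillary.irrigated_area,
    )


def presence_share(
    result: AllocationResult,
    landscape: Landscape,
    crop_id: int,
    *,
    threshold: float = PRESENCE_THRESHOLD,
) -> float:
    """Percent of cropland pixels where the crop's allocation is non-zero.

    Can exceed 100 only when the allocator expanded an SRU's cropland
    (``result.adjust_flags``), which lets area spill onto non-cropland pixels.
    """
    cropland_px = int(((landscape.cropland > 0) & landscape.country_mask).sum())
    if cropland_px == 0:
        raise UndefinedStatisticError("no cropland pixels: presence share undefined")
    i = result.crop_index(crop_id)
    present = int(
        ((result.harvested_area[i] > threshold) & landscape.country_mask).sum()
    )
    return 100.0 * present / cropland_px


def _passive_remainder(
    result: AllocationResult,
    aggregates: list[CropDefinition],
    agg_table: pd.DataFrame,
    landscape: Landscape,
    crops: list[CropDefinition],
    config: EntropyConfig,
) -> AllocationResult:
    """Assign each pixel's residual cropland to the aggregate crop(s).

    Residuals (cropland minus actively allocated physical area, clipped at
    zero) are split across aggregates in proportion to their country
    harvested areas; production is rescaled to match each SRU's table entry.
    """
    residual = np.clip(
        landscape.cropland - result.physical_area.sum(axis=(0, 1)), 0.0, None
    )
    country = agg_table.groupby("crop_id")["harvested_area_ha"].sum()
    tot = sum(max(country.get(a.crop_id, 0.0), 0.0) for a in aggregates)
    shares = {
        a.crop_id: (country.get(a.crop_id, 0.0) / tot if tot > 0 else 1.0 / len(aggregates))
        for a in aggregates
    }

    all_crops = crops + aggregates
    n_sys = len(SYSTEMS)
    shape = landscape.shape
    physical = np.zeros((len(all_crops), n_sys, *shape))
    physical[: len(crops)] = result.physical_area
    harvested = np.zeros((len(all_crops), *shape))
    harvested[: len(crops)] = result.harvested_area
    production = np.zeros((len(all_crops), *shape))
    production[: len(crops)] = result.production

    sys_split = np.array([0.0, *config.rainfed_split])
    for k, agg in enumerate(aggregates):
        i = len(crops) + k
        phys = residual * shares[agg.crop_id]
        physical[i] = phys[None, :, :] * sys_split[:, None, None]
        ci = np.asarray(agg.cropping_intensity)
        harvested[i] = (physical[i] * ci[:, None, None]).sum(axis=0)
        rows = agg_table[agg_table["crop_id"] == agg.crop_id]
        for row in rows.itertuples():
            mask = landscape.unit_mask(int(row.admin_level), int(row.sru_id))
            h = harvested[i][mask]
            if h.sum() > 0 and row.production_mt > 0:
                production[i][mask] = row.production_mt * h / h.sum()

    with np.errstate(divide="ignore", invalid="ignore"):
        yield_ = np.where(harvested > 0, production / np.maximum(harvested, 1e-300), 0.0)
    return AllocationResult(
        crop_ids=tuple(c.crop_id for c in all_crops),
        systems=SYSTEMS,
        physical_area=physical,
        harvested_area=harvested,
        production=production,
        yield_=yield_,
        provenance={**result.provenance, "remainder": "passive"},
        adjust_flags=result.adjust_flags,
    )


def run_scenario(
    spec: ScenarioSpec,
    landscape: Landscape,
    ancillary: AncillaryLayers,
    crops: list[CropDefinition],
    sru_table: pd.DataFrame,
    config: EntropyConfig | None = None,
) -> AllocationResult:
    """Run one scenario and tag the result with its id."""
    base_config = config or EntropyConfig()
    sid = spec.scenario_id
    try:
        if sid == "allocation_method":
            result = allocate_simple(sru_table, landscape, crops)
        elif sid == "crop_choice":
            new_crops, new_table = merge_crops(crops, sru_table, spec.crop_merge_map)
            new_anc = merge_ancillary(
                ancillary,
                sru_table,
                spec.crop_merge_map,
                tuple(c.crop_id for c in new_crops),
            )
            result = _entropy(landscape, new_anc, new_crops, new_table, base_config)
        elif sid == "remainder_allocation":
            active = [c for c in crops if not c.is_aggregate]
            aggs = [c for c in crops if c.is_aggregate]
            if not aggs:
                raise ValidationError(
                    "remainder_allocation needs at least one aggregate crop"
                )
            active_ids = {c.crop_id for c in active}
            active_table = sru_table[sru_table["crop_id"].isin(active_ids)].reset_index(
                drop=True
            )
            agg_table = sru_table[~sru_table["crop_id"].isin(active_ids)].reset_index(
                drop=True
            )
            result = _entropy(landscape, ancillary, active, active_table, base_config)
            result = _passive_remainder(
                result, aggs, agg_table, landscape, active, base_config
            )
        elif sid in ("crop_suitability", "market_access", "crop_price"):
            flag = {
                "crop_suitability": "use_suitability_constraint",
                "market_access": "use_market_access",
                "crop_price": "use_prices",
            }[sid]
            cfg = dataclasses.replace(base_config, **{flag: False})
            result = _entropy(landscape, ancillary, crops, sru_table, cfg)
        elif sid in ("adm0_only", "adm1_only"):
            to_level = 0 if sid == "adm0_only" else 1
            finer = sru_table[sru_table["admin_level"] >= to_level]
            coarser = sru_table[sru_table["admin_level"] < to_level]
            degraded = degrade_statistics(
                finer.reset_index(drop=True), landscape, to_level
            )
            if len(coarser):
                degraded = (
                    pd.concat([degraded, coarser], ignore_index=True)
                    .sort_values(["sru_id", "crop_id"])
                    .reset_index(drop=True)
                )
            result = _entropy(landscape, ancillary, crops, degraded, base_config)
        else:  # baseline
            result = _entropy(landscape, ancillary, crops, sru_table, base_config)
    except Exception as exc:
        exc.args = (f"[scenario {sid}] {exc.args[0] if exc.args else ''}",) + exc.args[1:]
        raise
    result.provenance["scenario"] = sid
    if spec.notes:
        result.provenance["notes"] = spec.notes
    return result


def _entropy(landscape, ancillary, crops, table, config) -> AllocationResult:
    priors = build_priors(
        landscape, ancillary, crops, config, on_degenerate="cropland"
    )
    return allocate_cross_entropy(priors, table, landscape, ancillary, crops, config)


def default_merge_map(crops: list[CropDefinition]) -> dict[int, list[int]]:
    """Example merge map: fold the last two non-aggregate crops together."""
    named = [c.crop_id for c in crops if not c.is_aggregate]
    if len(named) < 2:
        raise ValidationError("need at least two non-aggregate crops to merge")
    gid = max(c.crop_id for c in crops) + 1
    return {gid: named[-2:]}
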