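"""Simple proportional allocation.

Each crop's SRU harvested area is spread over the SRU's pixels in proportion
to each pixel's share of the SRU's cropland, the SRU's average yield is
assigned uniformly to every pixel, and production is their product. There is
no production-system split (a single composite system) and no capacity cap:
crops are allocated independently, so summed crop area may exceed a pixel's
cropland under multi-cropping.
"""

from __future__ import annotations

import numpy as np

from .errors import AllocationInfeasibleError, ValidationError
from .types import (
    AllocationResult,
    CropDefinition,
    Landscape,
    validate_sru_table,
)


def allocate_simple(
    sru_table,
    landscape: Landscape,
    crops: list[CropDefinition],
) -> AllocationResult:
    """Allocate SRU statistics to pixels proportionally to cropland share.

    Raises :class:`AllocationInfeasibleError` (naming the SRU) if an SRU
    reports positive harvested area but contains no cropland.
    """
    validate_sru_table(sru_table)
    landscape.validate()
    crop_pos = {c.crop_id: i for i, c in enumerate(crops)}
    n_crops = len(crops)
    shape = landscape.shape

    harvested = np.zeros((n_crops, *shape))
    production = np.zeros((n_crops, *shape))
    yield_ = np.zeros((n_crops, *shape))
    seen = np.zeros((n_crops, *shape), dtype=np.int64)

    for (sid, level), rows in sru_table.groupby(["sru_id", "admin_level"]):
        mask = landscape.unit_mask(int(level), int(sid))
        if not mask.any():
            raise ValidationError(f"SRU {sid} (level {level}) has no pixels")
        crop_total = landscape.cropland[mask].sum()
        weights = None
        if crop_total > 0:
            weights = landscape.cropland[mask] / crop_total
        for row in rows.itertuples():
            if int(row.crop_id) not in crop_pos:
                raise ValidationError(f"unknown crop {row.crop_id} in SRU table")
            i = crop_pos[int(row.crop_id)]
            if row.harvested_area_ha <= 0:
                seen[i][mask] += 1
                continue
            if weights is None:
                raise AllocationInfeasibleError(
                    f"SRU {sid} reports {row.harvested_area_ha} ha of crop "
                    f"{row.crop_id} but contains no cropland",
                    sru_id=int(sid),
                    crop_id=int(row.crop_id),
                )
            h = row.harvested_area_ha * weights
            harvested[i][mask] = h
            yield_[i][mask] = row.yield_mt_ha
            production[i][mask] = h * row.yield_mt_ha
            seen[i][mask] += 1

    if np.any(seen > 1):
        raise ValidationError(
            "overlapping SRUs: some pixel is covered twice for the same crop"
        )

    # single composite production system; physical = harvested / mean CI
    physical = np.empty((n_crops, 1, *shape))
    for i, crop in enumerate(crops):
        ci = crop.mean_cropping_intensity
        physical[i, 0] = harvested[i] / ci if ci > 0 else 0.0

    return AllocationResult(
        crop_ids=tuple(c.crop_id for c in crops),
        systems=("composite",),
        physical_area=physical,
        harvested_area=harvested,
        production=production,
        yield_=yield_,
        provenance={"method": "simple"},
        adjust_flags={},
    )
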