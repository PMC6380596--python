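"""Core domain types shared across the pipeline.

Conventions (fixed project-wide): grids are row-major with 0-based (row, col)
indices; areas are hectares, production metric tons, yields mt/ha. Admin codes
are opaque non-negative integers; level 0 is the country, levels 1 and 2 are
successively finer nested subdivisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

#: Production systems, in canonical order.
SYSTEMS: tuple[str, ...] = (
    "irrigated",
    "rainfed_high",
    "rainfed_low",
    "rainfed_subsistence",
)

#: Index of the irrigated system within :data:`SYSTEMS`.
IRRIGATED = 0

#: Allocated harvested area above this (ha) counts as crop presence.
PRESENCE_THRESHOLD = 1e-6

#: Required columns of an SRU statistics table.
SRU_COLUMNS = (
    "sru_id",
    "admin_level",
    "crop_id",
    "harvested_area_ha",
    "production_mt",
    "yield_mt_ha",
)


@dataclass
class Landscape:
    """A pixel grid with cropland and a nested administrative partition.

    Attributes
    ----------
    pixel_area : float
        Hectares per pixel; uniform across the synthetic grid.
    cropland : ndarray of shape (n_rows, n_cols)
        Cropland hectares per pixel, in ``[0, pixel_area]``.
    admin_code : dict mapping level -> int ndarray (n_rows, n_cols)
        Unit label per pixel for levels 0, 1 and 2.
    country_mask : bool ndarray (n_rows, n_cols)
        In-country indicator (all True on synthetic grids).
    """

    pixel_area: float
    cropland: np.ndarray
    admin_code: dict[int, np.ndarray]
    country_mask: np.ndarray

    @property
    def n_rows(self) -> int:
        return self.cropland.shape[0]

    @property
    def n_cols(self) -> int:
        return self.cropland.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.cropland.shape

    def units(self, level: int) -> np.ndarray:
        """Sorted unique admin codes at ``level`` (within the country)."""
        return np.unique(self.admin_code[level][self.country_mask])

    def unit_mask(self, level: int, code: int) -> np.ndarray:
        """Boolean pixel mask of one admin unit."""
        return (self.admin_code[level] == code) & self.country_mask

    def parent_map(self, fine: int, coarse: int) -> dict[int, int]:
        """Map each admin code at ``fine`` level to its code at ``coarse``."""
        if coarse > fine:
            raise ValidationError(
                f"level {coarse} is finer than level {fine}; no parent map"
            )
        fine_codes = self.admin_code[fine][self.country_mask]
        coarse_codes = self.admin_code[coarse][self.country_mask]
        out: dict[int, int] = {}
        for f, c in zip(fine_codes.ravel(), coarse_codes.ravel()):
            prev = out.setdefault(int(f), int(c))
            if prev != int(c):
                raise ValidationError(
                    f"admin hierarchy not nested: unit {f} at level {fine} "
                    f"spans units {prev} and {c} at level {coarse}"
                )
        return out

    def validate(self) -> None:
        if self.cropland.ndim != 2:
            raise ValidationError("cropland must be a 2-D array")
        if np.any(self.cropland < 0):
            raise ValidationError("cropland must be nonnegative")
        if np.any(self.cropland > self.pixel_area * (1 + 1e-12)):
            raise ValidationError("cropland exceeds pixel area")
        for level in (0, 1, 2):
            if level not in self.admin_code:
                raise ValidationError(f"missing admin level {level}")
            if self.admin_code[level].shape != self.cropland.shape:
                raise ValidationError(f"admin level {level} shape mismatch")
        # nesting (raises if violated)
        self.parent_map(2, 1)
        self.parent_map(1, 0)


@dataclass(frozen=True)
class CropDefinition:
    """A crop (or composite crop aggregate) and its economic parameters."""

    crop_id: int
    name: str
    price: float = 1.0  # international dollars per mt
    cropping_intensity: tuple[float, ...] = (1.0,) * len(SYSTEMS)
    is_aggregate: bool = False

    def __post_init__(self):
        if self.price <= 0:
            raise ValidationError(f"crop {self.name}: price must be > 0")
        if len(self.cropping_intensity) != len(SYSTEMS):
            raise ValidationError(
                f"crop {self.name}: need one cropping intensity per system"
            )
        if any(ci < 0 for ci in self.cropping_intensity):
            raise ValidationError(f"crop {self.name}: negative cropping intensity")

    @property
    def mean_cropping_intensity(self) -> float:
        return float(np.mean(self.cropping_intensity))


@dataclass
class AncillaryLayers:
    """Per-pixel ancillary layers driving the informed priors.

    ``suitable_area`` and ``potential_yield`` have shape
    (n_crops, n_systems, n_rows, n_cols); the crop axis follows ``crop_ids``.
    """

    crop_ids: tuple[int, ...]
    suitable_area: np.ndarray  # ha
    potential_yield: np.ndarray  # mt/ha
    rural_pop_density: np.ndarray  # persons / km^2
    irrigated_area: np.ndarray  # ha

    def crop_index(self, crop_id: int) -> int:
        try:
            return self.crop_ids.index(crop_id)
        except ValueError:
            raise SchemaError(f"crop {crop_id} absent from ancillary layers")

    def validate(self, landscape: Landscape | None = None) -> None:
        for name in ("suitable_area", "potential_yield"):
            arr = getattr(self, name)
            if arr.shape[:2] != (len(self.crop_ids), len(SYSTEMS)):
                raise ValidationError(f"{name}: wrong crop/system axes")
            if np.any(arr < 0):
                raise ValidationError(f"{name} must be nonnegative")
        if np.any(self.rural_pop_density < 0) or np.any(self.irrigated_area < 0):
            raise ValidationError("population and irrigated area must be nonnegative")
        if landscape is not None:
            if self.suitable_area.shape[2:] != landscape.shape:
                raise ValidationError("ancillary grids not co-registered")
            if np.any(self.suitable_area > landscape.pixel_area * (1 + 1e-12)):
                raise ValidationError("suitable area exceeds pixel area")


@dataclass
class TrueAllocation:
    """Ground-truth pixel allocation used to manufacture SRU statistics."""

    crop_ids: tuple[int, ...]
    physical_area: np.ndarray  # (n_crops, n_systems, n_rows, n_cols), ha
    yields: np.ndarray  # same shape, mt/ha


@dataclass
class PriorShares:
    """Prior share pi(pixel, crop, system) of each crop-system's area."""

    crop_ids: tuple[int, ...]
    pi: np.ndarray  # (n_crops, n_systems, n_rows, n_cols)

    def validate(self) -> None:
        if np.any(self.pi < 0):
            raise ValidationError("priors must be nonnegative")
        totals = self.pi.sum(axis=(2, 3))
        ok = np.isclose(totals, 1.0, rtol=1e-9, atol=1e-12) | (totals == 0)
        if not np.all(ok):
            raise ValidationError("priors must sum to 1 per (crop, system)")


@dataclass
class EntropyConfig:
    """Toggles and tolerances for the cross-entropy allocator."""

    use_suitability_constraint: bool = True
    use_market_access: bool = True
    use_prices: bool = True
    cropland_slack: float = 2.0
    solver_tol: float = 1e-8
    max_iter: int = 20000
    #: split of the non-irrigated share across (high, low, subsistence)
    rainfed_split: tuple[float, float, float] = (0.45, 0.35, 0.20)
    presence_threshold: float = PRESENCE_THRESHOLD

    def __post_init__(self):
        if self.solver_tol <= 0:
            raise ValidationError("solver_tol must be > 0")
        if self.cropland_slack < 1:
            raise ValidationError("cropland_slack must be >= 1")
        if abs(sum(self.rainfed_split) - 1.0) > 1e-9:
            raise ValidationError("rainfed_split must sum to 1")


@dataclass
class AllocationResult:
    """Pixel-level allocation of one method/scenario.

    ``physical_area`` is per (crop, system); harvested area, production and
    yield are per crop, summed (area/production) or area-weighted averaged
    (yield) across systems.
    """

    crop_ids: tuple[int, ...]
    systems: tuple[str, ...]
    physical_area: np.ndarray  # (n_crops, n_systems, n_rows, n_cols)
    harvested_area: np.ndarray  # (n_crops, n_rows, n_cols)
    production: np.ndarray  # (n_crops, n_rows, n_cols)
    yield_: np.ndarray  # (n_crops, n_rows, n_cols)
    provenance: dict = field(default_factory=dict)
    adjust_flags: dict = field(default_factory=dict)  # sru_id -> bool

    def crop_index(self, crop_id: int) -> int:
        try:
            return self.crop_ids.index(crop_id)
        except ValueError:
            raise SchemaError(f"crop {crop_id} absent from allocation result")

    @property
    def any_adjusted(self) -> bool:
        return any(self.adjust_flags.values())


def validate_sru_table(table: pd.DataFrame) -> None:
    """Check schema and internal consistency of an SRU statistics table."""
    for col in SRU_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"SRU table missing column {col!r}")
    if table.duplicated(subset=["sru_id", "crop_id"]).any():
        raise ValidationError("duplicate (sru_id, crop_id) rows in SRU table")
    if not table["admin_level"].isin([0, 1, 2]).all():
        raise ValidationError("admin_level must be 0, 1 or 2")
    if (table["harvested_area_ha"] < 0).any() or (table["production_mt"] < 0).any():
        raise ValidationError("negative area or production in SRU table")
    pos = table["harvested_area_ha"] > 0
    implied = table.loc[pos, "production_mt"] / table.loc[pos, "harvested_area_ha"]
    if not np.allclose(implied, table.loc[pos, "yield_mt_ha"], rtol=1e-9, atol=1e-12):
        raise ValidationError("yield x harvested_area != production in SRU table")
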