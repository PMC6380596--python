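"""Readers and writers for the plain-text project formats.

Rasters travel as long-format CSV (one row per pixel, full float precision),
tables as CSV with mandatory headers, configuration as YAML and run manifests
as JSON. All files are UTF-8 with '.' decimals.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError, ValidationError
from .types import (
    SYSTEMS,
    AllocationResult,
    AncillaryLayers,
    CropDefinition,
    EntropyConfig,
    Landscape,
    TrueAllocation,
    validate_sru_table,
)

_FLOAT = "%.17g"  # lossless float round-trip

LANDSCAPE_COLUMNS = (
    "row",
    "col",
    "pixel_area_ha",
    "cropland_ha",
    "adm0",
    "adm1",
    "adm2",
    "in_country",
)


def _require(frame: pd.DataFrame, columns, what: str) -> None:
    for col in columns:
        if col not in frame.columns:
            raise SchemaError(f"{what}: missing column {col!r}")


def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise SchemaError(f"{path}: unreadable CSV ({exc})") from exc


def _grid_shape(frame: pd.DataFrame, what: str) -> tuple[int, int]:
    n_rows = int(frame["row"].max()) + 1
    n_cols = int(frame["col"].max()) + 1
    if len(frame) != n_rows * n_cols or frame.duplicated(["row", "col"]).any():
        raise SchemaError(f"{what}: pixel rows do not tile a full {n_rows}x{n_cols} grid")
    return n_rows, n_cols


def write_landscape(landscape: Landscape, path) -> None:
    rows, cols = np.indices(landscape.shape)
    frame = pd.DataFrame(
        {
            "row": rows.ravel(),
            "col": cols.ravel(),
            "pixel_area_ha": landscape.pixel_area,
            "cropland_ha": landscape.cropland.ravel(),
            "adm0": landscape.admin_code[0].ravel(),
            "adm1": landscape.admin_code[1].ravel(),
            "adm2": landscape.admin_code[2].ravel(),
            "in_country": landscape.country_mask.ravel().astype(int),
        }
    )
    frame.to_csv(path, index=False, float_format=_FLOAT)


def read_landscape(path) -> Landscape:
    frame = _read_csv(path)
    _require(frame, LANDSCAPE_COLUMNS, "landscape")
    if frame[list(LANDSCAPE_COLUMNS)].isna().any().any():
        raise SchemaError("landscape: NaN values present")
    shape = _grid_shape(frame, "landscape")
    frame = frame.sort_values(["row", "col"])

    def grid(col, dtype=float):
        return frame[col].to_numpy(dtype=dtype).reshape(shape)

    landscape = Landscape(
        pixel_area=float(frame["pixel_area_ha"].iloc[0]),
        cropland=grid("cropland_ha"),
        admin_code={
            0: grid("adm0", np.int64),
            1: grid("adm1", np.int64),
            2: grid("adm2", np.int64),
        },
        country_mask=grid("in_country", np.int64).astype(bool),
    )
    landscape.validate()
    return landscape


def write_crops(crops: list[CropDefinition], path) -> None:
    rows = []
    for c in crops:
        row = {"crop_id": c.crop_id, "name": c.name, "price": c.price,
               "is_aggregate": int(c.is_aggregate)}
        for s, name in enumerate(SYSTEMS):
            row[f"ci_{name}"] = c.cropping_intensity[s]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT)


def read_crops(path) -> list[CropDefinition]:
    frame = _read_csv(path)
    cols = ["crop_id", "name", "price", "is_aggregate"] + [f"ci_{s}" for s in SYSTEMS]
    _require(frame, cols, "crops")
    return [
        CropDefinition(
            crop_id=int(r.crop_id),
            name=str(r.name),
            price=float(r.price),
            cropping_intensity=tuple(
                float(getattr(r, f"ci_{s}")) for s in SYSTEMS
            ),
            is_aggregate=bool(r.is_aggregate),
        )
        for r in frame.itertuples()
    ]


def write_ancillary(ancillary: AncillaryLayers, crop_path, pixel_path) -> None:
    shape = ancillary.rural_pop_density.shape
    rows, cols = np.indices(shape)
    recs = []
    for ci, cid in enumerate(ancillary.crop_ids):
        for s, sname in enumerate(SYSTEMS):
            recs.append(
                pd.DataFrame(
                    {
                        "row": rows.ravel(),
                        "col": cols.ravel(),
                        "crop_id": cid,
                        "system": sname,
                        "suitable_area_ha": ancillary.suitable_area[ci, s].ravel(),
                        "potential_yield_mt_ha": ancillary.potential_yield[ci, s].ravel(),
                    }
                )
            )
    pd.concat(recs, ignore_index=True).to_csv(crop_path, index=False, float_format=_FLOAT)
    pd.DataFrame(
        {
            "row": rows.ravel(),
            "col": cols.ravel(),
            "rural_pop_density": ancillary.rural_pop_density.ravel(),
            "irrigated_area_ha": ancillary.irrigated_area.ravel(),
        }
    ).to_csv(pixel_path, index=False, float_format=_FLOAT)


def read_ancillary(crop_path, pixel_path) -> AncillaryLayers:
    cf = _read_csv(crop_path)
    _require(
        cf,
        ("row", "col", "crop_id", "system", "suitable_area_ha", "potential_yield_mt_ha"),
        "ancillary (crop)",
    )
    pf = _read_csv(pixel_path)
    _require(pf, ("row", "col", "rural_pop_density", "irrigated_area_ha"), "ancillary (pixel)")
    shape = _grid_shape(pf, "ancillary (pixel)")
    pf = pf.sort_values(["row", "col"])
    crop_ids = tuple(int(c) for c in sorted(cf["crop_id"].unique()))
    suit = np.zeros((len(crop_ids), len(SYSTEMS), *shape))
    pyld = np.zeros_like(suit)
    sys_pos = {s: i for i, s in enumerate(SYSTEMS)}
    for (cid, sname), grp in cf.groupby(["crop_id", "system"]):
        if sname not in sys_pos:
            raise SchemaError(f"ancillary (crop): unknown system {sname!r}")
        if len(grp) != shape[0] * shape[1]:
            raise SchemaError(f"ancillary (crop): incomplete grid for crop {cid}/{sname}")
        grp = grp.sort_values(["row", "col"])
        i = crop_ids.index(int(cid))
        suit[i, sys_pos[sname]] = grp["suitable_area_ha"].to_numpy().reshape(shape)
        pyld[i, sys_pos[sname]] = grp["potential_yield_mt_ha"].to_numpy().reshape(shape)
    return AncillaryLayers(
        crop_ids=crop_ids,
        suitable_area=suit,
        potential_yield=pyld,
        rural_pop_density=pf["rural_pop_density"].to_numpy().reshape(shape),
        irrigated_area=pf["irrigated_area_ha"].to_numpy().reshape(shape),
    )


def write_truth(truth: TrueAllocation, path) -> None:
    shape = truth.physical_area.shape[2:]
    rows, cols = np.indices(shape)
    recs = []
    for ci, cid in enumerate(truth.crop_ids):
        for s, sname in enumerate(SYSTEMS):
            recs.append(
                pd.DataFrame(
                    {
                        "row": rows.ravel(),
                        "col": cols.ravel(),
                        "crop_id": cid,
                        "system": sname,
                        "physical_area_ha": truth.physical_area[ci, s].ravel(),
                        "yield_mt_ha": truth.yields[ci, s].ravel(),
                    }
                )
            )
    pd.concat(recs, ignore_index=True).to_csv(path, index=False, float_format=_FLOAT)


def read_truth(path) -> TrueAllocation:
    frame = _read_csv(path)
    _require(
        frame,
        ("row", "col", "crop_id", "system", "physical_area_ha", "yield_mt_ha"),
        "truth",
    )
    crop_ids = tuple(int(c) for c in sorted(frame["crop_id"].unique()))
    shape = (int(frame["row"].max()) + 1, int(frame["col"].max()) + 1)
    phys = np.zeros((len(crop_ids), len(SYSTEMS), *shape))
    ylds = np.zeros_like(phys)
    sys_pos = {s: i for i, s in enumerate(SYSTEMS)}
    for (cid, sname), grp in frame.groupby(["crop_id", "system"]):
        grp = grp.sort_values(["row", "col"])
        i = crop_ids.index(int(cid))
        phys[i, sys_pos[str(sname)]] = grp["physical_area_ha"].to_numpy().reshape(shape)
        ylds[i, sys_pos[str(sname)]] = grp["yield_mt_ha"].to_numpy().reshape(shape)
    return TrueAllocation(crop_ids=crop_ids, physical_area=phys, yields=ylds)


def write_sru_table(table: pd.DataFrame, path) -> None:
    validate_sru_table(table)
    table.to_csv(path, index=False, float_format=_FLOAT)


def read_sru_table(path) -> pd.DataFrame:
    frame = _read_csv(path)
    validate_sru_table(frame)
    return frame


def write_allocation(result: AllocationResult, out_dir) -> dict[str, str]:
    """Write an allocation as crop-level and system-level CSVs plus metadata.

    Returns the mapping of logical names to file paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    shape = result.harvested_area.shape[1:]
    rows, cols = np.indices(shape)
    recs = []
    for ci, cid in enumerate(result.crop_ids):
        recs.append(
            pd.DataFrame(
                {
                    "row": rows.ravel(),
                    "col": cols.ravel(),
                    "crop_id": cid,
                    "harvested_area_ha": result.harvested_area[ci].ravel(),
                    "production_mt": result.production[ci].ravel(),
                    "yield_mt_ha": result.yield_[ci].ravel(),
                }
            )
        )
    crop_csv = out_dir / "allocation.csv"
    pd.concat(recs, ignore_index=True).to_csv(crop_csv, index=False, float_format=_FLOAT)

    recs = []
    for ci, cid in enumerate(result.crop_ids):
        for s, sname in enumerate(result.systems):
            recs.append(
                pd.DataFrame(
                    {
                        "row": rows.ravel(),
                        "col": cols.ravel(),
                        "crop_id": cid,
                        "system": sname,
                        "physical_area_ha": result.physical_area[ci, s].ravel(),
                    }
                )
            )
    phys_csv = out_dir / "physical.csv"
    pd.concat(recs, ignore_index=True).to_csv(phys_csv, index=False, float_format=_FLOAT)

    meta = {
        "crop_ids": list(result.crop_ids),
        "systems": list(result.systems),
        "provenance": _jsonable(result.provenance),
        "adjust_flags": {str(k): bool(v) for k, v in result.adjust_flags.items()},
    }
    meta_json = out_dir / "allocation_meta.json"
    meta_json.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return {
        "allocation": str(crop_csv),
        "physical": str(phys_csv),
        "meta": str(meta_json),
    }


def read_allocation(out_dir) -> AllocationResult:
    out_dir = Path(out_dir)
    meta = json.loads((out_dir / "allocation_meta.json").read_text())
    crop_ids = tuple(int(c) for c in meta["crop_ids"])
    systems = tuple(meta["systems"])
    cf = _read_csv(out_dir / "allocation.csv")
    _require(
        cf,
        ("row", "col", "crop_id", "harvested_area_ha", "production_mt", "yield_mt_ha"),
        "allocation",
    )
    shape = (int(cf["row"].max()) + 1, int(cf["col"].max()) + 1)
    harvested = np.zeros((len(crop_ids), *shape))
    production = np.zeros_like(harvested)
    yield_ = np.zeros_like(harvested)
    for cid, grp in cf.groupby("crop_id"):
        grp = grp.sort_values(["row", "col"])
        i = crop_ids.index(int(cid))
        harvested[i] = grp["harvested_area_ha"].to_numpy().reshape(shape)
        production[i] = grp["production_mt"].to_numpy().reshape(shape)
        yield_[i] = grp["yield_mt_ha"].to_numpy().reshape(shape)
    pf = _read_csv(out_dir / "physical.csv")
    _require(pf, ("row", "col", "crop_id", "system", "physical_area_ha"), "physical")
    physical = np.zeros((len(crop_ids), len(systems), *shape))
    for (cid, sname), grp in pf.groupby(["crop_id", "system"]):
        grp = grp.sort_values(["row", "col"])
        physical[crop_ids.index(int(cid)), systems.index(str(sname))] = (
            grp["physical_area_ha"].to_numpy().reshape(shape)
        )
    return AllocationResult(
        crop_ids=crop_ids,
        systems=systems,
        physical_area=physical,
        harvested_area=harvested,
        production=production,
        yield_=yield_,
        provenance=meta.get("provenance", {}),
        adjust_flags={int(k): bool(v) for k, v in meta.get("adjust_flags", {}).items()},
    )


def write_config(config: EntropyConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_jsonable(dataclasses.asdict(config))))


def read_config(path) -> EntropyConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(EntropyConfig)}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"config: unknown keys {sorted(unknown)}")
    if "rainfed_split" in raw:
        raw["rainfed_split"] = tuple(raw["rainfed_split"])
    return EntropyConfig(**raw)


def validate_inputs(
    landscape: Landscape,
    ancillary: AncillaryLayers | None,
    sru_table: pd.DataFrame | None,
) -> list[str]:
    """Cross-check inputs; returns an itemized list of problems (empty = ok)."""
    issues: list[str] = []
    try:
        landscape.validate()
    except ValidationError as exc:
        issues.append(f"landscape: {exc}")
    if ancillary is not None:
        try:
            ancillary.validate(landscape)
        except ValidationError as exc:
            issues.append(f"ancillary: {exc}")
    if sru_table is not None:
        try:
            validate_sru_table(sru_table)
        except (ValidationError, SchemaError) as exc:
            issues.append(f"sru_table: {exc}")
        else:
            pos = sru_table["harvested_area_ha"] > 0
            implied = (
                sru_table.loc[pos, "production_mt"]
                / sru_table.loc[pos, "harvested_area_ha"]
            )
            bad = ~np.isclose(
                implied, sru_table.loc[pos, "yield_mt_ha"], rtol=1e-9, atol=1e-12
            )
            for idx in sru_table.loc[pos].index[bad]:
                issues.append(
                    f"sru_table row {idx}: yield inconsistent with production/area "
                    "(repair: recompute yield)"
                )
            for row in sru_table.itertuples():
                level = int(row.admin_level)
                if level in landscape.admin_code:
                    if not landscape.unit_mask(level, int(row.sru_id)).any():
                        issues.append(
                            f"sru_table row {row.Index}: orphan unit {row.sru_id} "
                            f"absent from landscape level {level}"
                        )
    return issues


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def build_manifest(
    outputs: dict[str, str],
    *,
    seed: int | None = None,
    config: dict | None = None,
    extra: dict | None = None,
) -> dict:
    """A reproducibility manifest: digests, seeds and config snapshot."""
    manifest = {
        "outputs": {
            name: {"path": str(p), "sha256": file_digest(p)}
            for name, p in outputs.items()
        },
        "seed": seed,
        "config": _jsonable(config) if config else None,
    }
    if extra:
        manifest.update(_jsonable(extra))
    return manifest


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
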