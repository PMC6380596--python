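"""Spatial concordance metrics.

The pixel similarity of two nonnegative surfaces is
``1 - |a - b| / max(a, b)``, evaluated only where at least one surface is
non-zero; crop-level similarity is the mean over those compared pixels, and
the country-level score is the harvested-area-weighted mean of crop scores
(weights always taken from the designated baseline). A global Moran's I
(queen or rook contiguity, row-standardized) diagnoses spatial clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .errors import ExcludedPixelError, UndefinedStatisticError, ValidationError
from .smoothing import KernelSpec, focal_smooth
from .types import PRESENCE_THRESHOLD, AllocationResult, CropDefinition, Landscape

VARIABLES = ("harvested", "production", "yield")


def ssi_pixel(a: float, b: float) -> float:
    """Similarity of one pixel pair: ``1 - |a - b| / max(a, b)`` in [0, 1]."""
    if a < 0 or b < 0:
        raise ValidationError("similarity inputs must be nonnegative")
    m = max(a, b)
    if m == 0:
        raise ExcludedPixelError("both values zero: pixel excluded upstream")
    return 1.0 - abs(a - b) / m


def ssi_raster(
    a: np.ndarray,
    b: np.ndarray,
    *,
    threshold: float = PRESENCE_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel similarity plus the compared-pixel mask.

    A pixel enters the comparison when either input exceeds ``threshold``;
    elsewhere the similarity raster holds NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("rasters are not co-registered")
    if np.any(a < 0) or np.any(b < 0):
        raise ValidationError("similarity inputs must be nonnegative")
    compared = (a > threshold) | (b > threshold)
    m = np.maximum(a, b)
    out = np.full(a.shape, np.nan)
    out[compared] = 1.0 - np.abs(a - b)[compared] / m[compared]
    return out, compared


def ssi_crop(ssi_values: np.ndarray, mask: np.ndarray) -> float:
    """Mean similarity over the compared pixels."""
    n = int(mask.sum())
    if n == 0:
        raise UndefinedStatisticError("no compared pixels: crop similarity undefined")
    return float(np.asarray(ssi_values)[mask].mean())


def ssi_country(ssi_crop_values, crop_harvested_areas) -> float:
    """Harvested-area-weighted mean of crop-level similarities."""
    v = np.asarray(ssi_crop_values, dtype=float)
    w = np.asarray(crop_harvested_areas, dtype=float)
    if v.shape != w.shape:
        raise ValidationError("values and weights differ in length")
    if np.any(w < 0):
        raise ValidationError("weights must be nonnegative")
    tw = w.sum()
    if tw == 0:
        raise UndefinedStatisticError("all-zero weights: country similarity undefined")
    return float(np.dot(v, w) / tw)


def _contiguity(mask: np.ndarray, contiguity: str) -> sparse.csr_matrix:
    """Binary adjacency among masked pixels (queen or rook)."""
    if contiguity == "rook":
        steps = ((-1, 0), (1, 0), (0, -1), (0, 1))
    elif contiguity == "queen":
        steps = tuple(
            (di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)
        )
    else:
        raise ValidationError(f"unknown contiguity {contiguity!r}")
    idx = np.full(mask.shape, -1, dtype=np.int64)
    rows, cols = np.nonzero(mask)
    idx[rows, cols] = np.arange(len(rows))
    src, dst = [], []
    for di, dj in steps:
        ri, rj = rows + di, cols + dj
        ok = (0 <= ri) & (ri < mask.shape[0]) & (0 <= rj) & (rj < mask.shape[1])
        ok &= np.where(ok, mask[ri % mask.shape[0], rj % mask.shape[1]], False)
        src.append(idx[rows[ok], cols[ok]])
        dst.append(idx[ri[ok], rj[ok]])
    src = np.concatenate(src)
    dst = np.concatenate(dst)
    n = len(rows)
    return sparse.csr_matrix(
        (np.ones(len(src)), (src, dst)), shape=(n, n)
    )


def morans_i(
    raster: np.ndarray,
    mask: np.ndarray | None = None,
    *,
    contiguity: str = "queen",
) -> float:
    """Global Moran's I with row-standardized contiguity weights.

    -1 indicates perfect dispersion, values near ``-1/(n-1)`` spatial
    randomness, +1 perfect clustering.
    """
    raster = np.asarray(raster, dtype=float)
    if mask is None:
        mask = np.ones(raster.shape, dtype=bool)
    x = raster[mask]
    n = x.size
    if n < 2:
        raise UndefinedStatisticError("need at least 2 pixels for Moran's I")
    z = x - x.mean()
    den = float(z @ z)
    if den == 0:
        raise UndefinedStatisticError("zero variance: Moran's I undefined")
    adj = _contiguity(mask, contiguity)
    degree = np.asarray(adj.sum(axis=1)).ravel()
    if np.any(degree == 0):
        raise UndefinedStatisticError("isolated pixel: weights matrix has empty row")
    # row-standardized: numerator_i = (z_i / k_i) * sum_{j in N(i)} z_j; S0 = n
    num = float((z / degree) @ (adj @ z))
    return num / den


def rmse_regression(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """RMSE of an OLS fit of ``a`` on ``b`` over ``mask``.

    Diagnostic only — unbounded and outlier-sensitive, so it is never used
    for scoring; the bounded pixel similarity above is the primary metric.
    """
    av, bv = np.asarray(a)[mask], np.asarray(b)[mask]
    if av.size < 2:
        raise UndefinedStatisticError("need at least 2 pixels for a regression fit")
    coeffs = np.polyfit(bv, av, 1)
    resid = av - np.polyval(coeffs, bv)
    return float(np.sqrt(np.mean(resid**2)))


@dataclass
class SimilarityReport:
    """Concordance of two allocations over one landscape."""

    crop_ids: tuple[int, ...]
    ssi_rasters: dict = field(default_factory=dict)  # (crop_id, var) -> ndarray
    n_compared: dict = field(default_factory=dict)  # (crop_id, var) -> int
    ssi_crop: dict = field(default_factory=dict)  # (crop_id, var) -> float | nan
    ssi_country: dict = field(default_factory=dict)  # var -> float
    weights: dict = field(default_factory=dict)  # crop_id -> baseline harvested ha
    morans_i_a: dict = field(default_factory=dict)  # (crop_id, var) -> float | nan
    morans_i_b: dict = field(default_factory=dict)
    presence_a: dict = field(default_factory=dict)  # crop_id -> percent
    presence_b: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (crop, variable) table, heatmap-ready."""
        rows = []
        for cid in self.crop_ids:
            for var in VARIABLES:
                rows.append(
                    {
                        "crop_id": cid,
                        "variable": var,
                        "ssi": self.ssi_crop.get((cid, var), np.nan),
                        "n_compared": self.n_compared.get((cid, var), 0),
                        "weight_ha": self.weights.get(cid, np.nan),
                        "morans_i_a": self.morans_i_a.get((cid, var), np.nan),
                        "morans_i_b": self.morans_i_b.get((cid, var), np.nan),
                    }
                )
        return pd.DataFrame(rows)


def compare(
    result_a: AllocationResult,
    result_b: AllocationResult,
    landscape: Landscape,
    crops: list[CropDefinition],
    kernel: KernelSpec,
    *,
    threshold: float = PRESENCE_THRESHOLD,
) -> SimilarityReport:
    """Smooth, score and aggregate the concordance of two allocations.

    ``result_b`` is the designated baseline: country-level weights are its
    per-crop harvested-area totals. Both inputs are focal-smoothed over the
    country mask before pixel similarities are computed.
    """
    from .scenarios import presence_share  # late import; avoids a cycle

    report = SimilarityReport(crop_ids=tuple(c.crop_id for c in crops))
    mask = landscape.country_mask
    for crop in crops:
        ia = result_a.crop_index(crop.crop_id)
        ib = result_b.crop_index(crop.crop_id)
        report.weights[crop.crop_id] = float(result_b.harvested_area[ib].sum())
        planes = {
            "harvested": (result_a.harvested_area[ia], result_b.harvested_area[ib]),
            "production": (result_a.production[ia], result_b.production[ib]),
            "yield": (result_a.yield_[ia], result_b.yield_[ib]),
        }
        for var, (pa, pb) in planes.items():
            sa = focal_smooth(pa, kernel, mask)
            sb = focal_smooth(pb, kernel, mask)
            rast, compared = ssi_raster(sa, sb, threshold=threshold)
            compared &= mask
            key = (crop.crop_id, var)
            report.ssi_rasters[key] = rast
            report.n_compared[key] = int(compared.sum())
            report.ssi_crop[key] = (
                ssi_crop(rast, compared) if compared.any() else np.nan
            )
            for target, res_plane in (
                (report.morans_i_a, sa),
                (report.morans_i_b, sb),
            ):
                try:
                    target[key] = morans_i(res_plane, mask)
                except UndefinedStatisticError:
                    target[key] = np.nan
        report.presence_a[crop.crop_id] = presence_share(
            result_a, landscape, crop.crop_id, threshold=threshold
        )
        report.presence_b[crop.crop_id] = presence_share(
            result_b, landscape, crop.crop_id, threshold=threshold
        )

    for var in VARIABLES:
        vals, wts = [], []
        for cid in report.crop_ids:
            v = report.ssi_crop.get((cid, var), np.nan)
            if not np.isnan(v):
                vals.append(v)
                wts.append(report.weights[cid])
        if vals and sum(wts) > 0:
            report.ssi_country[var] = ssi_country(vals, wts)
        else:
            report.ssi_country[var] = np.nan
    return report
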