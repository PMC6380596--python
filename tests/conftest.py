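import numpy as np
import pytest

import cropgrid as cg
from cropgrid.types import SYSTEMS, AncillaryLayers, EntropyConfig, Landscape


def toy_landscape(cropland, pixel_area=100.0, adm1=None, adm2=None):
    """Build a landscape from an explicit cropland array (single country)."""
    cropland = np.asarray(cropland, dtype=float)
    shape = cropland.shape
    if adm1 is None:
        adm1 = np.ones(shape, dtype=np.int64)
    if adm2 is None:
        adm2 = 100 * np.asarray(adm1) + 1
    return Landscape(
        pixel_area=pixel_area,
        cropland=cropland,
        admin_code={
            0: np.zeros(shape, dtype=np.int64),
            1: np.asarray(adm1, dtype=np.int64),
            2: np.asarray(adm2, dtype=np.int64),
        },
        country_mask=np.ones(shape, dtype=bool),
    )


def uniform_ancillary(landscape, crops, *, on_cropland_only=False, irrigated_frac=0.2):
    """Flat suitability/yield layers (optionally restricted to cropland)."""
    shape = landscape.shape
    base = np.ones(shape)
    if on_cropland_only:
        base = (landscape.cropland > 0).astype(float)
    n = len(crops)
    suit = np.broadcast_to(
        base * landscape.pixel_area * 0.9, (n, len(SYSTEMS), *shape)
    ).copy()
    pyld = np.broadcast_to(base * 2.0, (n, len(SYSTEMS), *shape)).copy()
    return AncillaryLayers(
        crop_ids=tuple(c.crop_id for c in crops),
        suitable_area=suit,
        potential_yield=pyld,
        rural_pop_density=np.full(shape, 40.0),
        irrigated_area=landscape.cropland * irrigated_frac,
    )


@pytest.fixture(scope="session")
def bundle():
    """A small but fully structured synthetic world, shared across tests."""
    landscape = cg.generate_landscape(16, 16, 2, 2, 3.0, seed=11)
    crops = cg.default_crops(3, seed=11)
    ancillary = cg.generate_ancillary(landscape, crops, 2.0, seed=11)
    truth = cg.generate_true_allocation(landscape, ancillary, crops, 1.5, seed=11)
    table2 = cg.aggregate_to_sru(truth, landscape, crops, 2)
    return {
        "landscape": landscape,
        "crops": crops,
        "ancillary": ancillary,
        "truth": truth,
        "table2": table2,
        "config": EntropyConfig(),
    }


@pytest.fixture(scope="session")
def entropy_result(bundle):
    priors = cg.build_priors(
        bundle["landscape"], bundle["ancillary"], bundle["crops"], bundle["config"]
    )
    return cg.allocate_cross_entropy(
        priors,
        bundle["table2"],
        bundle["landscape"],
        bundle["ancillary"],
        bundle["crops"],
        bundle["config"],
    )
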