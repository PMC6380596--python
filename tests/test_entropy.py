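import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import NonlinearConstraint, minimize

import cropgrid as cg
from cropgrid.entropy import _solve_sru_dual, access_weight
from cropgrid.errors import AllocationInfeasibleError, DegeneratePriorError
from cropgrid.types import EntropyConfig

from conftest import toy_landscape, uniform_ancillary


def slsqp_oracle(pi, targets, cap, upper):
    """Independent generic convex solver for the per-SRU program.

    Variables are the flattened shares; the objective sum s ln(s/pi) and the
    linear constraints are handed to SLSQP without any knowledge of the
    package's dual formulation.
    """
    n_var, n_px = pi.shape
    t = targets

    def objective(x):
        s = x.reshape(n_var, n_px)
        with np.errstate(divide="ignore", invalid="ignore"):
            val = np.where(s > 1e-300, s * np.log(s / pi), 0.0)
        return val.sum()

    cons = []
    for v in range(n_var):
        mask = np.zeros((n_var, n_px))
        mask[v] = 1.0
        cons.append({
            "type": "eq",
            "fun": lambda x, m=mask.ravel(): x @ m - 1.0,
        })
    load = np.repeat(t, n_px).reshape(n_var, n_px).ravel()
    for p in range(n_px):
        sel = np.zeros((n_var, n_px))
        sel[:, p] = 1.0
        cons.append({
            "type": "ineq",
            "fun": lambda x, m=(sel.ravel() * load), c=cap[p]: c - x @ m,
        })
    bounds = []
    for v in range(n_var):
        for p in range(n_px):
            hi = min(1.0, upper[v, p] / t[v]) if np.isfinite(upper[v, p]) else 1.0
            bounds.append((0.0, hi))
    x0 = (pi / pi.sum(axis=1, keepdims=True)).ravel()
    x0 = np.minimum(x0, [b[1] for b in bounds])
    res = minimize(objective, x0, method="SLSQP", bounds=bounds,
                   constraints=cons, options={"maxiter": 2000, "ftol": 1e-14})
    assert res.success, res.message
    return res.x.reshape(n_var, n_px), res.fun


def random_instance(rng, n_px, n_var):
    """A random feasible per-SRU instance (may have binding constraints)."""
    pi = rng.uniform(0.05, 1.0, size=(n_var, n_px))
    pi /= pi.sum(axis=1, keepdims=True)
    targets = rng.uniform(0.5, 2.0, size=n_var)
    # capacity somewhere between tight and loose, but feasible
    cap = rng.uniform(0.3, 1.2, size=n_px) * targets.sum() / n_px
    while cap.sum() < targets.sum() * 1.05:
        cap *= 1.1
    upper = np.full((n_var, n_px), np.inf)
    if rng.random() < 0.5:  # add elementwise caps on half the instances
        upper = rng.uniform(0.4, 2.0, size=(n_var, n_px)) * targets[:, None] / n_px * 3
        for v in range(n_var):
            while upper[v].sum() < targets[v] * 1.05:
                upper[v] *= 1.1
    return pi, targets, cap, upper


class TestSolverOracle:
    def test_prior_returned_when_feasible(self):
        pi = np.array([[0.25, 0.75], [0.5, 0.5]])
        targets = np.array([1.0, 1.0])
        cap = np.array([100.0, 100.0])
        upper = np.full((2, 2), np.inf)
        s, obj, info = _solve_sru_dual(np.log(pi), targets, cap, upper, 1e-8, 1000)
        np.testing.assert_allclose(s, pi, atol=1e-9)
        assert obj == pytest.approx(0.0, abs=1e-12)

    def test_two_pixel_binding_cap(self):
        # brute-force oracle on the 1-D simplex: cap 0.3 of the target on
        # pixel 1 forces s = (0.3, 0.7)
        pi = np.array([[0.5, 0.5]])
        targets = np.array([1.0])
        cap = np.array([0.3, 10.0])
        upper = np.full((1, 2), np.inf)
        grid = np.linspace(1e-6, 0.3, 30001)
        kl = grid * np.log(grid / 0.5) + (1 - grid) * np.log((1 - grid) / 0.5)
        best = grid[np.argmin(kl)]
        s, obj, _ = _solve_sru_dual(np.log(pi), targets, cap, upper, 1e-8, 1000)
        assert best == pytest.approx(0.3, abs=1e-4)
        np.testing.assert_allclose(s, [[0.3, 0.7]], atol=1e-7)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_generic_solver(self, seed):
        rng = np.random.default_rng(seed)
        pi, targets, cap, upper = random_instance(rng, n_px=4, n_var=3)
        s, obj, _ = _solve_sru_dual(np.log(pi), targets, cap, upper, 1e-8, 5000)
        s_ref, obj_ref = slsqp_oracle(pi, targets, cap, upper)
        assert obj == pytest.approx(obj_ref, abs=1e-6)
        np.testing.assert_allclose(s, s_ref, atol=1e-5)

    def test_relaxation_lowers_objective(self):
        rng = np.random.default_rng(3)
        pi, targets, cap, upper = random_instance(rng, n_px=5, n_var=2)
        _, tight, _ = _solve_sru_dual(np.log(pi), targets, cap, upper, 1e-8, 5000)
        _, loose, _ = _solve_sru_dual(
            np.log(pi), targets, cap * 10, np.full_like(upper, np.inf), 1e-8, 5000)
        assert loose <= tight + 1e-9


class TestBuildPriors:
    def test_price_invariance_when_disabled(self, bundle):
        land, anc = bundle["landscape"], bundle["ancillary"]
        crops = bundle["crops"]
        scaled = [
            dataclasses.replace(c, price=c.price * 7.5) for c in crops
        ]
        cfg = EntropyConfig(use_prices=False)
        a = cg.build_priors(land, anc, crops, cfg)
        b = cg.build_priors(land, anc, scaled, cfg)
        np.testing.assert_array_equal(a.pi, b.pi)

    def test_uniform_inputs_uniform_prior(self):
        land = toy_landscape(np.full((3, 3), 50.0))
        crops = [cg.CropDefinition(crop_id=1, name="c")]
        anc = uniform_ancillary(land, crops, on_cropland_only=True)
        cfg = EntropyConfig(use_market_access=False)
        priors = cg.build_priors(land, anc, crops, cfg)
        np.testing.assert_allclose(priors.pi[0, 1], np.full((3, 3), 1 / 9), rtol=1e-12)

    def test_monotone_in_suitability(self, bundle):
        land, anc, crops = bundle["landscape"], bundle["ancillary"], bundle["crops"]
        cfg = bundle["config"]
        base = cg.build_priors(land, anc, crops, cfg)
        bumped = dataclasses.replace(anc)
        bumped.suitable_area = anc.suitable_area.copy()
        r, c = 5, 5
        bumped.suitable_area[0, 1, r, c] = min(
            anc.suitable_area[0, 1, r, c] * 2, land.pixel_area)
        assert bumped.suitable_area[0, 1, r, c] > anc.suitable_area[0, 1, r, c]
        after = cg.build_priors(land, bumped, crops, cfg)
        assert after.pi[0, 1, r, c] > base.pi[0, 1, r, c]

    def test_degenerate_prior_raises_and_falls_back(self):
        land = toy_landscape(np.full((2, 2), 50.0))
        crops = [cg.CropDefinition(crop_id=1, name="c")]
        anc = uniform_ancillary(land, crops)
        anc.suitable_area[:] = 0.0
        cfg = EntropyConfig()
        with pytest.raises(DegeneratePriorError):
            cg.build_priors(land, anc, crops, cfg)
        priors = cg.build_priors(land, anc, crops, cfg, on_degenerate="cropland")
        np.testing.assert_allclose(priors.pi[0, 0].sum(), 1.0)

    def test_normalized(self, bundle):
        priors = cg.build_priors(
            bundle["landscape"], bundle["ancillary"], bundle["crops"],
            bundle["config"])
        np.testing.assert_allclose(priors.pi.sum(axis=(2, 3)), 1.0, rtol=1e-9)

    def test_access_weight_shape(self):
        d = np.array([0.0, 10.0, 1000.0])
        w = access_weight(d)
        assert np.all(np.diff(w) > 0) and np.all((w >= 1) & (w < 2))
        ws = access_weight(d, subsistence=True)
        assert np.all(np.diff(ws) < 0)


class TestAdjustCropland:
    def _one_sru(self, cropland, harvested):
        land = toy_landscape(np.asarray(cropland, dtype=float))
        crops = [cg.CropDefinition(crop_id=1, name="c")]
        table = pd.DataFrame([{
            "sru_id": 0, "admin_level": 0, "crop_id": 1,
            "harvested_area_ha": harvested,
            "production_mt": harvested * 2.0,
            "yield_mt_ha": 2.0 if harvested > 0 else 0.0,
        }])
        return land, crops, table

    def test_feasible_unchanged(self):
        land, crops, table = self._one_sru([[60.0, 40.0]], 80.0)
        cap, flags = cg.adjust_cropland(land, table, crops, 2.0)
        np.testing.assert_array_equal(cap, land.cropland)
        assert flags == {0: False}

    def test_minimal_scaling(self):
        # required 120 on cropland 100 -> every capacity x 1.2
        land, crops, table = self._one_sru([[60.0, 40.0]], 120.0)
        cap, flags = cg.adjust_cropland(land, table, crops, 2.0)
        np.testing.assert_allclose(cap, [[72.0, 48.0]], rtol=1e-12)
        assert flags == {0: True}

    def test_zero_required_unchanged(self):
        land, crops, table = self._one_sru([[60.0, 40.0]], 0.0)
        cap, flags = cg.adjust_cropland(land, table, crops, 2.0)
        np.testing.assert_array_equal(cap, land.cropland)
        assert flags == {0: False}

    def test_hard_infeasibility(self):
        land, crops, table = self._one_sru([[60.0, 40.0]], 500.0)
        with pytest.raises(AllocationInfeasibleError):
            cg.adjust_cropland(land, table, crops, 1.5)


class TestAllocateCrossEntropy:
    def test_constraints_and_conservation(self, bundle, entropy_result):
        land, table = bundle["landscape"], bundle["table2"]
        res = entropy_result
        totals = res.physical_area.sum(axis=(0, 1))
        scale = max(land.cropland.max(), 1.0)
        assert np.all(totals - land.cropland <= 1e-6 * scale)
        for (sid, level), rows in table.groupby(["sru_id", "admin_level"]):
            mask = land.unit_mask(int(level), int(sid))
            for row in rows.itertuples():
                i = res.crop_index(int(row.crop_id))
                assert res.harvested_area[i][mask].sum() == pytest.approx(
                    row.harvested_area_ha, rel=1e-6)
                assert res.production[i][mask].sum() == pytest.approx(
                    row.production_mt, rel=1e-6)

    def test_suitability_cap_respected(self, bundle, entropy_result):
        anc = bundle["ancillary"]
        res = entropy_result
        scale = max(bundle["landscape"].pixel_area, 1.0)
        assert np.all(res.physical_area - anc.suitable_area <= 1e-6 * scale)

    def test_irrigated_cap_respected(self, bundle, entropy_result):
        anc = bundle["ancillary"]
        irr = entropy_result.physical_area[:, 0]  # irrigated system plane
        scale = max(bundle["landscape"].pixel_area, 1.0)
        assert np.all(irr - anc.irrigated_area[None] <= 1e-6 * scale)

    def test_deterministic(self, bundle, entropy_result):
        priors = cg.build_priors(
            bundle["landscape"], bundle["ancillary"], bundle["crops"],
            bundle["config"])
        res2 = cg.allocate_cross_entropy(
            priors, bundle["table2"], bundle["landscape"], bundle["ancillary"],
            bundle["crops"], bundle["config"])
        np.testing.assert_array_equal(res2.physical_area, entropy_result.physical_area)

    def test_uniform_symmetry(self):
        # uniform prior, no binding constraints -> uniform over cropland px
        land = toy_landscape(np.full((2, 3), 80.0))
        crops = [cg.CropDefinition(crop_id=1, name="c")]
        anc = uniform_ancillary(land, crops, irrigated_frac=0.5)
        table = pd.DataFrame([{
            "sru_id": 0, "admin_level": 0, "crop_id": 1,
            "harvested_area_ha": 60.0, "production_mt": 120.0,
            "yield_mt_ha": 2.0,
        }])
        cfg = EntropyConfig(use_market_access=False)
        priors = cg.build_priors(land, anc, crops, cfg)
        res = cg.allocate_cross_entropy(priors, table, land, anc, crops, cfg)
        np.testing.assert_allclose(
            res.harvested_area[0], np.full((2, 3), 10.0), rtol=1e-6)
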