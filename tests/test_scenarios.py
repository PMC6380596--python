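import numpy as np
import pandas as pd
import pytest

import cropgrid as cg
from cropgrid.errors import UndefinedStatisticError, ValidationError
from cropgrid.scenarios import ScenarioSpec, default_merge_map, run_scenario
from cropgrid.types import EntropyConfig

from conftest import toy_landscape, uniform_ancillary


class TestScenarioSpec:
    def test_unknown_id_rejected(self):
        with pytest.raises(ValidationError):
            ScenarioSpec(scenario_id="nonsense")

    def test_merge_map_required_iff_crop_choice(self):
        with pytest.raises(ValidationError):
            ScenarioSpec(scenario_id="crop_choice")
        with pytest.raises(ValidationError):
            ScenarioSpec(scenario_id="baseline", crop_merge_map={9: [1, 2]})
        ScenarioSpec(scenario_id="crop_choice", crop_merge_map={9: [1, 2]})


class TestMergeCrops:
    def _crops(self):
        return [
            cg.CropDefinition(crop_id=1, name="a", price=100.0),
            cg.CropDefinition(crop_id=2, name="b", price=300.0),
        ]

    def _table(self):
        return pd.DataFrame([
            {"sru_id": 0, "admin_level": 0, "crop_id": 1,
             "harvested_area_ha": 10.0, "production_mt": 20.0, "yield_mt_ha": 2.0},
            {"sru_id": 0, "admin_level": 0, "crop_id": 2,
             "harvested_area_ha": 30.0, "production_mt": 90.0, "yield_mt_ha": 3.0},
        ])

    def test_weighted_price(self):
        # areas 10 and 30, prices 100 and 300 -> 0.25*100 + 0.75*300 = 250
        crops, table = self._crops(), self._table()
        merged_crops, merged = cg.merge_crops(crops, table, {9: [1, 2]})
        assert len(merged_crops) == 1
        assert merged_crops[0].price == pytest.approx(250.0)
        assert merged_crops[0].is_aggregate

    def test_sums_and_yield_identity(self):
        crops, table = self._crops(), self._table()
        _, merged = cg.merge_crops(crops, table, {9: [1, 2]})
        assert merged.harvested_area_ha.iloc[0] == pytest.approx(40.0)
        assert merged.production_mt.iloc[0] == pytest.approx(110.0)
        assert merged.yield_mt_ha.iloc[0] == pytest.approx(110.0 / 40.0)

    def test_identity_map(self):
        crops, table = self._crops(), self._table()
        out_crops, out = cg.merge_crops(crops, table, {})
        assert out_crops == crops
        pd.testing.assert_frame_equal(
            out.reset_index(drop=True), table, check_dtype=False)

    def test_double_mapping_rejected(self):
        crops, table = self._crops(), self._table()
        with pytest.raises(ValidationError):
            cg.merge_crops(crops, table, {8: [1], 9: [1, 2]})


class TestPresenceShare:
    def test_counting(self):
        land = toy_landscape(np.array([[10.0, 10.0], [10.0, 10.0]]))
        crops = [cg.CropDefinition(crop_id=1, name="c")]
        harvested = np.array([[[5.0, 5.0], [5.0, 0.0]]])
        res = cg.AllocationResult(
            crop_ids=(1,), systems=("composite",),
            physical_area=harvested[:, None], harvested_area=harvested,
            production=harvested * 2, yield_=np.where(harvested > 0, 2.0, 0.0),
        )
        assert cg.presence_share(res, land, 1) == pytest.approx(75.0)

    def test_absent_crop(self):
        land = toy_landscape(np.full((2, 2), 10.0))
        zeros = np.zeros((1, 2, 2))
        res = cg.AllocationResult(
            crop_ids=(1,), systems=("composite",),
            physical_area=zeros[:, None], harvested_area=zeros,
            production=zeros, yield_=zeros,
        )
        assert cg.presence_share(res, land, 1) == 0.0

    def test_zero_cropland_undefined(self):
        land = toy_landscape(np.zeros((2, 2)))
        zeros = np.zeros((1, 2, 2))
        res = cg.AllocationResult(
            crop_ids=(1,), systems=("composite",),
            physical_area=zeros[:, None], harvested_area=zeros,
            production=zeros, yield_=zeros,
        )
        with pytest.raises(UndefinedStatisticError):
            cg.presence_share(res, land, 1)

    def test_over_100_requires_adjustment(self):
        # SRU must place 1.2x its cropland: flag raised, spill onto the
        # zero-cropland pixel lifts presence above 100%
        cropland = np.array([[50.0, 50.0, 0.0]])
        land = toy_landscape(cropland)
        crops = [cg.CropDefinition(crop_id=1, name="c")]
        anc = uniform_ancillary(land, crops)
        table = pd.DataFrame([{
            "sru_id": 0, "admin_level": 0, "crop_id": 1,
            "harvested_area_ha": 120.0, "production_mt": 240.0,
            "yield_mt_ha": 2.0,
        }])
        cfg = EntropyConfig()
        priors = cg.build_priors(land, anc, crops, cfg)
        res = cg.allocate_cross_entropy(priors, table, land, anc, crops, cfg)
        assert res.adjust_flags[0] is True
        assert cg.presence_share(res, land, 1) > 100.0


class TestRunScenario:
    def test_all_scenarios_run_and_conserve(self, bundle):
        land, crops = bundle["landscape"], bundle["crops"]
        anc, table, cfg = bundle["ancillary"], bundle["table2"], bundle["config"]
        country = table.groupby("crop_id")["production_mt"].sum()
        for sid in cg.SCENARIO_IDS:
            mm = default_merge_map(crops) if sid == "crop_choice" else None
            res = run_scenario(
                ScenarioSpec(scenario_id=sid, crop_merge_map=mm),
                land, anc, crops, table, cfg)
            assert res.provenance["scenario"] == sid
            if sid == "crop_choice":
                merged_country = {}
                for gid, members in mm.items():
                    merged_country[gid] = country[members].sum()
                for cid in res.crop_ids:
                    expected = merged_country.get(cid, country.get(cid))
                    got = res.production[res.crop_index(cid)].sum()
                    assert got == pytest.approx(expected, rel=1e-6)
            else:
                for cid in res.crop_ids:
                    got = res.production[res.crop_index(cid)].sum()
                    assert got == pytest.approx(country[cid], rel=1e-6)

    def test_crop_price_noop_with_unit_prices(self, bundle):
        land, anc, table = bundle["landscape"], bundle["ancillary"], bundle["table2"]
        cfg = bundle["config"]
        crops = [
            cg.CropDefinition(c.crop_id, c.name, 1.0, c.cropping_intensity,
                              c.is_aggregate)
            for c in bundle["crops"]
        ]
        base = run_scenario(ScenarioSpec("baseline"), land, anc, crops, table, cfg)
        cp = run_scenario(ScenarioSpec("crop_price"), land, anc, crops, table, cfg)
        assert np.array_equal(base.physical_area, cp.physical_area)
        assert np.array_equal(base.production, cp.production)

    def test_adm1_only_fixed_point(self, bundle):
        land, crops = bundle["landscape"], bundle["crops"]
        anc, cfg = bundle["ancillary"], bundle["config"]
        t1 = cg.aggregate_to_sru(bundle["truth"], land, crops, 1)
        base = run_scenario(ScenarioSpec("baseline"), land, anc, crops, t1, cfg)
        a1 = run_scenario(ScenarioSpec("adm1_only"), land, anc, crops, t1, cfg)
        assert np.array_equal(base.physical_area, a1.physical_area)
        assert np.array_equal(base.harvested_area, a1.harvested_area)

    def test_remainder_residual_arithmetic(self):
        # 2-pixel toy: rest-of-crops area = max(0, cropland - named physical)
        land = toy_landscape(np.array([[60.0, 40.0]]))
        crops = [
            cg.CropDefinition(crop_id=1, name="named"),
            cg.CropDefinition(crop_id=2, name="rest", is_aggregate=True),
        ]
        anc = uniform_ancillary(land, crops)
        table = pd.DataFrame([
            {"sru_id": 0, "admin_level": 0, "crop_id": 1,
             "harvested_area_ha": 50.0, "production_mt": 100.0, "yield_mt_ha": 2.0},
            {"sru_id": 0, "admin_level": 0, "crop_id": 2,
             "harvested_area_ha": 30.0, "production_mt": 30.0, "yield_mt_ha": 1.0},
        ])
        cfg = EntropyConfig()
        res = run_scenario(
            ScenarioSpec("remainder_allocation"), land, anc, crops, table, cfg)
        named_phys = res.physical_area[res.crop_index(1)].sum(axis=0)
        rest_phys = res.physical_area[res.crop_index(2)].sum(axis=0)
        np.testing.assert_allclose(
            rest_phys, np.clip(land.cropland - named_phys, 0, None), rtol=1e-9)

    def test_scenario_errors_tagged(self, bundle):
        land, crops = bundle["landscape"], bundle["crops"]
        anc, cfg = bundle["ancillary"], bundle["config"]
        named_only = [c for c in crops if not c.is_aggregate]
        with pytest.raises(ValidationError, match="remainder_allocation"):
            run_scenario(
                ScenarioSpec("remainder_allocation"), land, anc,
                named_only, bundle["table2"], cfg)

    def test_deterministic(self, bundle):
        land, crops = bundle["landscape"], bundle["crops"]
        anc, table, cfg = bundle["ancillary"], bundle["table2"], bundle["config"]
        a = run_scenario(ScenarioSpec("adm0_only"), land, anc, crops, table, cfg)
        b = run_scenario(ScenarioSpec("adm0_only"), land, anc, crops, table, cfg)
        assert np.array_equal(a.physical_area, b.physical_area)
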