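"""Reconstruction of inorganic-arsenic concentrations per medium."""

import numpy as np
import pytest

from iasrisk.concentrations import (
    build_concentration_table,
    reconstruct_clam_iAs,
    reconstruct_crop_iAs,
    reconstruct_fish_iAs,
    sample_drinking_water_iAs,
    write_concentration_csv,
)
from iasrisk.config import CROPS, EnvironmentalInputs, ScenarioConfig
from iasrisk.distributions import (
    DistributionSpec,
    child_rng,
    truncated_normal_mean,
)


def point(value, units="dimensionless"):
    return DistributionSpec(family="point", value=value, units=units)


def point_env(lake=0.00735, baf=16.15, mult=1.0, frac=0.1295, soil=4.915,
              clam=5.67, water=0.00899):
    return EnvironmentalInputs(
        water_As=point(water, "mg/L"),
        soil_As=point(soil, "mg/kg"),
        lake_As=point(lake, "mg/L"),
        clam_total_As_dw=point(clam, "mg/kg"),
        BAF=point(baf, "L/kg"),
        dry_season_multiplier=point(mult),
        aquatic_iAs_fraction=point(frac),
    )


class TestFish:
    def test_zero_lake_water_gives_zero_fish(self):
        env = point_env(lake=0.0)
        out = reconstruct_fish_iAs(env, ["rainy", "dry"], 2, child_rng(0, "f"))
        assert np.all(out == 0)

    def test_point_value_chain(self):
        """lake 0.00735 mg/L x BAF 16.15 x mult 1 x fraction 0.1295 = 0.01537 ug/g."""
        env = point_env()
        out = reconstruct_fish_iAs(env, ["rainy"] * 3, 3, child_rng(0, "f"))
        np.testing.assert_allclose(out, 0.01537197, rtol=1e-6)

    def test_dry_season_applies_multiplier(self):
        env = point_env(mult=6.71)
        rainy = reconstruct_fish_iAs(env, ["rainy"] * 2, 2, child_rng(0, "f"))
        dry = reconstruct_fish_iAs(env, ["dry"] * 2, 2, child_rng(0, "f"))
        np.testing.assert_allclose(dry, 6.71 * rainy, rtol=1e-12)

    def test_bad_season_flags_rejected(self):
        env = point_env()
        with pytest.raises(ValueError, match="season"):
            reconstruct_fish_iAs(env, ["monsoon"], 1, child_rng(0, "f"))
        with pytest.raises(ValueError, match="length"):
            reconstruct_fish_iAs(env, ["rainy"], 2, child_rng(0, "f"))


class TestClam:
    def test_point_value_chain(self):
        """5.67 mg/kg dw x 0.1295 inorganic fraction = 0.7343 ug/g."""
        env = point_env()
        out = reconstruct_clam_iAs(env, 4, child_rng(0, "c"))
        np.testing.assert_allclose(out, 0.734265, rtol=1e-6)

    def test_stochastic_mean_matches_truncated_normal_oracle(self, params):
        """Mean clam iAs ~= E[TruncNorm(5.67,3,0,14.67)] x E[fraction]."""
        out = reconstruct_clam_iAs(params.environmental, 100_000, child_rng(1, "c"))
        expected = truncated_normal_mean(5.67, 3.0, 0.0, 14.67) * 0.1295
        assert out.mean() == pytest.approx(expected, rel=0.02)

    def test_interval_containment(self, params):
        out = reconstruct_clam_iAs(params.environmental, 20_000, child_rng(2, "c"))
        assert out.min() >= 0.117 * 0.0
        assert out.max() <= 0.142 * 14.67


class TestCrops:
    def test_point_value_chain_upper_bound(self):
        """soil 4.915 x TF 0.021 x fraction 0.9 = 0.0929 ug/g (rice midpoints)."""
        env = point_env()
        tf = _point_tf(rice=0.021)
        scenario = ScenarioConfig.upper_bound(n_iterations=2)
        out = reconstruct_crop_iAs("rice", env, tf, scenario, 2, child_rng(0, "r"))
        np.testing.assert_allclose(out, 0.0928935, rtol=1e-6)

    def test_unknown_crop_rejected(self, params):
        scenario = ScenarioConfig.lower_bound()
        with pytest.raises(KeyError, match="cassava"):
            reconstruct_crop_iAs(
                "cassava", params.environmental, params.transfer_factors,
                scenario, 1, child_rng(0, "x"),
            )

    def test_mean_concentration_ordering(self, lb_run):
        """Reconstructed crop iAs means order rice > corn > vegetables > root crops."""
        means = lb_run.concentrations[list(CROPS)].mean()
        assert (
            means["rice"] > means["corn"] > means["vegetables"] > means["root_crops"]
        )


def _point_tf(rice=0.021, corn=0.016, vegetables=0.01415, root_crops=0.0049):
    from iasrisk.config import TransferFactorTable

    return TransferFactorTable(
        factors={
            "rice": DistributionSpec(family="point", value=rice),
            "corn": DistributionSpec(family="point", value=corn),
            "vegetables": DistributionSpec(family="point", value=vegetables),
            "root_crops": DistributionSpec(family="point", value=root_crops),
        }
    )


class TestDrinkingWater:
    def test_geometric_mean_and_coverage(self, params):
        draws = sample_drinking_water_iAs(
            params.environmental, 100_000, child_rng(3, "w")
        )
        gm = np.exp(np.log(draws).mean())
        assert gm == pytest.approx(8.99166, rel=0.02)  # ug/L
        inside = np.mean((draws >= 0.735) & (draws <= 110.0))
        assert inside == pytest.approx(1 - 1 / 72, abs=0.005)

    def test_water_column_identical_between_scenarios(self, params):
        tables = {}
        for sid in ("LB", "UB"):
            scenario = ScenarioConfig(scenario_id=sid, n_iterations=500,
                                      random_seed=9)
            tables[sid] = build_concentration_table(
                params.environmental, params.transfer_factors, scenario
            )
        for col in ("drinking_water", "fish", "clam"):
            np.testing.assert_array_equal(tables["LB"][col], tables["UB"][col])


class TestConcentrationTable:
    def test_scenario_coupling_crops_scale_by_terrestrial_fraction(self, params):
        """Under a shared seed UB crop concentrations are exactly 1.8x LB."""
        tables = {}
        for sid in ("LB", "UB"):
            scenario = ScenarioConfig(scenario_id=sid, n_iterations=1000,
                                      random_seed=5)
            tables[sid] = build_concentration_table(
                params.environmental, params.transfer_factors, scenario
            )
        for crop in CROPS:
            np.testing.assert_allclose(
                tables["UB"][crop], 1.8 * tables["LB"][crop], rtol=1e-12
            )

    def test_soil_draw_shared_across_crops(self, lb_run):
        """One soil environment per individual: crop / TF recovers the same soil."""
        t = lb_run.concentrations
        frac = 0.5
        for crop, tf_col in zip(CROPS, ("TF_rice", "TF_corn", "TF_vegetables",
                                        "TF_root")):
            np.testing.assert_allclose(
                t[crop] / t[tf_col] / frac, t["soil_As"], rtol=1e-10
            )

    def test_linearity_in_soil(self, params):
        scenario = ScenarioConfig.lower_bound(n_iterations=200, random_seed=3)
        base = point_env(soil=2.0)
        doubled = point_env(soil=4.0)
        t1 = build_concentration_table(base, params.transfer_factors, scenario)
        t2 = build_concentration_table(doubled, params.transfer_factors, scenario)
        for crop in CROPS:
            np.testing.assert_allclose(t2[crop], 2 * t1[crop], rtol=1e-12)

    def test_dry_season_concentrations_dominate(self, params):
        """With common draws every dry-season fish value exceeds its rainy twin."""
        scenario = ScenarioConfig.lower_bound(n_iterations=2000, random_seed=5)
        rainy = build_concentration_table(
            params.environmental, params.transfer_factors, scenario, p_dry=0.0
        )
        dry = build_concentration_table(
            params.environmental, params.transfer_factors, scenario, p_dry=1.0
        )
        assert np.all(dry["fish"].to_numpy() >= rainy["fish"].to_numpy())
        # lower bound of the seasonal factor is 2.21 > 1, so strict dominance
        assert np.all(dry["fish"].to_numpy() > rainy["fish"].to_numpy())

    def test_csv_export_includes_units_row(self, lb_run, tmp_path):
        path = tmp_path / "conc.csv"
        write_concentration_csv(lb_run.concentrations.head(5), path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("fish,clam")
        assert "ug/g" in lines[1] and "ug/L" in lines[1]
        assert len(lines) == 7  # header + units + 5 rows
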