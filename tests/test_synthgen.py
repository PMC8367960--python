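"""Seeded generators: determinism, calibration, parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from meadow import erosion, forage, synthgen, tourism, vegdata
from meadow.synthgen import (
    GeneratorConfig,
    SynthGenError,
    gen_checkdams,
    gen_livestock,
    gen_quadrats,
    gen_soil,
    gen_survey,
    gen_visitors,
    gen_weather,
    generate_all,
)


class TestQuadratGenerator:
    def test_exact_mode_recovers_published_row(self):
        """Targets density 1.40, frequency 73.33 reproduce exactly through the analytics."""
        targets = pd.DataFrame(
            {"species": ["Achillea millefolium"], "density": [1.40],
             "frequency_pct": [73.33]}
        )
        obs = gen_quadrats(targets, n_quadrats=30, seed=1, exact=True)
        stats = vegdata.round_stats(
            vegdata.compute_species_stats(obs, vegdata.SurveyDesign(30))
        )
        assert stats.iloc[0]["density"] == 1.40
        assert stats.iloc[0]["frequency_pct"] == 73.33
        assert stats.iloc[0]["abundance"] == 1.91

    def test_whole_published_table_round_trips(self, zone_vegetation):
        """Exact mode reproduces density and frequency for all 47 published rows."""
        obs = gen_quadrats(zone_vegetation, n_quadrats=30, seed=1, exact=True)
        design = vegdata.SurveyDesign(30)
        for zone, grp in obs.groupby("zone"):
            stats = vegdata.round_stats(vegdata.compute_species_stats(grp, design))
            expected = (
                zone_vegetation.loc[zone_vegetation["zone"] == zone]
                .sort_values("species")
                .reset_index(drop=True)
            )
            assert list(stats["species"]) == list(expected["species"])
            assert np.allclose(stats["density"], expected["density"])
            assert np.allclose(stats["frequency_pct"], expected["frequency_pct"])

    def test_zero_density_species_absent(self):
        targets = pd.DataFrame(
            {"species": ["ghost"], "density": [0.0], "frequency_pct": [0.0]}
        )
        assert gen_quadrats(targets, seed=1).empty

    def test_infeasible_targets_rejected(self):
        targets = pd.DataFrame(
            {"species": ["x"], "density": [0.1], "frequency_pct": [50.0]}
        )
        with pytest.raises(SynthGenError):  # 3 individuals cannot fill 15 quadrats
            gen_quadrats(targets, seed=1)
        with pytest.raises(SynthGenError):
            gen_quadrats(
                pd.DataFrame({"species": ["x"], "density": [1.0],
                              "frequency_pct": [120.0]}),
                seed=1,
            )

    def test_stochastic_mode_recovers_density_in_expectation(self):
        """Mean recovered density over replicates stays within Monte-Carlo error."""
        target_density, occ_freq = 2.0, 80.0
        targets = pd.DataFrame(
            {"species": ["sp"], "density": [target_density],
             "frequency_pct": [occ_freq]}
        )
        densities = []
        for rep in range(200):
            obs = gen_quadrats(targets, n_quadrats=30, seed=1000 + rep, exact=False)
            stats = vegdata.compute_species_stats(obs, vegdata.SurveyDesign(30))
            densities.append(stats.iloc[0]["density"])
        se = np.std(densities, ddof=1) / np.sqrt(len(densities))
        assert abs(np.mean(densities) - target_density) <= 3 * max(se, 0.01)


class TestWeatherGenerator:
    @pytest.mark.parametrize("p, expected_cf", [(0.0, 1.0), (1.0, 0.0)])
    def test_degenerate_probabilities(self, p, expected_cf):
        weather = gen_weather("2018-01-01", "2018-12-31", p, 0.5, seed=2)
        cf = tourism.correction_factor_from_weather(weather, "rain")
        assert cf.value == expected_cf

    def test_heavy_day_rate_near_probability(self):
        p = 369 / 909
        weather = gen_weather("2017-01-01", "2019-12-31", p, 51 / 186, seed=2)
        cf = tourism.correction_factor_from_weather(weather, "rain")
        assert cf.value == pytest.approx(1 - p, abs=0.04)

    def test_amounts_respect_thresholds(self):
        weather = gen_weather("2018-06-01", "2018-06-30", 0.5, 0.5, seed=2)
        heavy = weather["rain_mm"] > 250
        assert heavy.any() and (~heavy).any()
        assert (weather.loc[~heavy, "rain_mm"] <= 250).all()


class TestLivestockGenerator:
    def test_noiseless_trend_recovered_exactly(self, animal_units):
        census = gen_livestock(range(2015, 2020), 881, -20, 0.0, animal_units,
                               seed=3, year0=2019)
        totals = pd.DataFrame(
            [
                {"year": year,
                 "cu": forage.to_cow_units(grp, animal_units)["total"]}
                for year, grp in census.groupby("year")
            ]
        )
        assert forage.cu_trend(totals) == pytest.approx(-20.0)

    def test_calibrated_total_is_exact(self, animal_units):
        census = gen_livestock([2019], 881, 0.0, 0.0, animal_units, seed=3)
        assert forage.to_cow_units(census, animal_units)["total"] == 881

    def test_noisy_slope_recovery(self, animal_units):
        census = gen_livestock(range(2010, 2020), 500, 33, 10.0, animal_units,
                               seed=3, year0=2010)
        totals = (
            census.merge(animal_units[["animal", "animal_unit"]], on="animal")
            .assign(cu=lambda d: d["count"] * d["animal_unit"])
            .groupby("year", as_index=False)["cu"].sum()
        )
        assert forage.cu_trend(totals) == pytest.approx(33, abs=10)


class TestCheckdamGenerator:
    def test_target_total_exact(self):
        dams = gen_checkdams(n=38, target_total=169.64, seed=4)
        total = sum(erosion.records_from_frame(dams)[i].debris_mass_t for i in range(38))
        assert total == pytest.approx(169.64, abs=1e-9)

    def test_single_dam(self):
        dams = gen_checkdams(n=1, target_total=5.0, seed=4)
        assert erosion.records_from_frame(dams)[0].debris_mass_t == pytest.approx(5.0)

    def test_zero_target(self):
        dams = gen_checkdams(n=5, target_total=0.0, seed=4)
        assert (dams["volume_m3"] == 0).all()

    def test_gully_assignment(self):
        dams = gen_checkdams(n=38, seed=4, n_gullies=3)
        assert set(dams["gully"]) == {"G1", "G2", "G3"}


class TestSoilGenerator:
    def test_zero_se_gives_constant(self, soil_chemistry):
        table = soil_chemistry.assign(se=0.0)
        draws = gen_soil(table, n_replicates=4, seed=5)
        merged = draws.merge(table, on=["zone", "variable"])
        assert np.allclose(merged["value"], merged["mean"])

    def test_sample_mean_near_population_mean(self, soil_chemistry):
        """GTZ pH draws at SE 0.28 average within 3 CLT standard errors."""
        row = soil_chemistry.query("zone == 'GTZ' and variable == 'soil_ph'")
        draws = gen_soil(row, n_replicates=200, seed=5)
        assert draws["value"].mean() == pytest.approx(4.96, abs=0.06)

    def test_truncation_keeps_physical_ranges(self):
        table = pd.DataFrame(
            {"zone": ["Z"], "variable": ["water_holding_capacity_pct"],
             "mean": [1.0], "se": [5.0]}
        )
        draws = gen_soil(table, n_replicates=500, seed=5)
        assert (draws["value"] >= 0).all()


class TestSurveyGenerator:
    @pytest.mark.parametrize(
        "probs, expected", [((0.0, 0.0, 1.0), 3.0), ((1.0, 0.0, 0.0), 0.0)]
    )
    def test_degenerate_probabilities(self, probs, expected):
        from meadow.scorecard import aggregate_survey

        survey = gen_survey({"v": probs}, n_respondents_per_village=10, seed=6)
        assert aggregate_survey(survey).variable_scores["v"] == expected

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(SynthGenError):
            gen_survey({"v": (0.5, 0.5, 0.5)}, seed=6)

    def test_mean_recovery(self):
        from meadow.scorecard import aggregate_survey

        survey = gen_survey({"v": (0.2, 0.5, 0.3)}, n_respondents_per_village=60, seed=6)
        assert aggregate_survey(survey).variable_scores["v"] == pytest.approx(1.65, abs=0.3)


class TestDeterminism:
    def test_identical_seed_gives_byte_identical_files(self, tmp_path):
        cfg = GeneratorConfig(seed=42)
        files_a = generate_all(cfg, tmp_path / "a")
        files_b = generate_all(cfg, tmp_path / "b")
        for name in files_a:
            assert files_a[name].read_bytes() == files_b[name].read_bytes()

    def test_substreams_are_independent(self):
        """Weather draws do not shift when another generator runs first."""
        w1 = gen_weather("2018-01-01", "2018-03-31", 0.4, 0.3, seed=7)
        gen_checkdams(seed=7)
        w2 = gen_weather("2018-01-01", "2018-03-31", 0.4, 0.3, seed=7)
        pd.testing.assert_frame_equal(w1, w2)
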