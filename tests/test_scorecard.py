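"""Banded variable scoring, category indices and zone comparison."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meadow import scorecard
from meadow.scorecard import (
    EcosystemZoneScore,
    ScorecardError,
    VariableScore,
    aggregate_survey,
    category_index,
    ecosystem_index,
    evaluation_index,
    rank_zones,
    score_variable,
)
from meadow.synthgen import gen_survey


class TestScoreVariable:
    @pytest.mark.parametrize(
        "variable, value, level, score",
        [
            ("soil_ph", 4.96, "satisfactory", 3.0),
            ("water_holding_capacity_pct", 49.85, "average", 1.5),
            ("erosion_t_ha_yr", 0.5, "satisfactory", 3.0),
            ("grazing_cu", 881, "not_satisfactory", 0.0),
            ("tourists_per_day", 54, "satisfactory", 3.0),
            ("organic_carbon_pct", 4.83, "not_satisfactory", 0.0),
        ],
    )
    def test_published_band_placements(self, criteria, variable, value, level, score):
        vs = score_variable(value, criteria[variable])
        assert vs.level == level
        assert vs.score == score

    @pytest.mark.parametrize(
        "variable, value, level",
        [
            ("soil_ph", 4.7, "satisfactory"),  # boundary goes to the better band
            ("water_holding_capacity_pct", 50.0, "satisfactory"),
            ("water_holding_capacity_pct", 40.0, "average"),
            ("grazing_cu", 285, "satisfactory"),
            ("grazing_cu", 857, "average"),
            ("vegetation_cover_pct", 60.0, "satisfactory"),
            ("soil_ph", 6.0, "average"),  # above the target band: off-target
            ("water_holding_capacity_pct", 70.0, "average"),
        ],
    )
    def test_boundary_and_high_side_conventions(self, criteria, variable, value, level):
        assert criteria[variable].classify(value) == level

    def test_out_of_domain_named_in_error(self, criteria):
        with pytest.raises(ScorecardError, match="soil_ph"):
            score_variable(15.0, criteria["soil_ph"])

    def test_configurable_mid_score(self, criteria):
        vs = score_variable(49.85, criteria["water_holding_capacity_pct"], mid_score=2.0)
        assert vs.score == 2.0


def test_shipped_profile_band_totality(criteria):
    """Every shipped criterion covers its whole domain (checked on load)."""
    assert len(criteria) == 10
    for crit in criteria.values():
        crit._validate_totality()  # raises on any gap


class TestCategoryIndex:
    def test_mixed_scores(self):
        scores = [VariableScore("a", 0, "satisfactory", 3.0),
                  VariableScore("b", 0, "satisfactory", 3.0),
                  VariableScore("c", 0, "average", 1.5)]
        ci = category_index(scores, "E")
        assert ci.total == 7.5
        assert ci.index == pytest.approx(7.5 / 9)

    @pytest.mark.parametrize("score, expected", [(3.0, 1.0), (0.0, 0.0)])
    def test_extremes(self, score, expected):
        scores = [VariableScore(v, 0, "x", score) for v in "abcd"]
        assert category_index(scores, "M").index == expected

    def test_empty_errors(self):
        with pytest.raises(ScorecardError):
            category_index([], "M")


class TestEvaluationIndex:
    def test_published_consistency_value(self):
        """A raw category-score sum of 11.09 over a 16-point maximum is 69.31%."""
        assert evaluation_index([11.09], max_score=16) == pytest.approx(69.31, abs=0.01)

    def test_zero_and_clamped_maximum(self):
        assert evaluation_index([0.0]) == 0.0
        assert evaluation_index([20.0], max_score=16) == 100.0

    def test_accepts_category_objects(self):
        scores = [VariableScore("a", 0, "x", 3.0)]
        ci = category_index(scores, "M")
        assert evaluation_index([ci], max_score=3) == 100.0


class TestAggregateSurvey:
    @staticmethod
    def _responses(ratings):
        return pd.DataFrame(
            {
                "respondent": [f"R{i}" for i in range(len(ratings))],
                "village": "Barsu",
                "age_group": "20-40",
                "variable": "cost_effectiveness",
                "rating": ratings,
            }
        )

    def test_all_high(self):
        agg = aggregate_survey(self._responses(["H"] * 10))
        assert agg.variable_scores["cost_effectiveness"] == 3.0

    def test_half_low_half_high(self):
        agg = aggregate_survey(self._responses(["L", "H"] * 5))
        assert agg.variable_scores["cost_effectiveness"] == 1.5

    def test_multinomial_mean_recovery(self):
        """60+60 respondents drawn (0.1, 0.3, 0.6) average near 0.1·0+0.3·1.5+0.6·3."""
        survey = gen_survey({"v": (0.1, 0.3, 0.6)}, n_respondents_per_village=60, seed=2)
        agg = aggregate_survey(survey)
        assert agg.n_respondents == 120
        assert agg.variable_scores["v"] == pytest.approx(2.25, abs=0.25)

    def test_unknown_rating_rejected(self):
        with pytest.raises(ScorecardError):
            aggregate_survey(self._responses(["X"]))

    def test_missing_expected_variable_warns(self):
        with pytest.warns(UserWarning, match="economic_efficiency"):
            aggregate_survey(
                self._responses(["H"]),
                expected_variables=["cost_effectiveness", "economic_efficiency"],
            )

    def test_proportions_sum_to_one(self):
        survey = gen_survey({"v": (0.2, 0.5, 0.3)}, n_respondents_per_village=30, seed=4)
        agg = aggregate_survey(survey)
        sums = agg.rating_proportions.groupby(["village", "age_group"])["proportion"].sum()
        assert sums.to_numpy() == pytest.approx(1.0)


class TestEcosystemIndex:
    @staticmethod
    def _replicates(values_by_rep):
        rows = [
            {"replicate": rep, "variable": var, "value": val}
            for rep, values in values_by_rep.items()
            for var, val in values.items()
        ]
        return pd.DataFrame(rows)

    def test_all_satisfactory_is_hundred_percent(self, criteria):
        values = {"soil_ph": 5.0, "water_holding_capacity_pct": 55.0,
                  "erosion_t_ha_yr": 1.0, "tourists_per_day": 10.0}
        zs = ecosystem_index("R", self._replicates({1: values}), criteria)
        assert zs.percent_score == 100.0

    def test_partial_scores(self, criteria):
        """Scores (3, 1.5, 0) over 3 variables give 50%."""
        values = {"soil_ph": 5.0, "water_holding_capacity_pct": 45.0,
                  "organic_carbon_pct": 1.0}
        zs = ecosystem_index("Z", self._replicates({1: values}), criteria)
        assert zs.percent_score == pytest.approx(50.0)

    def test_missing_variable_in_replicate_errors(self, criteria):
        frame = self._replicates(
            {1: {"soil_ph": 5.0, "erosion_t_ha_yr": 1.0}, 2: {"soil_ph": 5.0}}
        )
        with pytest.raises(ScorecardError, match="erosion_t_ha_yr"):
            ecosystem_index("Z", frame, criteria)

    def test_zone_ordering_on_packaged_tables(self, criteria, soil_chemistry):
        """Reference > treated > degraded on the packaged zone means."""
        from meadow import datasets

        cover = datasets.load_vegetation_cover().set_index("zone")
        scores = {}
        for zone, grp in soil_chemistry.groupby("zone"):
            rows = [
                {"replicate": 1, "variable": r["variable"], "value": r["mean"]}
                for _, r in grp.iterrows()
                if r["variable"] in criteria
            ]
            rows.append({"replicate": 1, "variable": "vegetation_cover_pct",
                         "value": cover.loc[zone, "vegetation_cover_pct"]})
            scores[zone] = ecosystem_index(str(zone), pd.DataFrame(rows), criteria)
        assert scores["R"].percent_score > scores["GTZ"].percent_score
        assert scores["GTZ"].percent_score > scores["UTZ"].percent_score


class TestRankZones:
    def test_published_ordering(self):
        scores = [EcosystemZoneScore("treated", 72.0, 3.78),
                  EcosystemZoneScore("degraded", 55.61, 4.79),
                  EcosystemZoneScore("reference", 88.0, 3.17)]
        ranking = rank_zones(scores)
        assert [r["zone"] for r in ranking] == ["reference", "treated", "degraded"]
        assert not any(r["tied"] for r in ranking)

    def test_equal_scores_flagged_in_input_order(self):
        scores = [EcosystemZoneScore("a", 50.0, 0.0), EcosystemZoneScore("b", 50.0, 0.0)]
        ranking = rank_zones(scores)
        assert [r["zone"] for r in ranking] == ["a", "b"]
        assert all(r["tied"] for r in ranking)

    def test_two_zones(self):
        ranking = rank_zones([EcosystemZoneScore("x", 10.0, 0.0),
                              EcosystemZoneScore("y", 20.0, 0.0)])
        assert [r["zone"] for r in ranking] == ["y", "x"]


@settings(deadline=None, max_examples=60)
@given(
    value=st.floats(min_value=0, max_value=100),
    delta=st.floats(min_value=0, max_value=20),
)
def test_monotone_toward_satisfactory_band(value, delta, criteria):
    """Raising organic carbon toward its satisfactory band never lowers the score."""
    crit = criteria["organic_carbon_pct"]
    low = score_variable(value, crit).score
    high = score_variable(min(100.0, value + delta), crit).score
    assert high >= low
    assert 0.0 <= low <= 3.0
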