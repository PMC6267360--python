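"""Survey loading, reverse coding, reliability, scoring, discretization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import safetybn as sb
from safetybn.survey import (ACCIDENT_COLUMNS, ItemSpec, build_records,
                             cronbach_alpha, dichotomize_accidents,
                             discretize_personal, discretize_score,
                             factor_scores, load_survey, reverse_code)


@pytest.fixture(scope="module")
def generated(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("gen")
    cfg = sb.GeneratorConfig(seed=4)
    paths = sb.generate(cfg, outdir)
    return cfg, paths


class TestLoadSurvey:
    def test_generator_output_round_trips(self, generated):
        cfg, paths = generated
        data = load_survey(paths["survey"],
                           [s.item_id for s in cfg.item_specs])
        assert data.n_respondents == 155
        assert data.likert.shape == (155, 38)

    def test_out_of_range_likert_cites_cell(self, tmp_path, generated):
        cfg, paths = generated
        df = pd.read_csv(paths["survey"])
        df.loc[3, "sa2"] = 6
        bad = tmp_path / "bad.csv"
        df.to_csv(bad, index=False)
        with pytest.raises(ValueError, match=r"row 3.*'sa2'"):
            load_survey(bad, [s.item_id for s in cfg.item_specs])

    def test_missing_accident_column_is_schema_error(self, tmp_path,
                                                     generated):
        cfg, paths = generated
        df = pd.read_csv(paths["survey"]).drop(columns=["near_miss"])
        bad = tmp_path / "noacc.csv"
        df.to_csv(bad, index=False)
        with pytest.raises(ValueError, match="missing columns"):
            load_survey(bad)

    def test_negative_count_rejected(self, tmp_path, generated):
        cfg, paths = generated
        df = pd.read_csv(paths["survey"])
        df.loc[0, "no_absence"] = -1
        bad = tmp_path / "neg.csv"
        df.to_csv(bad, index=False)
        with pytest.raises(ValueError, match="negative accident count"):
            load_survey(bad, [s.item_id for s in cfg.item_specs])


class TestReverseCode:
    def _toy(self):
        return sb.SurveyDataset(
            likert=pd.DataFrame({"q1": [5, 2], "q2": [4, 3]}),
            experience_years=pd.Series([3.0, 12.0]),
            smoking=pd.Series(["Not smoking"] * 2),
            drinking=pd.Series(["Not drinking"] * 2),
            accidents=pd.DataFrame(np.zeros((2, 4), dtype=int),
                                   columns=list(ACCIDENT_COLUMNS)))

    def test_flagged_item_flips_others_unchanged(self):
        items = [ItemSpec("q1", reverse_coded=True), ItemSpec("q2")]
        coded = reverse_code(self._toy(), items)
        assert coded.likert["q1"].tolist() == [1, 4]  # 6 - x
        assert coded.likert["q2"].tolist() == [4, 3]

    def test_double_application_guarded(self):
        items = [ItemSpec("q1", reverse_coded=True)]
        coded = reverse_code(self._toy(), items)
        with pytest.raises(ValueError, match="already reverse-coded"):
            reverse_code(coded, items)


class TestCronbachAlpha:
    def test_perfectly_correlated_items_give_one(self):
        x = np.arange(10.0)
        assert cronbach_alpha(np.column_stack([x, x])) == pytest.approx(1.0)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10_000, 2))
        assert abs(cronbach_alpha(X)) < 0.1

    def test_single_item_rejected(self):
        with pytest.raises(ValueError, match="two items"):
            cronbach_alpha(np.ones((5, 1)))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            cronbach_alpha(np.ones((5, 3)))

    def test_matches_pingouin(self):
        """Independent cross-check against the reference implementation."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        F = rng.normal(size=(200, 1))
        X = 0.7 * F + 0.5 * rng.normal(size=(200, 4))
        ours = cronbach_alpha(X)
        theirs = pingouin.cronbach_alpha(data=pd.DataFrame(X))[0]
        assert ours == pytest.approx(theirs, abs=1e-10)


class TestScoringAndDiscretization:
    def test_factor_score_is_item_mean(self):
        from safetybn.efa import FactorModel
        lik = pd.DataFrame({f"q{i}": v for i, v in
                            enumerate([[4, 3], [5, 3], [4, 3], [5, 3]], 1)})
        data = sb.SurveyDataset(
            likert=lik, experience_years=pd.Series([1.0, 1.0]),
            smoking=pd.Series(["Not smoking"] * 2),
            drinking=pd.Series(["Not drinking"] * 2),
            accidents=pd.DataFrame(np.zeros((2, 4), dtype=int),
                                   columns=list(ACCIDENT_COLUMNS)),
            reverse_coded=True)
        fm = FactorModel(loadings=pd.DataFrame(), factor_names=["f"],
                         assignment={f"q{i}": "f" for i in range(1, 5)},
                         explained_variance_ratio=0.5)
        scores = factor_scores(data, fm)
        assert scores["f"].tolist() == [4.5, 3.0]

    def test_reverse_coded_attitude_example(self):
        """Responses (2,2,1,5) with the first three items negatively worded
        score (4+4+5+5)/4 = 4.5 after reverse coding."""
        raw = [2, 2, 1, 5]
        flags = [True, True, True, False]
        coded = [6 - x if f else x for x, f in zip(raw, flags)]
        assert np.mean(coded) == 4.5

    @pytest.mark.parametrize("score,state", [
        (4.2, "Good"), (3.5, "Good"), (3.0, "Average"), (2.5, "Average"),
        (2.4999, "Poor"), (1.0, "Poor"), (5.0, "Good"),
    ])
    def test_score_bands(self, score, state):
        assert discretize_score(score) == state

    @given(st.floats(min_value=1.0, max_value=5.0, allow_nan=False))
    def test_score_band_property(self, score):
        """Bands partition [1, 5]: Good iff >= 3.5, Poor iff < 2.5."""
        state = discretize_score(score)
        assert state == ("Good" if score >= 3.5
                         else "Average" if score >= 2.5 else "Poor")

    def test_score_out_of_range(self):
        with pytest.raises(ValueError):
            discretize_score(5.3)

    @pytest.mark.parametrize("years,state", [
        (12, "Long"), (10, "Medium"), (6, "Medium"), (5.5, "Medium"),
        (5, "Short"), (0, "Short"),
    ])
    def test_experience_bins(self, years, state):
        exp, _, _ = discretize_personal(years, "Not smoking", "Not drinking")
        assert exp == state

    def test_invalid_habit_category_rejected(self):
        with pytest.raises(ValueError, match="unknown state"):
            discretize_personal(3, "Vaping", "Not drinking")

    @pytest.mark.parametrize("counts,state", [
        ((1, 1, 0, 0), "High"), ((0, 1, 0, 0), "Low"), ((0, 0, 0, 0), "Low"),
        ((0, 0, 0, 2), "High"),
    ])
    def test_accident_dichotomy(self, counts, state):
        assert dichotomize_accidents(counts) == state


class TestBuildRecords:
    def test_full_cohort_every_node_assigned(self, generated):
        cfg, paths = generated
        data = load_survey(paths["survey"],
                           [s.item_id for s in cfg.item_specs])
        fm, coded = sb.run_reduction(data, cfg.item_specs)
        records = build_records(coded, fm)
        assert len(records) == 155
        for rec in records:
            assert set(rec) == set(sb.build_accident_network().nodes)

    def test_high_fraction_matches_sampled_states_exactly(self, generated):
        """Accident counts are emitted conditional on the sampled outcome
        state, so dichotomization recovers the High fraction exactly."""
        cfg, paths = generated
        states = sb.sample_states(cfg)
        data = load_survey(paths["survey"],
                           [s.item_id for s in cfg.item_specs])
        fm, coded = sb.run_reduction(data, cfg.item_specs)
        records = build_records(coded, fm)
        frac = np.mean([r["number_of_accidents"] == "High" for r in records])
        truth = np.mean([r["number_of_accidents"] == "High" for r in states])
        assert frac == pytest.approx(truth, abs=1e-12)  # counts round-trip

    def test_empty_dataset_rejected(self):
        empty = sb.SurveyDataset(
            likert=pd.DataFrame(columns=["q1"]),
            experience_years=pd.Series(dtype=float),
            smoking=pd.Series(dtype=object),
            drinking=pd.Series(dtype=object),
            accidents=pd.DataFrame(columns=list(ACCIDENT_COLUMNS)),
            reverse_coded=True)
        from safetybn.efa import FactorModel
        fm = FactorModel(loadings=pd.DataFrame(), factor_names=["f"],
                         assignment={"q1": "f"},
                         explained_variance_ratio=0.5)
        with pytest.raises(ValueError, match="empty"):
            build_records(empty, fm)
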