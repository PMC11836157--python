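"""Survey I/O, exclusion rule, subset filters, categorization, median split."""

import numpy as np
import pandas as pd
import pytest

from mvtforage import (
    SimulationConfig,
    SurveyFormatError,
    categorize,
    exclude_incomplete,
    median_split,
    read_survey,
    select_mvt_subset,
    simulate_foragers,
    write_survey,
)


@pytest.fixture
def survey(tmp_path):
    df = simulate_foragers(SimulationConfig(n=120, seed=13, p_missing_key=0.05))
    path = tmp_path / "survey.csv"
    write_survey(df, path)
    return df, path


class TestReadSurvey:
    def test_write_then_read_round_trip(self, survey):
        df, path = survey
        back = read_survey(path)
        assert len(back) == len(df)
        for col in ("travel_time_min", "patch_time_min", "gain_euro", "age"):
            np.testing.assert_allclose(back[col], df[col])
        assert (back["trip_type"] == df["trip_type"]).all()
        assert (back["main_patch"].astype(bool) == df["main_patch"]).all()

    def test_blank_gain_cell_becomes_missing(self, tmp_path, survey):
        df, path = survey
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
        raw.loc[0, "gain_euro"] = ""
        p2 = tmp_path / "edited.csv"
        raw.to_csv(p2, index=False)
        back = read_survey(p2)
        assert np.isnan(back.loc[0, "gain_euro"])

    def test_missing_mandatory_column_named_in_error(self, tmp_path, survey):
        _, path = survey
        raw = pd.read_csv(path).drop(columns=["patch_time_min"])
        p2 = tmp_path / "broken.csv"
        raw.to_csv(p2, index=False)
        with pytest.raises(SurveyFormatError, match="patch_time_min"):
            read_survey(p2)

    def test_malformed_numeric_cell_reports_row(self, tmp_path, survey):
        _, path = survey
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
        raw.loc[7, "gain_euro"] = "about twenty"
        p2 = tmp_path / "bad.csv"
        raw.to_csv(p2, index=False)
        with pytest.raises(SurveyFormatError, match="row 7"):
            read_survey(p2)

    def test_unknown_columns_preserved(self, tmp_path, survey):
        _, path = survey
        raw = pd.read_csv(path)
        raw["free_text_note"] = "hello"
        p2 = tmp_path / "extra.csv"
        raw.to_csv(p2, index=False)
        assert "free_text_note" in read_survey(p2).columns

    def test_distance_column_dropped(self, tmp_path, survey):
        _, path = survey
        raw = pd.read_csv(path)
        raw["distance_km_est"] = 1.5
        p2 = tmp_path / "dist.csv"
        raw.to_csv(p2, index=False)
        assert "distance_km_est" not in read_survey(p2).columns


class TestExcludeIncomplete:
    def test_four_of_194_missing_leaves_190(self):
        df = simulate_foragers(SimulationConfig(n=194, seed=2, p_missing_key=0.0))
        df.loc[df.index[:4], "gain_euro"] = np.nan
        kept, excluded = exclude_incomplete(df)
        assert len(kept) == 190
        assert len(excluded) == 4

    def test_no_missing_fields_excludes_nothing(self):
        df = simulate_foragers(SimulationConfig(n=30, seed=2, p_missing_key=0.0))
        kept, excluded = exclude_incomplete(df)
        assert len(kept) == 30 and len(excluded) == 0

    def test_matches_generator_bookkeeping(self):
        df = simulate_foragers(SimulationConfig(n=1000, seed=17, p_missing_key=0.1))
        kept, _ = exclude_incomplete(df)
        assert len(kept) == df.attrs["simulation"]["n_complete"]

    def test_partition(self):
        df = simulate_foragers(SimulationConfig(n=100, seed=5, p_missing_key=0.2))
        kept, excluded = exclude_incomplete(df)
        assert len(kept) + len(excluded) == len(df)
        assert set(kept.index).isdisjoint(excluded.index)


class TestSelectSubset:
    def test_matches_brute_force_conjunction(self):
        df = simulate_foragers(SimulationConfig(n=500, seed=29))
        subset, report = select_mvt_subset(df)
        kept, _ = exclude_incomplete(df)
        brute = sum(
            bool(r.main_patch)
            and r.trip_type == "home_roundtrip"
            and r.transport == "foot"
            for r in kept.itertuples()
        )
        assert report.n_subset == len(subset) == brute

    def test_all_false_flags_empty_subset(self):
        df = simulate_foragers(
            SimulationConfig(n=40, seed=3, p_main_patch=0.0, p_missing_key=0.0)
        )
        subset, report = select_mvt_subset(df)
        assert len(subset) == 0
        assert report.drop_not_main_patch == 40

    def test_idempotent(self):
        df = simulate_foragers(SimulationConfig(n=300, seed=7, p_missing_key=0.05))
        once, rep1 = select_mvt_subset(df)
        twice, rep2 = select_mvt_subset(once)
        pd.testing.assert_frame_equal(once, twice)
        assert rep2.n_subset == rep1.n_subset
        assert rep2.n_excluded_incomplete == 0

    def test_attrition_accounts_for_every_row(self):
        df = simulate_foragers(SimulationConfig(n=250, seed=11, p_missing_key=0.05))
        _, r = select_mvt_subset(df)
        assert (
            r.n_excluded_incomplete
            + r.drop_not_main_patch
            + r.drop_not_home_roundtrip
            + r.drop_not_foot
            + r.n_subset
            == r.n_input
        )


class TestCategorize:
    def test_household_and_age_bins(self):
        df = pd.DataFrame(
            {"household_n": [1, 2, 4, np.nan], "age": [22, 35, 67, np.nan]}
        )
        out = categorize(df)
        assert list(out["household_cat"][:3]) == ["1", "2", ">2"]
        assert list(out["age_cat"][:3]) == ["18-29", "30-49", "50+"]
        assert out["household_cat"].isna().iloc[3] and out["age_cat"].isna().iloc[3]

    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("3 or 4 times a week", "3-4/wk"),
            ("5 or 6 times a week", "5+/wk"),
            ("once a week", "1-2/wk"),
            ("twice a week", "1-2/wk"),
            ("daily", "5+/wk"),
            ("less than once a week", "<1/wk"),
            ("2-3 times a week", "1-2/wk"),
        ],
    )
    def test_frequency_parser(self, raw, expected):
        out = categorize(pd.DataFrame({"shop_freq_raw": [raw]}))
        assert out["shop_freq_cat"].iloc[0] == expected

    def test_unparseable_frequency_becomes_missing(self):
        out = categorize(pd.DataFrame({"shop_freq_raw": ["whenever I feel like it"]}))
        assert out["shop_freq_cat"].isna().iloc[0]

    def test_dummies_partition(self):
        df = simulate_foragers(SimulationConfig(n=150, seed=41, p_missing_key=0.0))
        out = categorize(df)
        for var in ("shop_freq_cat", "household_cat", "age_cat", "gender"):
            cols = [c for c in out.columns if c.startswith(f"{var}__")]
            sums = out[cols].sum(axis=1)
            nonmissing = out[var].notna()
            assert (sums[nonmissing] == 1.0).all()


class TestMedianSplit:
    def test_basic_split(self):
        assert list(median_split([1, 2, 3, 4])) == ["low", "low", "high", "high"]

    def test_ties_at_median_go_low(self):
        assert list(median_split([5, 5, 5])) == ["low", "low", "low"]

    def test_missing_stays_unlabeled(self):
        labels = median_split([1.0, np.nan, 3.0])
        assert labels[1] is None

    def test_group_sizes_differ_at_most_by_median_ties(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 20, size=201).astype(float)
        labels = median_split(x)
        med = np.median(x)
        n_ties = int((x == med).sum())
        low = (labels == "low").sum()
        high = (labels == "high").sum()
        assert abs(low - high) <= n_ties + 1

    def test_too_few_values_error(self):
        with pytest.raises(ValueError):
            median_split([np.nan, np.nan, 1.0])
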