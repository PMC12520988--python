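import numpy as np
import pandas as pd
import pytest
from scipy import stats

from proteoflow import preprocess
from proteoflow.io import IntensityMatrix


def make(values: dict, scale="log2", index=None):
    df = pd.DataFrame(values)
    if index is not None:
        df.index = index
    return IntensityMatrix(df, scale=scale)


class TestLog2AndClean:
    def test_log2_arithmetic(self):
        m = make({"s1": [8.0], "s2": [2.0]}, scale="raw")
        out = preprocess.log2_and_clean(m)
        assert out.scale == "log2"
        assert out.values.at[0, "s1"] == 3.0
        assert out.values.at[0, "s2"] == 1.0

    def test_contaminant_prefix_removed(self):
        m = make({"s1": [8.0, 4.0]}, scale="raw", index=["contam_KERATIN", "P1"])
        out = preprocess.log2_and_clean(m, contaminant_prefixes=("contam_",))
        assert list(out.protein_ids) == ["P1"]

    def test_already_log2_rejected(self, small_matrix):
        with pytest.raises(ValueError):
            preprocess.log2_and_clean(small_matrix)

    def test_non_positive_value_rejected(self):
        m = make({"s1": [0.0]}, scale="raw")
        with pytest.raises(ValueError, match="non-positive"):
            preprocess.log2_and_clean(m)

    def test_missingness_preserved(self):
        m = make({"s1": [8.0, np.nan]}, scale="raw")
        assert preprocess.log2_and_clean(m).n_missing == 1


GROUPS8 = pd.Series(["A"] * 4 + ["B"] * 4,
                    index=[f"s{i}" for i in range(8)])


class TestGroupValidityFilter:
    def matrix(self, row):
        return make({f"s{i}": [row[i]] for i in range(8)})

    def test_three_valid_in_one_group_retained(self):
        m = self.matrix([1.0, 1, 1, np.nan, np.nan, np.nan, np.nan, np.nan])
        out = preprocess.filter_by_group_validity(m, GROUPS8, min_valid=3)
        assert len(out.protein_ids) == 1

    def test_two_valid_in_each_group_removed(self):
        m = self.matrix([1.0, 1, np.nan, np.nan, 1, 1, np.nan, np.nan])
        out = preprocess.filter_by_group_validity(m, GROUPS8, min_valid=3)
        assert len(out.protein_ids) == 0

    def test_min_valid_zero_is_identity(self, complete_matrix):
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=complete_matrix.sample_ids)
        out = preprocess.filter_by_group_validity(complete_matrix, groups, 0)
        pd.testing.assert_frame_equal(out.values, complete_matrix.values)

    def test_min_valid_above_group_size_warns_and_empties(self, caplog):
        m = self.matrix([1.0] * 8)
        with caplog.at_level("WARNING"):
            out = preprocess.filter_by_group_validity(m, GROUPS8, min_valid=5)
        assert len(out.protein_ids) == 0
        assert any("min_valid" in r.message for r in caplog.records)

    def test_commutes_with_row_permutation(self, rng, complete_matrix):
        values = complete_matrix.values.mask(
            pd.DataFrame(rng.random(complete_matrix.values.shape) < 0.4,
                         index=complete_matrix.protein_ids,
                         columns=complete_matrix.sample_ids))
        m = IntensityMatrix(values, scale="log2")
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=m.sample_ids)
        perm = rng.permutation(len(m.protein_ids))
        mp = IntensityMatrix(values.iloc[perm], scale="log2")
        out = preprocess.filter_by_group_validity(m, groups, 2)
        outp = preprocess.filter_by_group_validity(mp, groups, 2)
        assert set(out.protein_ids) == set(outp.protein_ids)


class TestMedianNormalize:
    def test_two_sample_medians_meet_in_the_middle(self):
        m = make({"s1": [9.0, 10, 11], "s2": [11.0, 12, 13]})
        out = preprocess.median_normalize(m)
        assert out.values["s1"].median() == 11.0
        assert out.values["s2"].median() == 11.0

    def test_idempotent(self, complete_matrix):
        once = preprocess.median_normalize(complete_matrix)
        twice = preprocess.median_normalize(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_single_sample_unchanged(self):
        m = make({"s1": [9.0, 10, 11]})
        pd.testing.assert_frame_equal(preprocess.median_normalize(m).values, m.values)

    def test_within_sample_differences_bit_identical(self, complete_matrix):
        out = preprocess.median_normalize(complete_matrix)
        for s in complete_matrix.sample_ids:
            before = np.diff(complete_matrix.values[s].to_numpy())
            after = np.diff(out.values[s].to_numpy())
            assert (before == after).all()

    def test_empty_sample_rejected(self):
        m = make({"s1": [1.0], "s2": [np.nan]})
        with pytest.raises(ValueError, match="s2"):
            preprocess.median_normalize(m)


class TestImputeLeftCensored:
    def test_no_missing_is_noop(self, complete_matrix):
        out = preprocess.impute_left_censored(complete_matrix, mode="all", seed=0)
        pd.testing.assert_frame_equal(out.values, complete_matrix.values)

    def test_draw_distribution_matches_downshifted_normal(self, rng):
        """Imputed draws follow Normal(m - 1.8 sd, (0.3 sd)^2) of the sample."""
        n = 20_000
        obs = rng.normal(0, 1, size=n)
        obs = (obs - obs.mean()) / obs.std(ddof=1) * 2.0 + 20.0  # mean 20, sd 2
        values = pd.DataFrame({"s1": np.concatenate([obs, [np.nan] * n]),
                               "s2": np.concatenate([obs, obs])})
        m = IntensityMatrix(values, scale="log2")
        out = preprocess.impute_left_censored(m, mode="all", seed=5)
        draws = out.values["s1"].iloc[n:]
        assert draws.mean() == pytest.approx(20 - 1.8 * 2, abs=0.05)
        assert draws.std(ddof=1) == pytest.approx(0.3 * 2, abs=0.03)
        # lower-tail contract: no draw reaches the sample's observed mean
        assert (draws < 20.0).all()

    def test_only_missing_cells_change(self, rng):
        values = pd.DataFrame(rng.normal(20, 2, size=(50, 4)),
                              columns=list("abcd"))
        holes = rng.random(values.shape) < 0.2
        m = IntensityMatrix(values.mask(holes), scale="log2")
        out = preprocess.impute_left_censored(m, mode="all", seed=1)
        observed = ~m.values.isna()
        pd.testing.assert_frame_equal(out.values[observed], m.values[observed])
        assert out.n_missing == 0

    def test_selective_mode_respects_group_validity(self):
        groups = pd.Series(["A", "A", "A", "B", "B", "B"],
                           index=list("abcdef"))
        values = pd.DataFrame(
            [[20.0, 21, 20, np.nan, np.nan, np.nan],     # A passes, B empty -> imputed
             [np.nan, np.nan, 20, np.nan, 21, np.nan],   # neither passes -> untouched
             [20.0, 21, np.nan, 20, 21, 20],             # sporadic hole in passing A -> imputed
             [19.0, 20, 21, 20, 19, 21],                 # complete padding rows so every
             [21.0, 20, 19, 21, 20, 19]],                # sample has >=2 observations
            columns=list("abcdef"))
        m = IntensityMatrix(values, scale="log2")
        out = preprocess.impute_left_censored(m, groups, min_valid=3,
                                              mode="selective", seed=2)
        assert out.values.iloc[0].notna().all()
        assert out.values.iloc[1].isna().sum() == 4
        assert out.values.iloc[2].notna().all()

    def test_same_seed_identical(self, rng):
        values = pd.DataFrame(rng.normal(20, 2, size=(30, 3)), columns=list("xyz"))
        m = IntensityMatrix(values.mask(rng.random(values.shape) < 0.3), scale="log2")
        a = preprocess.impute_left_censored(m, mode="all", seed=9)
        b = preprocess.impute_left_censored(m, mode="all", seed=9)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_sample_with_one_observation_rejected(self):
        m = make({"s1": [1.0, 2.0], "s2": [np.nan, 2.0]})
        m.values.iloc[1, 1] = np.nan
        m = IntensityMatrix(m.values, scale="log2")
        with pytest.raises(ValueError, match="s2"):
            preprocess.impute_left_censored(m, mode="all", seed=0)


class TestSummarizeQuality:
    def test_cv_definitions(self):
        # linear values (1,2,3): sd=1, mean=2 -> CV 50%; identical -> 0%
        values = pd.DataFrame({"r1": np.log2([1.0, 4.0]),
                               "r2": np.log2([2.0, 4.0]),
                               "r3": np.log2([3.0, 4.0])})
        m = IntensityMatrix(values, scale="log2")
        groups = pd.Series(["g", "g", "g"], index=["r1", "r2", "r3"])
        qc = preprocess.summarize_quality(m, groups)
        assert qc.cv.at[0, "g"] == pytest.approx(50.0)
        assert qc.cv.at[1, "g"] == pytest.approx(0.0)

    def test_completeness_fraction(self):
        values = pd.DataFrame(np.ones((5, 2)))
        values.iloc[4, 0] = np.nan
        m = IntensityMatrix(values, scale="log2")
        groups = pd.Series(["g", "g"], index=values.columns)
        assert preprocess.summarize_quality(m, groups).completeness == 0.8

    def test_singleton_group_excluded_with_warning(self, caplog, complete_matrix):
        groups = pd.Series(["a"] * 5 + ["lonely"], index=complete_matrix.sample_ids)
        with caplog.at_level("WARNING"):
            qc = preprocess.summarize_quality(complete_matrix, groups)
        assert list(qc.cv.columns) == ["a"]
        assert any("lonely" in r.message for r in caplog.records)
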