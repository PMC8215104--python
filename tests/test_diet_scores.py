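import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from genediet.cohort import FOOD_GROUP_COLUMNS
from genediet.diet_scores import (
    DASH_COMPONENTS,
    MDS_COMPONENTS,
    StratumSizeError,
    UndefinedRatioError,
    assign_tertiles,
    mufa_sfa_ratio,
    score_dash,
    score_mds,
    sex_specific_quantile_ranks,
)

from conftest import brute_force_quantile_groups


def _intake_frame(rng, n, sex=None):
    df = pd.DataFrame({c: rng.lognormal(3.0, 0.8, size=n) for c in FOOD_GROUP_COLUMNS})
    df["sodium"] = rng.lognormal(8.0, 0.3, size=n)
    df["mufa"] = rng.lognormal(3.5, 0.3, size=n)
    df["sfa"] = rng.lognormal(3.3, 0.3, size=n)
    df["sex"] = sex if sex is not None else rng.choice(["male", "female"], size=n)
    return df


# --- quantile ranks ----------------------------------------------------------

def test_quintile_ranks_1_to_10():
    v = pd.Series(np.arange(1.0, 11.0))
    sex = pd.Series(["male"] * 10)
    ranks = sex_specific_quantile_ranks(v, sex, k=5)
    assert list(ranks) == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]


def test_quintile_ranks_all_ties_share_lowest_group():
    v = pd.Series([7.0] * 12)
    ranks = sex_specific_quantile_ranks(v, pd.Series(["f"] * 12), k=5)
    assert (ranks == 1).all()


def test_quintile_ranks_computed_per_sex():
    # disjoint ranges: the smallest male value outranks every female value
    v = pd.Series([100, 200, 300, 400, 500, 1, 2, 3, 4, 5], dtype=float)
    sex = pd.Series(["male"] * 5 + ["female"] * 5)
    ranks = sex_specific_quantile_ranks(v, sex, k=5)
    assert list(ranks[:5]) == list(ranks[5:])  # identical within-stratum patterns


def test_quintile_ranks_small_stratum_raises():
    with pytest.raises(StratumSizeError, match="male"):
        sex_specific_quantile_ranks(pd.Series([1.0, 2.0]), pd.Series(["male", "male"]), k=5)


def test_quintile_ranks_match_brute_force_oracle(rng):
    for _ in range(20):
        n = int(rng.integers(20, 500))
        df = _intake_frame(rng, n)
        for sex in ("male", "female"):
            sub = df[df["sex"] == sex]
            if len(sub) < 5:
                continue
            got = sex_specific_quantile_ranks(df["fruits"], df["sex"], k=5)[sub.index]
            expected = brute_force_quantile_groups(sub["fruits"].to_numpy(), 5)
            np.testing.assert_array_equal(got.to_numpy(), expected)


# --- DASH -------------------------------------------------------------------

def test_dash_forced_extremes(rng):
    n = 20
    df = _intake_frame(rng, n, sex=["male"] * n)
    # subject 0: top of every emphasized intake, bottom of every discouraged one
    for name, (cols, emphasized) in DASH_COMPONENTS.items():
        for col in cols:
            df.loc[0, col] = df[col].max() * 10 if emphasized else 0.0
            df.loc[1, col] = 0.0 if emphasized else df[col].max() * 10
    out = score_dash(df)
    assert out.loc[0, "dash_total"] == 40
    assert out.loc[1, "dash_total"] == 8


def test_dash_matches_brute_force_oracle(rng):
    df = _intake_frame(rng, 10, sex=["female"] * 10)
    out = score_dash(df)
    # independent construction: sort-bucket each summed component, reverse the
    # discouraged ones, sum
    totals = np.zeros(10)
    for name, (cols, emphasized) in DASH_COMPONENTS.items():
        amount = df[list(cols)].sum(axis=1).to_numpy()
        ranks = brute_force_quantile_groups(amount, 5)
        totals += ranks if emphasized else 6 - ranks
    np.testing.assert_array_equal(out["dash_total"].to_numpy(), totals)


def test_dash_monotone_in_fruit_intake(rng):
    df = _intake_frame(rng, 50)
    base = score_dash(df)["dash_total"]
    bumped = df.copy()
    bumped.loc[bumped.index[3], "fruits"] *= 5
    after = score_dash(bumped)["dash_total"]
    assert after.iloc[3] >= base.iloc[3]
    # untouched subjects can only move down or stay (subject 3 passed them)
    others = df.index[df.index != df.index[3]]
    assert (after[others] <= base[others]).all()


def test_dash_bounds_random_cohorts(rng):
    for _ in range(10):
        df = _intake_frame(rng, int(rng.integers(12, 300)))
        totals = score_dash(df)["dash_total"].dropna()
        assert totals.between(8, 40).all()


def test_dash_missing_component_flags_unscored(rng):
    df = _intake_frame(rng, 30)
    df.loc[df.index[0], "fruits"] = np.nan
    out = score_dash(df)
    assert np.isnan(out.loc[df.index[0], "dash_total"])
    assert out["dash_total"].notna().sum() == 29


# --- MDS --------------------------------------------------------------------

def test_mds_forced_extremes(rng):
    n = 21
    df = _intake_frame(rng, n, sex=["male"] * n)
    protective_cols = [c for name, (cols, prot) in MDS_COMPONENTS.items() for c in cols if prot]
    nonprot_cols = [c for name, (cols, prot) in MDS_COMPONENTS.items() for c in cols if not prot]
    for col in protective_cols:
        df.loc[0, col] = df[col].max() * 10
        df.loc[1, col] = 0.0
    for col in nonprot_cols:
        df.loc[0, col] = 0.0
        df.loc[1, col] = df[col].max() * 10
    df.loc[0, "mufa"], df.loc[0, "sfa"] = 100.0, 1.0
    df.loc[1, "mufa"], df.loc[1, "sfa"] = 0.01, 100.0
    out = score_mds(df)
    assert out.loc[0, "mds_total"] == 8
    assert out.loc[1, "mds_total"] == 0


def test_mds_at_median_counts_as_one():
    df = _intake_frame(np.random.default_rng(5), 9, sex=["male"] * 9)
    median = df["vegetables"].median()
    df.loc[0, "vegetables"] = median
    out = score_mds(df)
    # an odd-sized sample's median is an observed value; at-median scores 1
    assert out.loc[0, "vegetables"] in (0.0, 1.0)
    df2 = df.copy()
    df2["vegetables"] = np.arange(1.0, 10.0)
    out2 = score_mds(df2)
    assert out2.loc[4, "vegetables"] == 1.0  # value 5 is exactly the median


def test_mds_protective_indicator_covers_at_least_half(rng):
    df = _intake_frame(rng, 101, sex=["female"] * 101)
    out = score_mds(df)
    for name, (cols, prot) in MDS_COMPONENTS.items():
        if prot:
            assert out[name].mean() >= 0.5


def test_mds_zero_sfa_flags_component_unscored(rng):
    df = _intake_frame(rng, 20)
    df.loc[df.index[0], "sfa"] = 0.0
    out = score_mds(df)
    assert np.isnan(out.loc[df.index[0], "mufa_sfa"])
    assert np.isnan(out.loc[df.index[0], "mds_total"])


def test_mds_bounds_random_cohorts(rng):
    for _ in range(10):
        df = _intake_frame(rng, int(rng.integers(10, 300)))
        totals = score_mds(df)["mds_total"].dropna()
        assert totals.between(0, 8).all()


# --- MUFA:SFA ratio ----------------------------------------------------------

def test_mufa_sfa_ratio_values():
    assert mufa_sfa_ratio(24.0, 24.0) == pytest.approx(1.0)
    assert mufa_sfa_ratio(30.0, 24.0) == pytest.approx(1.25)
    with pytest.raises(UndefinedRatioError):
        mufa_sfa_ratio(30.0, 0.0)


# --- tertiles ----------------------------------------------------------------

def test_tertiles_nine_distinct_split_evenly():
    scores = pd.Series([3.0, 1, 9, 2, 7, 5, 8, 4, 6])
    t = assign_tertiles(scores).tertile
    assert t.value_counts().tolist() == [3, 3, 3]


def test_tertiles_all_equal_tie_policy():
    t = assign_tertiles(pd.Series([4.0] * 8)).tertile
    assert (t == 1).all()


def test_tertiles_one_to_six_mapping():
    t = assign_tertiles(pd.Series([1.0, 2, 3, 4, 5, 6])).tertile
    assert list(t) == [1, 1, 2, 2, 3, 3]


def test_tertiles_match_brute_force_oracle(rng):
    for _ in range(20):
        scores = pd.Series(rng.normal(size=int(rng.integers(5, 500))))
        got = assign_tertiles(scores).tertile.to_numpy()
        expected = brute_force_quantile_groups(scores.to_numpy(), 3)
        np.testing.assert_array_equal(got, expected)


def test_tertiles_small_stratum_raises():
    with pytest.raises(StratumSizeError):
        assign_tertiles(pd.Series([1.0, 2.0]))


# --- permutation equivariance -------------------------------------------------

def test_scoring_invariant_to_subject_order(rng):
    df = _intake_frame(rng, 60)
    perm = rng.permutation(60)
    shuffled = df.iloc[perm].reset_index(drop=True)
    dash_a = score_dash(df)["dash_total"].to_numpy()[perm]
    dash_b = score_dash(shuffled)["dash_total"].to_numpy()
    np.testing.assert_array_equal(dash_a, dash_b)
    mds_a = score_mds(df)["mds_total"].to_numpy()[perm]
    mds_b = score_mds(shuffled)["mds_total"].to_numpy()
    np.testing.assert_array_equal(mds_a, mds_b)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_dash_and_mds_bounds_property(seed):
    rng = np.random.default_rng(seed)
    df = _intake_frame(rng, 25)
    dash = score_dash(df)["dash_total"].dropna()
    mds = score_mds(df)["mds_total"].dropna()
    assert dash.between(8, 40).all()
    assert mds.between(0, 8).all()
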