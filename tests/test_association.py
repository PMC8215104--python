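import numpy as np
import pandas as pd
import pytest

from genediet.association import (
    MODEL_SPECS,
    ancova_interaction,
    fit_diet_genotype_multinomial,
    fit_genotype_outcome_or,
    posthoc_cell_comparisons,
    tables_by_tertile,
)


def _interaction_frame(rng, n=350, cell_shift=None, covariate_effect=0.0):
    """Genotype + tertile + Gaussian response, optionally with one shifted cell."""
    geno = rng.choice(["CC", "CT", "TT"], size=n, p=(0.378, 0.519, 0.103))
    tert = rng.integers(1, 4, size=n)
    age = rng.uniform(20, 50, size=n)
    y = rng.standard_normal(n) + covariate_effect * (age - 35.0)
    if cell_shift is not None:
        (g, t), delta = cell_shift
        y = y + delta * ((geno == g) & (tert == t))
    return pd.DataFrame({"genotype": geno, "tertile": tert, "age": age, "y": y})


# --- comparison tables -------------------------------------------------------

def test_chi_square_matches_hand_computation():
    # 2x2 table (20,80 / 10,90): chi-square without continuity correction
    var = ["yes"] * 20 + ["no"] * 80 + ["yes"] * 10 + ["no"] * 90
    tert = [1] * 100 + [2] * 100
    df = pd.DataFrame({"flag": var})
    out = tables_by_tertile(df, pd.Series(tert), categorical=("flag",))
    stat = out.loc[out["variable"] == "flag", "statistic"].iloc[0]
    # hand: n(ad-bc)^2 / (row and column margins) = 200*1000^2 / (100*100*30*170)
    assert stat == pytest.approx(200 * 1000**2 / (100 * 100 * 30 * 170), rel=1e-12)


def test_chi_square_identical_distributions():
    df = pd.DataFrame({"flag": ["a", "b"] * 30})
    tert = pd.Series(([1] * 2 + [2] * 2 + [3] * 2) * 10)
    out = tables_by_tertile(df, tert, categorical=("flag",))
    assert out["statistic"].iloc[0] == pytest.approx(0.0, abs=1e-12)
    assert out["p_value"].iloc[0] == pytest.approx(1.0)


def test_anova_type_one_error_calibrated(rng):
    """Three tertile groups drawn from one distribution: ANOVA rejects at
    roughly the nominal 5% rate."""
    rejections = 0
    reps = 400
    for _ in range(reps):
        df = pd.DataFrame({"x": rng.standard_normal(300)})
        tert = pd.Series(rng.integers(1, 4, size=300))
        out = tables_by_tertile(df, tert, continuous=("x",))
        rejections += out["p_value"].iloc[0] < 0.05
    assert 0.02 <= rejections / reps <= 0.08


# --- logistic odds ratios -----------------------------------------------------

def test_crude_or_equals_cross_product_ratio():
    # TT/CC 2x2 table a=20, b=80, c=10, d=90 -> OR 2.25
    geno = ["TT"] * 100 + ["CC"] * 100
    y = [1] * 20 + [0] * 80 + [1] * 10 + [0] * 90
    df = pd.DataFrame({"genotype": geno, "flag": y})
    res = [r for r in fit_genotype_outcome_or(df, "flag", "crude") if r.contrast == "TT vs CC"]
    assert res[0].odds_ratio == pytest.approx(2.25, rel=1e-6)
    assert res[0].ci_low <= res[0].odds_ratio <= res[0].ci_high


def test_null_or_near_one(rng):
    n = 10000
    df = pd.DataFrame({
        "genotype": rng.choice(["CC", "CT", "TT"], size=n, p=(0.378, 0.519, 0.103)),
        "flag": rng.random(n) < 0.3,
    })
    for r in fit_genotype_outcome_or(df, "flag", "crude"):
        assert 0.9 < r.odds_ratio < 1.1


def test_adjusted_or_uses_covariates(rng):
    n = 2000
    geno = rng.choice(["CC", "CT", "TT"], size=n)
    age = rng.uniform(20, 50, size=n)
    p = 1 / (1 + np.exp(-(-2.0 + 0.05 * (age - 35.0))))
    df = pd.DataFrame({
        "genotype": geno, "age": age,
        "physical_activity": rng.choice(["low", "moderate", "high"], size=n),
        "ses": rng.choice(["low", "middle", "high"], size=n),
        "flag": rng.random(n) < p,
    })
    res = fit_genotype_outcome_or(df, "flag", "model1")
    assert all(np.isfinite(r.odds_ratio) for r in res)
    assert all(r.model == "model1" for r in res)


def test_multinomial_matches_stratified_cross_products():
    """With a binary predictor, the multinomial slopes equal the two
    stratified 2x2 cross-product ratios."""
    rows = []
    # counts: score=1 -> CC 40, CT 30, TT 10; score=0 -> CC 50, CT 25, TT 20
    for score, counts in ((1, {"CC": 40, "CT": 30, "TT": 10}),
                          (0, {"CC": 50, "CT": 25, "TT": 20})):
        for g, k in counts.items():
            rows += [{"score": score, "genotype": g}] * k
    df = pd.DataFrame(rows)
    res = {r.contrast.split(" ")[0]: r for r in fit_diet_genotype_multinomial(df, "score", "crude")}
    or_ct = (30 * 50) / (25 * 40)  # CT-vs-CC cross-product
    or_tt = (10 * 50) / (20 * 40)  # TT-vs-CC cross-product
    assert res["CT"].odds_ratio == pytest.approx(or_ct, rel=1e-4)
    assert res["TT"].odds_ratio == pytest.approx(or_tt, rel=1e-4)


def test_multinomial_null_score(rng):
    n = 4000
    df = pd.DataFrame({
        "genotype": rng.choice(["CC", "CT", "TT"], size=n, p=(0.378, 0.519, 0.103)),
        "score": rng.normal(24, 4, size=n),
    })
    for r in fit_diet_genotype_multinomial(df, "score", "crude"):
        assert 0.97 < r.odds_ratio < 1.03


def test_multinomial_recovers_planted_slope(rng):
    n = 5000
    score = rng.normal(0, 2, size=n)
    # genotype log-odds: CT baseline log(0.519/0.378); TT slope 0.2 per unit
    eta_ct = np.log(0.519 / 0.378) + 0.0 * score
    eta_tt = np.log(0.103 / 0.378) + 0.2 * score
    denom = 1 + np.exp(eta_ct) + np.exp(eta_tt)
    u = rng.random(n)
    p_cc = 1 / denom
    p_ct = np.exp(eta_ct) / denom
    geno = np.where(u < p_cc, "CC", np.where(u < p_cc + p_ct, "CT", "TT"))
    df = pd.DataFrame({"genotype": geno, "score": score})
    res = {r.contrast.split(" ")[0]: r for r in fit_diet_genotype_multinomial(df, "score", "crude")}
    assert res["TT"].odds_ratio == pytest.approx(np.exp(0.2), rel=0.10)


# --- ANCOVA interaction --------------------------------------------------------

def _twoway_anova_f_oracle(df):
    """Interaction partial F by direct linear algebra (cell-mean vs additive
    least squares), independent of the model-fitting path under test."""
    cells = df.groupby(["genotype", "tertile"])["y"]
    sse_full = ((df["y"] - cells.transform("mean")) ** 2).sum()
    X = pd.get_dummies(df[["genotype", "tertile"]].astype(str), drop_first=True).astype(float)
    X.insert(0, "const", 1.0)
    beta, *_ = np.linalg.lstsq(X.to_numpy(), df["y"].to_numpy(), rcond=None)
    sse_add = ((df["y"].to_numpy() - X.to_numpy() @ beta) ** 2).sum()
    n_cells = cells.ngroups
    df_num = n_cells - X.shape[1]
    df_den = len(df) - n_cells
    f = ((sse_add - sse_full) / df_num) / (sse_full / df_den)
    return f, df_num, df_den


def test_ancova_without_covariates_equals_twoway_anova(rng):
    df = _interaction_frame(rng, n=300)
    res = ancova_interaction(df, "y", covariates=())
    f_oracle, df_num, df_den = _twoway_anova_f_oracle(df)
    assert res.f_statistic == pytest.approx(f_oracle, rel=1e-9)
    assert res.df_num == df_num and res.df_den == df_den


def test_adjusted_means_equal_raw_cell_means_without_covariates(rng):
    df = _interaction_frame(rng, n=270)
    res = ancova_interaction(df, "y", covariates=())
    raw = df.groupby(["genotype", "tertile"])["y"].mean()
    for _, row in res.cell_means.iterrows():
        assert row["mean"] == pytest.approx(raw[(row["genotype"], row["tertile"])], rel=1e-9)


def test_adjusted_means_invariant_to_covariate_recoding(rng):
    df = _interaction_frame(rng, n=400, covariate_effect=0.05)
    res_a = ancova_interaction(df, "y", covariates=("age",))
    df2 = df.copy()
    df2["age"] = 3.7 * df2["age"] - 100.0  # affine recoding
    res_b = ancova_interaction(df2, "y", covariates=("age",))
    np.testing.assert_allclose(res_a.cell_means["mean"], res_b.cell_means["mean"], rtol=1e-8)
    assert res_a.p_interaction == pytest.approx(res_b.p_interaction, rel=1e-8)


def test_interaction_detects_planted_cell_shift(rng):
    df = _interaction_frame(rng, n=2000, cell_shift=(("CT", 2), 0.8))
    res = ancova_interaction(df, "y", covariates=("age",))
    assert res.p_interaction < 0.01
    ph = posthoc_cell_comparisons(res)
    hit = ph[(ph["genotype"] == "CT") & (ph["contrast"] == "T1 - T2")]
    assert hit["p_value"].iloc[0] < 0.01
    assert hit["difference"].iloc[0] < 0  # T2 mean is higher


def test_posthoc_contrast_algebra(rng):
    df = _interaction_frame(rng, n=200)
    res = ancova_interaction(df, "y", covariates=())
    ph = posthoc_cell_comparisons(res)
    means = res.cell_means.set_index(["genotype", "tertile"])["mean"]
    for _, row in ph.iterrows():
        t1, t2 = (int(s[1]) for s in row["contrast"].split(" - "))
        expected = means[(row["genotype"], t1)] - means[(row["genotype"], t2)]
        assert row["difference"] == pytest.approx(expected, rel=1e-9)
    # t equals difference / SE
    np.testing.assert_allclose(ph["t"], ph["difference"] / ph["se"], rtol=1e-12)


def test_posthoc_bonferroni_never_smaller(rng):
    df = _interaction_frame(rng, n=200)
    res = ancova_interaction(df, "y", covariates=())
    lsd = posthoc_cell_comparisons(res, method="lsd")
    bon = posthoc_cell_comparisons(res, method="bonferroni")
    assert (bon["p_value"].to_numpy() >= lsd["p_value"].to_numpy() - 1e-12).all()


def test_cis_contain_point_estimates(rng):
    df = _interaction_frame(rng, n=600)
    df["flag"] = rng.random(len(df)) < 0.3
    for spec in ("crude",):
        for r in fit_genotype_outcome_or(df, "flag", spec):
            assert r.ci_low <= r.odds_ratio <= r.ci_high
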