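"""Sex-stratified inferential layer: tertile comparison tables, genotype-
outcome and diet-genotype odds-ratio models under nested adjustment sets,
and the gene x diet ANCOVA interaction with adjusted (least-squares) cell
means and post-hoc contrasts.

Adjustment sets follow the study design:

* ``crude``  — no covariates
* ``model1`` — age, physical activity, socio-economic status
* ``model2`` — model1 plus waist circumference

The interaction test is the partial F-test on the genotype x tertile
block (4 df when all nine cells are occupied) in the linear model
``response ~ genotype + tertile + genotype:tertile + covariates``, run
separately per sex.  Adjusted cell means are computed by standardising
over the observed covariate distribution (each subject's covariate row
is combined with the target cell's factor levels and predictions are
averaged), which reduces exactly to the raw cell means when there are no
covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .genotyping import GENOTYPES


@dataclass(frozen=True)
class ModelSpec:
    """A named adjustment set."""

    name: str
    covariates: tuple[str, ...]


MODEL_SPECS = {
    "crude": ModelSpec("crude", ()),
    "model1": ModelSpec("model1", ("age", "physical_activity", "ses")),
    "model2": ModelSpec("model2", ("age", "physical_activity", "ses", "waist_circumference")),
}

#: default ANCOVA covariate set (age, physical activity, SES, WC)
ANCOVA_COVARIATES = ("age", "physical_activity", "ses", "waist_circumference")


def _covariate_terms(data: pd.DataFrame, covariates) -> list[str]:
    terms = []
    for cov in covariates:
        if pd.api.types.is_numeric_dtype(data[cov]):
            terms.append(cov)
        else:
            terms.append(f"C({cov})")
    return terms


# --- descriptive comparison tables ------------------------------------------

def tables_by_tertile(
    cohort: pd.DataFrame,
    tertile: pd.Series,
    continuous: tuple[str, ...] = (),
    categorical: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Compare variables across tertile groups within one stratum.

    Continuous variables get a one-way ANOVA p-value across the tertile
    groups; categorical variables a chi-square p-value on the tertile x
    category contingency table (flagged when expected counts are sparse).
    """
    rows = []
    groups = sorted(tertile.dropna().unique())
    if len(groups) < 2:
        raise ValueError("need at least two non-empty tertile groups")
    for var in continuous:
        samples = [cohort.loc[tertile == g, var].dropna().to_numpy(float) for g in groups]
        per_group = {f"T{int(g)}_mean": float(np.mean(s)) if s.size else np.nan for g, s in zip(groups, samples)}
        if all(s.size >= 2 for s in samples):
            f, p = stats.f_oneway(*samples)
        else:
            f, p = np.nan, np.nan
        rows.append({"variable": var, "kind": "anova", "statistic": float(f), "p_value": float(p),
                     "flag": None, **per_group})
    for var in categorical:
        table = pd.crosstab(cohort[var], tertile)
        if table.to_numpy().sum() == 0 or table.shape[0] < 2:
            rows.append({"variable": var, "kind": "chi2", "statistic": np.nan, "p_value": np.nan,
                         "flag": "degenerate"})
            continue
        chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
        flag = "sparse_expected_counts" if (expected < 5).any() else None
        rows.append({"variable": var, "kind": "chi2", "statistic": float(chi2), "p_value": float(p),
                     "flag": flag})
    return pd.DataFrame(rows)


# --- odds-ratio models -------------------------------------------------------

@dataclass(frozen=True)
class ORResult:
    contrast: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    model: str
    flag: str | None = None


def _fit_logit(formula: str, data: pd.DataFrame):
    model = smf.logit(formula, data=data)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=0, maxiter=200)
    return res


def fit_genotype_outcome_or(
    cohort: pd.DataFrame,
    outcome: str,
    spec: ModelSpec | str = "crude",
    genotype_col: str = "genotype",
) -> list[ORResult]:
    """Binary logistic regression of a risk flag on genotype (CC reference).

    Returns exponentiated Wald estimates and 95% CIs for CT-vs-CC and
    TT-vs-CC under the requested adjustment set.  Quasi-separated fits
    are returned flagged rather than silently.
    """
    if isinstance(spec, str):
        spec = MODEL_SPECS[spec]
    data = cohort.dropna(subset=[outcome, genotype_col, *spec.covariates]).copy()
    data["_y"] = data[outcome].astype(float)
    terms = [f"C({genotype_col}, Treatment('CC'))"] + _covariate_terms(data, spec.covariates)
    res = _fit_logit("_y ~ " + " + ".join(terms), data)
    flag = None
    if not res.mle_retvals.get("converged", True) or np.any(res.bse > 50):
        flag = "quasi_separation"
    out = []
    ci = res.conf_int()
    for level in ("CT", "TT"):
        name = f"C({genotype_col}, Treatment('CC'))[T.{level}]"
        if name not in res.params.index:
            out.append(ORResult(f"{level} vs CC", np.nan, np.nan, np.nan, np.nan, spec.name, "level_absent"))
            continue
        out.append(ORResult(
            contrast=f"{level} vs CC",
            odds_ratio=float(np.exp(res.params[name])),
            ci_low=float(np.exp(ci.loc[name, 0])),
            ci_high=float(np.exp(ci.loc[name, 1])),
            p_value=float(res.pvalues[name]),
            model=spec.name,
            flag=flag,
        ))
    return out


def fit_diet_genotype_multinomial(
    cohort: pd.DataFrame,
    score: str,
    spec: ModelSpec | str = "crude",
    genotype_col: str = "genotype",
) -> list[ORResult]:
    """Multinomial logit of genotype (CC reference) on a diet-score total.

    Returns the per-unit-score OR and 95% CI for the CT and TT equations
    under the requested adjustment set.
    """
    if isinstance(spec, str):
        spec = MODEL_SPECS[spec]
    data = cohort.dropna(subset=[score, genotype_col, *spec.covariates]).copy()
    present = [g for g in GENOTYPES if (data[genotype_col] == g).any()]
    flag = None
    if len(present) < 3:
        flag = "level_dropped"
        warnings.warn(f"genotype level(s) empty in stratum: {sorted(set(GENOTYPES) - set(present))}")
    codes = pd.Categorical(data[genotype_col], categories=present, ordered=False).codes
    terms = [score] + _covariate_terms(data, spec.covariates)
    exog = patsy.dmatrix("~ " + " + ".join(terms), data, return_type="dataframe")
    model = sm.MNLogit(codes, exog)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=0, maxiter=500, method="bfgs", gtol=1e-7)
    out = []
    z = stats.norm.ppf(0.975)
    for j, level in enumerate(present[1:]):
        coef = res.params.loc[score].iloc[j]
        se = res.bse.loc[score].iloc[j]
        out.append(ORResult(
            contrast=f"{level} vs {present[0]} (per score unit)",
            odds_ratio=float(np.exp(coef)),
            ci_low=float(np.exp(coef - z * se)),
            ci_high=float(np.exp(coef + z * se)),
            p_value=float(2 * stats.norm.sf(abs(coef / se))),
            model=spec.name,
            flag=flag,
        ))
    return out


# --- ANCOVA interaction ------------------------------------------------------

@dataclass
class InteractionResult:
    """Gene x diet-tertile ANCOVA output for one stratum and response."""

    stratum: str
    response: str
    f_statistic: float
    p_interaction: float
    df_num: float
    df_den: float
    cell_means: pd.DataFrame  # columns: genotype, tertile, mean, se, n
    flag: str | None = None
    _fit: object = field(default=None, repr=False)
    _cell_rows: dict = field(default_factory=dict, repr=False)


def ancova_interaction(
    cohort: pd.DataFrame,
    response: str,
    covariates: tuple[str, ...] = ANCOVA_COVARIATES,
    genotype_col: str = "genotype",
    tertile_col: str = "tertile",
    stratum: str = "all",
) -> InteractionResult:
    """Test the genotype x tertile interaction on a continuous response.

    Fits ``response ~ C(genotype) + C(tertile) + C(genotype):C(tertile)
    + covariates`` by OLS and reads the interaction from the partial
    F-test against the main-effects model.  Adjusted cell means (+- SE)
    standardise predictions over the observed covariate rows.
    """
    cols = [response, genotype_col, tertile_col, *covariates]
    data = cohort.dropna(subset=cols).copy()
    data["_tert"] = data[tertile_col].astype(int).astype(str)
    cov_terms = _covariate_terms(data, covariates)
    base = f"{response} ~ C({genotype_col}) + C(_tert)"
    full_formula = base + f" + C({genotype_col}):C(_tert)"
    if cov_terms:
        base += " + " + " + ".join(cov_terms)
        full_formula += " + " + " + ".join(cov_terms)
    full = smf.ols(full_formula, data=data).fit()
    restricted = smf.ols(base, data=data).fit()

    flag = None
    counts = data.groupby([genotype_col, "_tert"], observed=True).size()
    if (counts == 0).any() or len(counts) < 9:
        flag = "empty_cells"
    try:
        f_stat, p_val, df_num = full.compare_f_test(restricted)
    except Exception:  # rank-deficient comparison
        return InteractionResult(stratum, response, np.nan, np.nan, np.nan, np.nan,
                                 pd.DataFrame(), flag="inestimable", _fit=full)

    design_info = full.model.data.design_info
    params = full.params.to_numpy()
    cov_params = full.cov_params().to_numpy()
    cells = []
    cell_rows = {}
    genos = sorted(data[genotype_col].unique())
    terts = sorted(data["_tert"].unique())
    for g in genos:
        for t in terts:
            ref = data.copy()
            ref[genotype_col] = g
            ref["_tert"] = t
            (dm,) = patsy.build_design_matrices([design_info], ref)
            xbar = np.asarray(dm).mean(axis=0)
            mean = float(xbar @ params)
            se = float(np.sqrt(xbar @ cov_params @ xbar))
            n_cell = int(counts.get((g, t), 0))
            cells.append({"genotype": g, "tertile": int(t), "mean": mean, "se": se, "n": n_cell})
            cell_rows[(g, int(t))] = xbar
    return InteractionResult(
        stratum=stratum, response=response,
        f_statistic=float(f_stat), p_interaction=float(p_val),
        df_num=float(df_num), df_den=float(full.df_resid),
        cell_means=pd.DataFrame(cells), flag=flag,
        _fit=full, _cell_rows=cell_rows,
    )


def posthoc_cell_comparisons(
    result: InteractionResult, method: str = "lsd"
) -> pd.DataFrame:
    """Pairwise comparisons of adjusted means within each genotype across tertiles.

    Each contrast is the difference of two adjusted cell means divided by
    its standard error, referred to a t distribution on the residual df.
    ``method`` is ``"lsd"`` (unadjusted, default) or ``"bonferroni"``.
    """
    if result._fit is None or not result._cell_rows:
        raise ValueError("interaction result carries no fitted model")
    fit = result._fit
    params = fit.params.to_numpy()
    cov = fit.cov_params().to_numpy()
    df = fit.df_resid
    genos = sorted({g for g, _ in result._cell_rows})
    terts = sorted({t for _, t in result._cell_rows})
    rows = []
    for g in genos:
        pairs = [(a, b) for i, a in enumerate(terts) for b in terts[i + 1:]]
        for t1, t2 in pairs:
            c = result._cell_rows[(g, t1)] - result._cell_rows[(g, t2)]
            diff = float(c @ params)
            se = float(np.sqrt(c @ cov @ c))
            if se == 0:
                rows.append({"genotype": g, "contrast": f"T{t1} - T{t2}", "difference": diff,
                             "se": se, "t": np.nan, "p_value": np.nan, "flag": "inestimable"})
                continue
            t_stat = diff / se
            p = float(2 * stats.t.sf(abs(t_stat), df))
            if method == "bonferroni":
                p = min(1.0, p * len(pairs))
            rows.append({"genotype": g, "contrast": f"T{t1} - T{t2}", "difference": diff,
                         "se": se, "t": float(t_stat), "p_value": p, "flag": None})
    return pd.DataFrame(rows)
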