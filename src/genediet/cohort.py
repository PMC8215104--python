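"""Cohort table I/O, eligibility filtering, SES scoring, and descriptive summaries.

The cohort is carried through the pipeline as a :class:`pandas.DataFrame`
with one row per subject and a canonical column vocabulary (see
:data:`NUMERIC_COLUMNS` / :data:`CATEGORICAL_COLUMNS`).  ``read_cohort``
maps arbitrary input headers onto that vocabulary, coerces numerics, and
validates invariants; every downstream stage consumes the canonical frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class SchemaError(ValueError):
    """Input table does not provide a mandatory column."""


class CohortValidationError(ValueError):
    """A field violates its declared domain."""


#: food-group intake columns, g/day
FOOD_GROUP_COLUMNS = (
    "fruits",
    "vegetables",
    "whole_grains",
    "low_fat_dairy",
    "nuts",
    "legumes",
    "red_processed_meat",
    "sweetened_beverages",
    "cereals",
    "fish_seafood",
    "dairy_total",
    "meat_total",
)

DASS_COLUMNS = tuple(f"dass_{i}" for i in range(1, 22))
#: default VAS appetite items: hunger, satiation, fullness, prospective
#: consumption, thirst, desire for sweet / salty / fatty food (mm, 0-100)
VAS_COLUMNS = tuple(f"vas_{i}" for i in range(1, 9))
SES_ITEM_COLUMNS = ("ses_education", "ses_occupation", "ses_house_ownership", "ses_family_size")

NUMERIC_COLUMNS = (
    ("age", "weight", "height", "waist_circumference", "fat_mass", "fat_free_mass", "energy_intake")
    + FOOD_GROUP_COLUMNS
    + ("sodium", "mufa", "sfa", "tc", "hdl", "tg", "glucose", "insulin", "sbp_1", "sbp_2", "dbp_1", "dbp_2")
    + DASS_COLUMNS
    + VAS_COLUMNS
    + SES_ITEM_COLUMNS
)

CATEGORICAL_COLUMNS = ("sex", "physical_activity", "marital_status")

#: columns a table must provide to enter the pipeline
MANDATORY_COLUMNS = ("subject_id",) + CATEGORICAL_COLUMNS[:1] + NUMERIC_COLUMNS

#: optional genotype evidence: a call label and/or RFLP fragment lengths
GENOTYPE_COLUMNS = ("genotype", "rflp_fragments")

ALL_COLUMNS = ("subject_id",) + CATEGORICAL_COLUMNS + NUMERIC_COLUMNS + GENOTYPE_COLUMNS


@dataclass(frozen=True)
class EligibilityConfig:
    """Inclusion rules: healthy obese adults with plausible energy reporting.

    Defaults encode the study population: ages 20-50 y, BMI >= 30 kg/m^2,
    reported energy inside the closed interval [800, 4200] kcal/day
    (implausible under/over-reporters fall outside it).
    """

    age_range: tuple[float, float] = (20.0, 50.0)
    bmi_min: float = 30.0
    energy_range: tuple[float, float] = (800.0, 4200.0)
    #: boolean columns that, when True, exclude the subject (medical
    #: history, pregnancy, relevant medication, ...)
    exclusion_flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.age_range[0] > self.age_range[1] or self.energy_range[0] > self.energy_range[1]:
            raise CohortValidationError("eligibility intervals must be non-empty")
        if self.bmi_min <= 0:
            raise CohortValidationError("bmi_min must be positive")


@dataclass
class ExclusionLog:
    """Per-subject record of the first eligibility rule each exclusion violated."""

    reasons: pd.Series  # indexed like the input; NaN for retained subjects
    n_input: int

    @property
    def n_excluded(self) -> int:
        return int(self.reasons.notna().sum())

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_excluded

    def counts(self) -> pd.Series:
        """Number of exclusions per rule."""
        return self.reasons.dropna().value_counts()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"excluded": self.reasons.notna(), "rule": self.reasons})


def read_cohort(path, schema: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a subject-level CSV into the canonical cohort frame.

    Parameters
    ----------
    path
        CSV file (UTF-8, header row). Missing values may be empty cells
        or ``NA``.
    schema
        Optional mapping ``{file column -> canonical column}`` applied
        before validation, for tables whose headers differ from the
        canonical vocabulary.

    Returns
    -------
    pandas.DataFrame
        One row per input row, row order preserved.  Unparseable numeric
        cells become NaN.

    Raises
    ------
    SchemaError
        If a mandatory column is absent (the message names every missing
        column) or the file is empty.
    """
    try:
        df = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty cohort file: {path}") from exc
    if schema:
        df = df.rename(columns=schema)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"mandatory column(s) missing: {', '.join(missing)}")
    if len(df) == 0:
        raise SchemaError(f"cohort file has a header but no rows: {path}")
    for col in NUMERIC_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["subject_id"] = df["subject_id"].astype(str)
    _validate_domains(df)
    return df.reset_index(drop=True)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a canonical cohort frame back to CSV (round-trips with read_cohort)."""
    cols = [c for c in ALL_COLUMNS if c in cohort.columns]
    cols += [c for c in cohort.columns if c not in cols]
    cohort.to_csv(path, index=False, columns=cols)


def _validate_domains(df: pd.DataFrame) -> None:
    bad_sex = ~df["sex"].isin(["male", "female"]) & df["sex"].notna()
    if bad_sex.any():
        raise CohortValidationError(f"sex must be male/female; bad rows: {list(df.index[bad_sex][:5])}")
    for col in DASS_COLUMNS:
        v = df[col]
        if ((v < 0) | (v > 3)).any():
            raise CohortValidationError(f"{col} outside 0-3")
    for col in VAS_COLUMNS:
        v = df[col]
        if ((v < 0) | (v > 100)).any():
            raise CohortValidationError(f"{col} outside 0-100 mm")
    for col in FOOD_GROUP_COLUMNS + ("sodium", "mufa", "sfa", "energy_intake"):
        if (df[col] < 0).any():
            raise CohortValidationError(f"{col} has negative intakes")


def bmi(weight_kg, height_cm):
    """Body-mass index, kg/m^2."""
    return np.asarray(weight_kg, dtype=float) / (np.asarray(height_cm, dtype=float) / 100.0) ** 2


def apply_eligibility(
    cohort: pd.DataFrame, criteria: EligibilityConfig | None = None
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Partition the cohort into retained and excluded subjects.

    A subject is retained iff age is within the closed age range, BMI
    (weight / height^2) is at least ``bmi_min``, reported energy intake is
    inside the closed energy interval, and no exclusion flag is set.
    Subjects missing any field an eligibility rule needs are excluded as
    ``incomplete``.  For each excluded subject only the *first* violated
    rule (in the order incomplete, age, bmi, energy, flag name) is logged,
    mirroring a screening flow.
    """
    criteria = criteria or EligibilityConfig()
    reasons = pd.Series(pd.NA, index=cohort.index, dtype="object")

    needed = ["age", "weight", "height", "energy_intake"]
    incomplete = cohort[needed].isna().any(axis=1)
    reasons[incomplete] = "incomplete"

    age_ok = cohort["age"].between(*criteria.age_range)
    reasons[reasons.isna() & ~age_ok] = "age"

    bmi_ok = bmi(cohort["weight"], cohort["height"]) >= criteria.bmi_min
    reasons[reasons.isna() & ~bmi_ok] = "bmi"

    energy_ok = cohort["energy_intake"].between(*criteria.energy_range)
    reasons[reasons.isna() & ~energy_ok] = "energy"

    for flag in criteria.exclusion_flags:
        if flag in cohort.columns:
            hit = cohort[flag].fillna(False).astype(bool)
            reasons[reasons.isna() & hit] = flag

    retained = cohort[reasons.isna()].copy()
    return retained, ExclusionLog(reasons=reasons, n_input=len(cohort))


# --- socio-economic status -------------------------------------------------

@dataclass(frozen=True)
class SESConfig:
    """How the summed SES score maps to {low, middle, high}.

    Three ordinal indicator scales (education, occupation, house
    ownership) are summed; family size is an optional fourth.  Cut points
    default to the empirical tertiles of the summed score; fixed cut
    points may be supplied instead.
    """

    items: tuple[str, ...] = ("ses_education", "ses_occupation", "ses_house_ownership")
    item_range: tuple[float, float] = (0.0, 4.0)
    cut_points: tuple[float, float] | None = None  # None -> empirical tertiles


def score_ses(cohort: pd.DataFrame, config: SESConfig | None = None) -> pd.Series:
    """Composite socio-economic category per subject: low / middle / high.

    Raises
    ------
    CohortValidationError
        If any item lies outside the configured ordinal scale.
    """
    config = config or SESConfig()
    items = cohort[list(config.items)]
    lo, hi = config.item_range
    if ((items < lo) | (items > hi)).any().any():
        raise CohortValidationError(f"SES item outside the configured scale [{lo}, {hi}]")
    total = items.sum(axis=1, skipna=False)
    if config.cut_points is None:
        c1, c2 = np.nanquantile(total.to_numpy(float), [1 / 3, 2 / 3])
    else:
        c1, c2 = config.cut_points
    cat = pd.Series("low", index=cohort.index, dtype="object")
    cat[total > c1] = "middle"
    cat[total > c2] = "high"
    cat[total.isna()] = pd.NA
    return cat


# --- descriptive summaries --------------------------------------------------

def summarize_cohort(
    cohort: pd.DataFrame,
    variables: list[str] | None = None,
    skew_threshold: float = 1.0,
) -> pd.DataFrame:
    """Descriptive summary with normality-based routing.

    Continuous variables with ``|skewness| <= skew_threshold`` are reported
    as mean (SD); more skewed variables as median (25th, 75th percentile).
    Categorical variables are reported as percentage tables.  A constant
    variable has SD 0 and, by convention, skewness 0.
    """
    variables = variables or [c for c in cohort.columns if c != "subject_id"]
    rows = []
    for var in variables:
        col = cohort[var]
        if pd.api.types.is_numeric_dtype(col):
            v = col.dropna().to_numpy(float)
            if v.size == 0:
                rows.append({"variable": var, "kind": "missing", "summary": "all missing"})
                continue
            skew = 0.0 if np.ptp(v) == 0 else float(stats.skew(v))
            if abs(skew) <= skew_threshold:
                rows.append({
                    "variable": var, "kind": "mean_sd", "skewness": skew,
                    "center": float(np.mean(v)), "spread_low": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
                    "spread_high": np.nan,
                    "summary": f"{np.mean(v):.2f} ({(np.std(v, ddof=1) if v.size > 1 else 0.0):.2f})",
                })
            else:
                q25, q50, q75 = np.percentile(v, [25, 50, 75])
                rows.append({
                    "variable": var, "kind": "median_iqr", "skewness": skew,
                    "center": float(q50), "spread_low": float(q25), "spread_high": float(q75),
                    "summary": f"{q50:.2f} ({q25:.2f}, {q75:.2f})",
                })
        else:
            pct = col.value_counts(normalize=True, dropna=True) * 100
            for level, p in pct.items():
                rows.append({
                    "variable": f"{var}={level}", "kind": "percent",
                    "center": float(p), "summary": f"{p:.1f}%",
                })
    return pd.DataFrame(rows)


# --- physical activity helper ----------------------------------------------

def ipaq_category(met_min_per_week: float) -> str:
    """Map IPAQ total MET-min/week to {low, moderate, high} at 600/3000 cut points."""
    if met_min_per_week < 0:
        raise CohortValidationError("MET-min/week must be non-negative")
    if met_min_per_week < 600:
        return "low"
    if met_min_per_week < 3000:
        return "moderate"
    return "high"
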