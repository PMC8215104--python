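"""Diet-quality indices: the Fung-style DASH score and the alcohol-free
Trichopoulou Mediterranean Diet Score (MDS).

Both indices are built on sex-specific quantile machinery applied within
the study population:

* DASH — eight food-group/nutrient components.  Emphasized components
  (fruits, vegetables, whole grains, low-fat dairy, nuts+legumes) score
  their sex-specific quintile rank 1-5; discouraged components (sodium,
  red/processed meat, sweetened beverages) are reverse-scored 6 - rank.
  The total therefore ranges 8-40.
* MDS — eight binary indicators at sex-specific medians: 1 for intake at
  or above the median of a protective component (vegetables, legumes,
  fruits+nuts, cereals, fish and seafood, MUFA:SFA ratio) and 1 for
  intake *below* the median of a non-protective component (meat, dairy).
  Total 0-8; the alcohol component is omitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class StratumSizeError(ValueError):
    """A sex stratum is too small for the requested quantile grouping."""


class UndefinedRatioError(ValueError):
    """MUFA:SFA ratio undefined (SFA <= 0)."""


#: DASH component -> (intake columns summed, emphasized?)
DASH_COMPONENTS: dict[str, tuple[tuple[str, ...], bool]] = {
    "fruits": (("fruits",), True),
    "vegetables": (("vegetables",), True),
    "whole_grains": (("whole_grains",), True),
    "low_fat_dairy": (("low_fat_dairy",), True),
    "nuts_legumes": (("nuts", "legumes"), True),
    "sodium": (("sodium",), False),
    "red_processed_meat": (("red_processed_meat",), False),
    "sweetened_beverages": (("sweetened_beverages",), False),
}

#: MDS component -> (intake columns summed, protective?); the MUFA:SFA
#: ratio component is computed separately.
MDS_COMPONENTS: dict[str, tuple[tuple[str, ...], bool]] = {
    "vegetables": (("vegetables",), True),
    "legumes": (("legumes",), True),
    "fruits_nuts": (("fruits", "nuts"), True),
    "cereals": (("cereals",), True),
    "fish_seafood": (("fish_seafood",), True),
    "meat": (("red_processed_meat",), False),
    "dairy": (("dairy_total",), False),
}


def sex_specific_quantile_ranks(
    values: pd.Series, sex: pd.Series, k: int = 5
) -> pd.Series:
    """Rank subjects into ``k`` quantile groups within each sex stratum.

    Group boundaries sit at the i/k empirical quantiles (linear
    interpolation); a subject's rank is 1 plus the number of boundaries
    its value strictly exceeds, so ties share the lowest qualifying group
    and a constant stratum collapses to rank 1.

    Raises
    ------
    StratumSizeError
        If a stratum has fewer than ``k`` non-missing values.
    """
    out = pd.Series(np.nan, index=values.index, dtype=float)
    for label, idx in values.groupby(sex, observed=True).groups.items():
        v = values.loc[idx]
        obs = v.dropna()
        if len(obs) < k:
            raise StratumSizeError(f"stratum {label!r} has {len(obs)} values; need >= {k}")
        cuts = np.quantile(obs.to_numpy(float), [i / k for i in range(1, k)])
        out.loc[obs.index] = 1 + (obs.to_numpy(float)[:, None] > cuts[None, :]).sum(axis=1)
    return out


def mufa_sfa_ratio(mufa, sfa):
    """MUFA:SFA ratio (dimensionless); undefined for SFA <= 0."""
    mufa = np.asarray(mufa, dtype=float)
    sfa = np.asarray(sfa, dtype=float)
    if np.any(sfa[~np.isnan(sfa)] <= 0):
        raise UndefinedRatioError("SFA must be positive to form the MUFA:SFA ratio")
    return mufa / sfa


def _component_amounts(cohort: pd.DataFrame, mapping) -> pd.DataFrame:
    return pd.DataFrame(
        {name: cohort[list(cols)].sum(axis=1, skipna=False) for name, (cols, _) in mapping.items()}
    )


def score_dash(
    cohort: pd.DataFrame,
    components: dict[str, tuple[tuple[str, ...], bool]] | None = None,
) -> pd.DataFrame:
    """Per-subject DASH component scores and total (range 8-40).

    Returns a frame with one integer column per component (1-5), a
    ``dash_total`` column, and NaN rows for subjects missing any
    component amount (flagged unscored, not dropped).
    """
    components = components or DASH_COMPONENTS
    amounts = _component_amounts(cohort, components)
    out = pd.DataFrame(index=cohort.index)
    for name, (cols, emphasized) in components.items():
        rank = sex_specific_quantile_ranks(amounts[name], cohort["sex"], k=5)
        out[name] = rank if emphasized else 6 - rank
    out["dash_total"] = out.sum(axis=1, skipna=False)
    return out


def score_mds(
    cohort: pd.DataFrame,
    components: dict[str, tuple[tuple[str, ...], bool]] | None = None,
) -> pd.DataFrame:
    """Per-subject MDS indicators and total (range 0-8).

    Protective components (including the MUFA:SFA ratio) score 1 at or
    above the sex-specific median; non-protective components score 1
    below it.  Subjects with an undefined ratio (SFA = 0) are unscored
    for that component and hence for the total.
    """
    components = components or MDS_COMPONENTS
    amounts = _component_amounts(cohort, components)
    sfa = cohort["sfa"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(sfa > 0, cohort["mufa"].to_numpy(float) / sfa, np.nan)
    amounts["mufa_sfa"] = ratio
    protective = {name: prot for name, (_, prot) in components.items()}
    protective["mufa_sfa"] = True

    out = pd.DataFrame(index=cohort.index)
    for name in amounts.columns:
        v = amounts[name]
        med = v.groupby(cohort["sex"], observed=True).transform("median")
        ind = (v >= med) if protective[name] else (v < med)
        out[name] = ind.astype(float).where(v.notna() & med.notna())
    out["mds_total"] = out.sum(axis=1, skipna=False)
    return out


@dataclass(frozen=True)
class TertileAssignment:
    """Tertile labels plus the per-stratum cut points used."""

    tertile: pd.Series = field(repr=False)  # values in {1, 2, 3}
    cut_points: dict[str, tuple[float, float]] = field(default_factory=dict)

    def label(self) -> pd.Series:
        return self.tertile.map({1: "T1", 2: "T2", 3: "T3"})


def assign_tertiles(
    scores: pd.Series, sex: pd.Series | None = None
) -> TertileAssignment:
    """Assign T1/T2/T3 with cut points at the 33.3rd/66.7th percentiles.

    If ``sex`` is given, cut points are computed separately per stratum.
    Ties at a cut point fall into the lower tertile.

    Raises
    ------
    StratumSizeError
        If a stratum holds fewer than 3 non-missing scores.
    """
    strata = sex if sex is not None else pd.Series("all", index=scores.index)
    tert = pd.Series(np.nan, index=scores.index, dtype=float)
    cuts_by_stratum: dict[str, tuple[float, float]] = {}
    for label, idx in scores.groupby(strata, observed=True).groups.items():
        obs = scores.loc[idx].dropna()
        if len(obs) < 3:
            raise StratumSizeError(f"stratum {label!r} has {len(obs)} scores; need >= 3")
        c1, c2 = np.quantile(obs.to_numpy(float), [1 / 3, 2 / 3])
        cuts_by_stratum[str(label)] = (float(c1), float(c2))
        tert.loc[obs.index] = 1 + (obs > c1).astype(int) + (obs > c2).astype(int)
    return TertileAssignment(tertile=tert, cut_points=cuts_by_stratum)
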