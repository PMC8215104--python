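"""Derived cardiometabolic indices, metabolic-syndrome classification,
binary risk flags, DASS-21 mental-health subscales, and the VAS appetite
summary.

Formulas (mass units, mg/dl and uU/ml):

* Friedewald LDL-C  = TC - HDL-C - TG/5, valid for TG < 400 mg/dl
* AIP               = log10(TG / HDL-C)
* HOMA-IR           = glucose x insulin / 405
* QUICKI            = 1 / (log10 insulin + log10 glucose)

Metabolic syndrome follows the NCEP ATP III rule: three or more of
{waist circumference > 102 cm (men) / > 88 cm (women); BP >= 130/85 mmHg;
TG >= 150 mg/dl; HDL-C < 40 (men) / < 50 (women) mg/dl; fasting glucose
>= 100 mg/dl}.  An alternative ruleset with WC > 88 cm for all subjects
and a glucose cut of 110 mg/dl is provided under the name
``"unisex_wc88"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


class DomainError(ValueError):
    """An input lies outside the formula's mathematical domain."""


class FriedewaldValidityError(ValueError):
    """TG >= 400 mg/dl: the Friedewald approximation is not valid."""


def friedewald_ldl(tc, hdl, tg, *, on_invalid: str = "raise"):
    """LDL cholesterol (mg/dl) by the Friedewald formula, TC - HDL - TG/5.

    ``on_invalid`` controls TG >= 400 mg/dl: ``"raise"`` (default) or
    ``"nan"`` to return a missing value for those subjects.
    """
    tc = np.asarray(tc, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    tg = np.asarray(tg, dtype=float)
    invalid = tg >= 400
    if np.any(invalid & ~np.isnan(tg)):
        if on_invalid == "raise":
            raise FriedewaldValidityError("TG >= 400 mg/dl; Friedewald formula not valid")
        if on_invalid != "nan":
            raise ValueError("on_invalid must be 'raise' or 'nan'")
    ldl = tc - hdl - tg / 5.0
    if on_invalid == "nan":
        ldl = np.where(invalid, np.nan, ldl)
    return ldl


def aip(tg, hdl):
    """Atherogenic index of plasma, log10(TG/HDL-C); both inputs mg/dl, > 0."""
    tg = np.asarray(tg, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    if np.any((tg <= 0) & ~np.isnan(tg)) or np.any((hdl <= 0) & ~np.isnan(hdl)):
        raise DomainError("AIP requires positive TG and HDL-C")
    return np.log10(tg / hdl)


def homa_ir(glucose, insulin):
    """HOMA insulin-resistance index: glucose [mg/dl] x insulin [uU/ml] / 405."""
    glucose = np.asarray(glucose, dtype=float)
    insulin = np.asarray(insulin, dtype=float)
    if np.any((glucose < 0) & ~np.isnan(glucose)) or np.any((insulin < 0) & ~np.isnan(insulin)):
        raise DomainError("HOMA-IR requires non-negative inputs")
    return glucose * insulin / 405.0


def quicki(glucose, insulin):
    """QUICKI insulin-sensitivity index: 1 / (log10 insulin + log10 glucose)."""
    glucose = np.asarray(glucose, dtype=float)
    insulin = np.asarray(insulin, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        logsum = np.log10(insulin) + np.log10(glucose)
    bad = (logsum <= 0) & ~np.isnan(logsum)
    if np.any(bad):
        raise DomainError("QUICKI undefined: log10(insulin) + log10(glucose) <= 0")
    return 1.0 / logsum


def mean_bp(reading_1, reading_2):
    """Average of two blood-pressure readings; falls back to the available one."""
    a = np.asarray(reading_1, dtype=float)
    b = np.asarray(reading_2, dtype=float)
    stacked = np.stack([a, b])
    with np.errstate(invalid="ignore"):
        return np.nanmean(stacked, axis=0)


def appetite_score(vas_items) -> float:
    """Mean of the configured VAS appetite items (mm on the 100-mm line)."""
    v = np.asarray(vas_items, dtype=float)
    if v.size == 0:
        raise ValueError("no VAS items supplied")
    if np.any((v < 0) | (v > 100)):
        raise DomainError("VAS items must lie in [0, 100] mm")
    return float(np.mean(v))


# --- metabolic syndrome -----------------------------------------------------

#: named MetS rulesets; each criterion is a callable of the subject row
METS_RULESETS = {
    "atp3": {
        "waist": lambda r: r["waist_circumference"] > (102.0 if r["sex"] == "male" else 88.0),
        "bp": lambda r: (r["sbp"] >= 130.0) or (r["dbp"] >= 85.0),
        "tg": lambda r: r["tg"] >= 150.0,
        "hdl": lambda r: r["hdl"] < (40.0 if r["sex"] == "male" else 50.0),
        "glucose": lambda r: r["glucose"] >= 100.0,
    },
    # unisex waist cut and the older impaired-fasting-glucose threshold
    "unisex_wc88": {
        "waist": lambda r: r["waist_circumference"] > 88.0,
        "bp": lambda r: (r["sbp"] >= 130.0) or (r["dbp"] >= 85.0),
        "tg": lambda r: r["tg"] >= 150.0,
        "hdl": lambda r: r["hdl"] < 50.0,
        "glucose": lambda r: r["glucose"] >= 110.0,
    },
}


def classify_mets(row: dict | pd.Series, ruleset: str = "atp3") -> tuple[bool | None, int | None]:
    """(MetS status, criteria count 0-5) for one subject.

    ``row`` must carry sex, waist_circumference, sbp, dbp, tg, hdl and
    glucose.  Any missing input leaves the subject unclassified
    (``(None, None)``).
    """
    rules = METS_RULESETS[ruleset]
    needed = ["sex", "waist_circumference", "sbp", "dbp", "tg", "hdl", "glucose"]
    for key in needed:
        val = row[key]
        if val is None or (isinstance(val, float) and math.isnan(val)):
            return None, None
    count = sum(bool(rule(row)) for rule in rules.values())
    return count >= 3, count


RISK_FLAG_NAMES = (
    "high_cholesterol", "high_ldl", "low_hdl", "high_tg",
    "high_bp", "hyperglycemia", "high_homa", "low_quicki",
)


def classify_risk_flags(row: dict | pd.Series, quicki_cut: float = 0.33) -> dict[str, bool | None]:
    """Eight binary cardiometabolic risk flags per ATP III-style cut-offs.

    TC >= 220; LDL-C >= 160; HDL-C < 40 (men) / < 50 (women); TG >= 150;
    SBP/DBP >= 130/85; glucose >= 100; HOMA-IR > 2.6 (strict); QUICKI
    below ``quicki_cut`` (default 0.33).  A missing input leaves that
    flag undefined (None).
    """
    def _get(key):
        val = row[key]
        if val is None or (isinstance(val, float) and math.isnan(val)):
            return None
        return val

    sex = row["sex"]
    rules = {
        "high_cholesterol": ("tc", lambda v: v >= 220.0),
        "high_ldl": ("ldl", lambda v: v >= 160.0),
        "low_hdl": ("hdl", lambda v: v < (40.0 if sex == "male" else 50.0)),
        "high_tg": ("tg", lambda v: v >= 150.0),
        "hyperglycemia": ("glucose", lambda v: v >= 100.0),
        "high_homa": ("homa_ir", lambda v: v > 2.6),
        "low_quicki": ("quicki", lambda v: v < quicki_cut),
    }
    flags: dict[str, bool | None] = {}
    for name, (key, rule) in rules.items():
        v = _get(key)
        flags[name] = None if v is None else bool(rule(v))
    sbp, dbp = _get("sbp"), _get("dbp")
    flags["high_bp"] = None if sbp is None or dbp is None else bool(sbp >= 130.0 or dbp >= 85.0)
    return {name: flags[name] for name in RISK_FLAG_NAMES}


# --- DASS-21 ----------------------------------------------------------------

#: 1-based item numbers of each DASS-21 subscale (standard assignment)
DASS_SUBSCALE_ITEMS = {
    "depression": (3, 5, 10, 13, 16, 17, 21),
    "anxiety": (2, 4, 7, 9, 15, 19, 20),
    "stress": (1, 6, 8, 11, 12, 14, 18),
}

#: Lovibond severity bands on the doubled (0-42) scores: upper bounds of
#: normal, mild, moderate and severe; above the last bound is extremely severe
DASS_SEVERITY_CUTS = {
    "depression": (9, 13, 20, 27),
    "anxiety": (7, 9, 14, 19),
    "stress": (14, 18, 25, 33),
}

DASS_SEVERITY_LABELS = ("normal", "mild", "moderate", "severe", "extremely_severe")


def score_dass(
    items,
    subscale_items: dict[str, tuple[int, ...]] | None = None,
    severity_cuts: dict[str, tuple[int, ...]] | None = None,
) -> dict[str, dict]:
    """DASS-21 subscale scores (doubled sums, 0-42, always even) + severity.

    ``items`` is the ordered sequence of the 21 responses (each 0-3).
    """
    subscale_items = subscale_items or DASS_SUBSCALE_ITEMS
    severity_cuts = severity_cuts or DASS_SEVERITY_CUTS
    v = np.asarray(items, dtype=float)
    if v.shape != (21,):
        raise ValueError(f"expected 21 DASS items, got {v.shape}")
    if np.any((v < 0) | (v > 3)):
        raise DomainError("DASS items must lie in 0-3")
    out = {}
    for scale, idx in subscale_items.items():
        score = int(2 * sum(v[i - 1] for i in idx))
        cuts = severity_cuts[scale]
        band = sum(score > c for c in cuts)
        out[scale] = {"score": score, "severity": DASS_SEVERITY_LABELS[band]}
    return out


# --- cohort-level panel -----------------------------------------------------

def phenotype_panel(
    cohort: pd.DataFrame,
    mets_ruleset: str = "atp3",
    quicki_cut: float = 0.33,
    friedewald_invalid: str = "nan",
) -> pd.DataFrame:
    """Derive the full phenotype panel for a canonical cohort frame.

    Columns: ldl, aip, homa_ir, quicki, sbp, dbp, mets, mets_count, the
    eight risk flags, dass_depression/anxiety/stress (+ severity) and
    appetite.  Per-subject missing inputs propagate to missing outputs.
    """
    out = pd.DataFrame(index=cohort.index)
    out["ldl"] = friedewald_ldl(cohort["tc"], cohort["hdl"], cohort["tg"], on_invalid=friedewald_invalid)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["aip"] = np.log10(cohort["tg"] / cohort["hdl"])
        logsum = np.log10(cohort["insulin"].to_numpy(float)) + np.log10(cohort["glucose"].to_numpy(float))
        out["homa_ir"] = homa_ir(cohort["glucose"].clip(lower=0), cohort["insulin"].clip(lower=0))
        out["quicki"] = np.where(logsum > 0, 1.0 / logsum, np.nan)
    out["sbp"] = mean_bp(cohort["sbp_1"], cohort["sbp_2"])
    out["dbp"] = mean_bp(cohort["dbp_1"], cohort["dbp_2"])

    panel_rows = pd.concat([cohort[["sex", "waist_circumference", "tc", "hdl", "tg", "glucose"]], out], axis=1)
    mets, counts = zip(*(classify_mets(row, ruleset=mets_ruleset) for _, row in panel_rows.iterrows()))
    out["mets"] = pd.array(mets, dtype="boolean")
    out["mets_count"] = pd.array(counts, dtype="Int64")
    flag_rows = [classify_risk_flags(row, quicki_cut=quicki_cut) for _, row in panel_rows.iterrows()]
    for name in RISK_FLAG_NAMES:
        out[name] = pd.array([r[name] for r in flag_rows], dtype="boolean")

    dass_cols = [f"dass_{i}" for i in range(1, 22)]
    if set(dass_cols) <= set(cohort.columns):
        for i, row in cohort[dass_cols].iterrows():
            if row.isna().any():
                continue
            scored = score_dass(row.to_numpy(float))
            for scale, res in scored.items():
                out.loc[i, f"dass_{scale}"] = res["score"]
                out.loc[i, f"dass_{scale}_severity"] = res["severity"]
    vas_cols = [c for c in cohort.columns if c.startswith("vas_")]
    if vas_cols:
        out["appetite"] = cohort[vas_cols].mean(axis=1)
    if "subject_id" in cohort.columns:
        out.insert(0, "subject_id", cohort["subject_id"])
    return out
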