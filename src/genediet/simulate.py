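"""Synthetic-cohort generator.

Generates subject-level tables with the statistical structure the
analysis assumes: the observed genotype mix (CC/CT/TT =
37.8/51.9/10.3%), log-normal food-group intakes and Gaussian biomarkers
anchored to the emulated study's reported marginals, and *plantable*
effects — per-
response genotype main-effect shifts, genotype x diet-tertile interaction
shifts, and binary-outcome log-odds — so that every downstream stage can
be exercised against a known ground truth.

All randomness flows from a single integer seed.  The same config + seed
always reproduces the identical cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import diet_scores
from .cohort import DASS_COLUMNS, VAS_COLUMNS

#: default genotype mix (CC, CT, TT), the observed cohort prevalence
DEFAULT_GENOTYPE_PROBS = (0.378, 0.519, 0.103)

#: per-component log-normal intake parameters: overall median (g/day;
#: sodium mg/day) and log-scale sigma, anchored to the emulated cohort's
#: reported values where available and chosen as realistic elsewhere.  Sex-specific medians apply a multiplicative
#: male/female factor.
DEFAULT_INTAKE_PARAMS: dict[str, tuple[float, float]] = {
    "fruits": (444.0, 0.70),
    "vegetables": (320.0, 0.59),
    "nuts": (11.0, 1.10),
    "legumes": (49.0, 0.70),
    "red_processed_meat": (49.0, 0.78),
    "cereals": (523.0, 0.50),
    "fish_seafood": (6.4, 1.20),
    "dairy_total": (260.0, 0.84),
    "sweetened_beverages": (80.0, 0.90),
    "sodium": (3500.0, 0.30),
}

#: (male, female) multiplicative factors on intake medians
SEX_INTAKE_FACTORS = {"male": 1.12, "female": 0.86}

#: biomarker marginals: mean, SD (normal draws, clipped to a floor)
DEFAULT_BIOMARKER_PARAMS: dict[str, tuple[float, float, float]] = {
    # name: (mean, sd, floor)
    "tc": (188.43, 33.73, 90.0),
    "hdl": (44.97, 8.85, 22.0),
    "tg": (119.97, 58.46, 35.0),
    "glucose": (91.5, 9.5, 60.0),
    "sbp": (115.64, 16.44, 85.0),
    "dbp": (76.33, 12.32, 45.0),
}

#: insulin is right-skewed: log-normal (median, log-sigma)
DEFAULT_INSULIN_PARAMS = (13.1, 0.70)


@dataclass
class EffectConfig:
    """Planted effects, all expressed on the response scale.

    ``main_effects[response][genotype]`` shifts the response mean for a
    genotype; ``interaction[response][(genotype, tertile)]`` shifts one
    genotype x diet-tertile cell; ``binary_outcomes[name]`` draws a 0/1
    column from a logistic model with a baseline log-odds plus per-
    genotype log-odds.  The default plants a TT-vs-CC odds ratio of 3.58
    on a high-triglyceride outcome, the study's headline association.
    """

    main_effects: dict = field(default_factory=dict)
    interaction: dict = field(default_factory=dict)
    binary_outcomes: dict = field(default_factory=lambda: {
        "high_tg_sim": {"baseline": math.log(0.25 / 0.75),
                        "genotype_logodds": {"CC": 0.0, "CT": 0.0, "TT": math.log(3.58)}},
    })

    @classmethod
    def null(cls) -> "EffectConfig":
        """No planted effects at all (for calibration studies)."""
        return cls(main_effects={}, interaction={}, binary_outcomes={})


@dataclass
class SimulationConfig:
    n: int = 347
    sex_ratio_male: float = 0.582
    genotype_probs: tuple[float, float, float] = DEFAULT_GENOTYPE_PROBS
    #: alternatively draw genotypes from Hardy-Weinberg at this MAF
    hwe_maf: float | None = None
    intake_params: dict = field(default_factory=lambda: dict(DEFAULT_INTAKE_PARAMS))
    biomarker_params: dict = field(default_factory=lambda: dict(DEFAULT_BIOMARKER_PARAMS))
    effects: EffectConfig = field(default_factory=EffectConfig)
    #: which diet score carries the planted interaction (dash or mds)
    interaction_score: str = "dash"
    #: keep reported energy inside the plausibility window so the default
    #: cohort passes eligibility unfiltered
    clip_energy: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not math.isclose(sum(self.genotype_probs), 1.0, abs_tol=1e-9):
            raise ValueError("genotype_probs must sum to 1")
        if not 0 <= self.sex_ratio_male <= 1:
            raise ValueError("sex_ratio_male must be in [0, 1]")
        for name, (med, sig) in self.intake_params.items():
            if med <= 0 or sig < 0:
                raise ValueError(f"invalid intake params for {name}")
        if self.hwe_maf is not None and not 0 <= self.hwe_maf <= 0.5:
            raise ValueError("hwe_maf must be in [0, 0.5]")
        if self.interaction_score not in ("dash", "mds"):
            raise ValueError("interaction_score must be 'dash' or 'mds'")


@dataclass
class SimulatedCohort:
    cohort: pd.DataFrame
    ground_truth: dict


def simulate_genotypes(n: int, config: SimulationConfig | None = None, rng=None) -> np.ndarray:
    """Draw i.i.d. CC/CT/TT labels from the configured mix (or HWE at a MAF)."""
    config = config or SimulationConfig()
    rng = _as_rng(rng, config.seed)
    if config.hwe_maf is not None:
        q = config.hwe_maf
        probs = ((1 - q) ** 2, 2 * q * (1 - q), q ** 2)
    else:
        probs = config.genotype_probs
    return rng.choice(["CC", "CT", "TT"], size=n, p=probs)


def simulate_intakes(
    n: int, sex: np.ndarray, config: SimulationConfig | None = None, rng=None
) -> pd.DataFrame:
    """Log-normal food-group and nutrient intakes with sex-specific medians.

    Also derives the dependent intake columns (whole grains as a share of
    cereals, low-fat dairy as a share of total dairy, meat total, MUFA and
    SFA) and reported energy as a linear function of the caloric
    components plus reporting noise.
    """
    config = config or SimulationConfig()
    rng = _as_rng(rng, config.seed)
    factors = np.where(np.asarray(sex) == "male", SEX_INTAKE_FACTORS["male"], SEX_INTAKE_FACTORS["female"])
    out = pd.DataFrame(index=range(n))
    for name, (median, sigma) in config.intake_params.items():
        out[name] = np.exp(np.log(median * factors) + sigma * rng.standard_normal(n))
    out["whole_grains"] = out["cereals"] * rng.beta(4, 9, size=n)  # ~30% of cereals
    out["low_fat_dairy"] = out["dairy_total"] * rng.beta(5, 5, size=n)
    out["meat_total"] = out["red_processed_meat"] * (1 + rng.beta(3, 5, size=n))
    out["sfa"] = np.exp(np.log(28.0 * factors) + 0.35 * rng.standard_normal(n))
    ratio = np.clip(rng.normal(1.21, 0.31, size=n), 0.25, None)
    out["mufa"] = ratio * out["sfa"]
    out["energy_intake"] = reported_energy(out, rng)
    if config.clip_energy:
        out["energy_intake"] = out["energy_intake"].clip(820.0, 4150.0)
    return out


#: kcal-per-gram weights of the caloric components in the reported-energy
#: model (FFQ foods not simulated individually are absorbed into the
#: intercept and noise)
ENERGY_WEIGHTS = {
    "cereals": 0.65,
    "fruits": 0.20,
    "vegetables": 0.11,
    "nuts": 2.2,
    "legumes": 0.50,
    "red_processed_meat": 1.0,
    "dairy_total": 0.25,
    "sweetened_beverages": 0.20,
}
ENERGY_INTERCEPT = 2050.0
ENERGY_FAT_KCAL_PER_G = 2.7  # applied to MUFA+SFA as a stand-in for total fat
ENERGY_NOISE_SD = 160.0


def reported_energy(intakes: pd.DataFrame, rng) -> np.ndarray:
    """Reported daily energy (kcal) as a configured function of component intakes."""
    kcal = ENERGY_INTERCEPT + ENERGY_NOISE_SD * rng.standard_normal(len(intakes))
    for comp, w in ENERGY_WEIGHTS.items():
        kcal = kcal + w * intakes[comp].to_numpy()
    kcal = kcal + ENERGY_FAT_KCAL_PER_G * (intakes["mufa"] + intakes["sfa"]).to_numpy()
    return kcal


def simulate_covariates(n: int, sex: np.ndarray, rng) -> pd.DataFrame:
    """Anthropometrics, SES items, activity, mental-health and appetite items."""
    male = np.asarray(sex) == "male"
    out = pd.DataFrame(index=range(n))
    out["age"] = np.clip(rng.normal(38.08, 7.49, size=n), 20.0, 50.0)
    out["weight"] = np.where(male, rng.normal(102.0, 10.0, size=n), rng.normal(89.0, 12.0, size=n))
    out["weight"] = np.clip(out["weight"], 60.0, None)
    bmi = rng.uniform(30.05, 40.0, size=n)
    out["height"] = np.sqrt(out["weight"] / bmi) * 100.0
    out["waist_circumference"] = np.clip(
        np.where(male, rng.normal(113.2, 7.5, size=n), rng.normal(104.2, 10.0, size=n)), 80.0, None)
    out["fat_mass"] = np.clip(np.where(male, rng.normal(29.2, 7.3, size=n), rng.normal(38.8, 8.0, size=n)), 10.0, None)
    out["fat_free_mass"] = np.clip(out["weight"] - out["fat_mass"], 30.0, None)
    for item in ("ses_education", "ses_occupation", "ses_house_ownership"):
        out[item] = rng.integers(0, 5, size=n)
    out["ses_family_size"] = rng.integers(1, 9, size=n).astype(float)
    out["physical_activity"] = rng.choice(["low", "moderate", "high"], size=n, p=(0.478, 0.277, 0.245))
    out["marital_status"] = rng.choice(["married", "single"], size=n, p=(0.86, 0.14))
    for col in DASS_COLUMNS:
        out[col] = rng.choice([0, 1, 2, 3], size=n, p=(0.5, 0.25, 0.15, 0.10)).astype(float)
    for col in VAS_COLUMNS:
        out[col] = np.clip(rng.normal(33.58, 14.0, size=n), 0.0, 100.0)
    return out


def simulate_biomarkers(
    cohort: pd.DataFrame, effects: EffectConfig, rng,
    biomarker_params: dict | None = None, tertile_col: str = "tertile",
) -> pd.DataFrame:
    """Biomarker columns with planted genotype and genotype x tertile effects.

    ``cohort`` must already carry ``sex``, ``genotype`` and (when
    interaction effects are planted) the diet-tertile column.  Continuous
    responses are baseline mean + main effect + interaction cell shift +
    Gaussian noise; configured binary outcomes are Bernoulli draws from a
    logistic model on genotype.
    """
    params = biomarker_params or DEFAULT_BIOMARKER_PARAMS
    n = len(cohort)
    geno = cohort["genotype"].to_numpy()
    out = pd.DataFrame(index=cohort.index)
    for name, (mean, sd, floor) in params.items():
        mu = np.full(n, float(mean))
        for g, shift in effects.main_effects.get(name, {}).items():
            mu[geno == g] += shift
        for (g, t), shift in effects.interaction.get(name, {}).items():
            mask = (geno == g) & (cohort[tertile_col].to_numpy() == t)
            mu[mask] += shift
        out[name] = np.clip(mu + sd * rng.standard_normal(n), floor, None)
    med, sigma = DEFAULT_INSULIN_PARAMS
    out["insulin"] = np.exp(np.log(med) + sigma * rng.standard_normal(n))
    # two BP readings around the subject's underlying level
    for comp in ("sbp", "dbp"):
        if comp not in out.columns:
            continue
        level = out.pop(comp)
        out[f"{comp}_1"] = level + rng.normal(0.0, 3.0, size=n)
        out[f"{comp}_2"] = level + rng.normal(0.0, 3.0, size=n)
    for name, spec in effects.binary_outcomes.items():
        logodds = np.full(n, float(spec["baseline"]))
        for g, shift in spec.get("genotype_logodds", {}).items():
            logodds[geno == g] += shift
        p = 1.0 / (1.0 + np.exp(-logodds))
        out[name] = (rng.random(n) < p).astype(int)
    return out


def simulate_cohort(config: SimulationConfig | None = None) -> SimulatedCohort:
    """End-to-end synthetic cohort in the canonical schema, with ground truth.

    Stage order mirrors the analysis: sex and genotype, intakes, diet
    scores and sex-specific tertiles (so interaction effects can be
    planted on the tertile scale), covariates, then biomarkers.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n
    sex = rng.choice(["male", "female"], size=n, p=(config.sex_ratio_male, 1 - config.sex_ratio_male))
    genotype = simulate_genotypes(n, config, rng)
    intakes = simulate_intakes(n, sex, config, rng)
    covars = simulate_covariates(n, sex, rng)

    frame = pd.concat([pd.DataFrame({"sex": sex, "genotype": genotype}), intakes, covars], axis=1)
    dash = diet_scores.score_dash(frame)
    mds = diet_scores.score_mds(frame)
    score = dash["dash_total"] if config.interaction_score == "dash" else mds["mds_total"]
    tert = diet_scores.assign_tertiles(score, pd.Series(sex, index=frame.index))
    frame["tertile"] = tert.tertile.astype(int)

    biom = simulate_biomarkers(frame, config.effects, rng, config.biomarker_params)
    frame = pd.concat([frame, biom], axis=1)
    frame.insert(0, "subject_id", [f"S{i:05d}" for i in range(1, n + 1)])

    truth = {
        "seed": config.seed,
        "n": n,
        "genotype_probs": list(config.genotype_probs),
        "interaction_score": config.interaction_score,
        "effects": _effects_as_json(config.effects),
        "tertile": frame["tertile"].tolist(),
        "dash_total": dash["dash_total"].tolist(),
        "mds_total": mds["mds_total"].tolist(),
    }
    tertile = frame.pop("tertile")
    frame["tertile"] = tertile  # keep last for readability
    return SimulatedCohort(cohort=frame, ground_truth=truth)


def _effects_as_json(effects: EffectConfig) -> dict:
    """JSON-safe effect description: (genotype, tertile) keys become 'CT:T2'."""
    raw = asdict(effects)
    raw["interaction"] = {
        resp: {f"{g}:T{t}": v for (g, t), v in cells.items()}
        for resp, cells in effects.interaction.items()
    }
    return raw


def _as_rng(rng, seed: int) -> np.random.Generator:
    if rng is None:
        return np.random.default_rng(seed)
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)
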