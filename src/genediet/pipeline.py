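"""End-to-end pipeline: cohort -> diet scores -> phenotypes -> genotypes ->
association models, with CSV table analogues and a machine-readable run
manifest.

The result bundle mirrors the study's reporting layout: cohort
descriptives, intake summary, sex-stratified tertile comparison tables,
diet-genotype odds ratios, genotype-risk odds ratios, and genotype x
diet-tertile interaction output with plot-ready adjusted cell means.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, biomarkers, cohort as cohort_mod, diet_scores, genotyping, simulate as simulate_mod

_pkg_version = "0.1.0"

log = logging.getLogger("genediet")

#: continuous responses tested for a gene x diet interaction by default
DEFAULT_INTERACTION_RESPONSES = ("tg", "glucose", "dbp")

#: binary outcomes modelled against genotype by default
DEFAULT_RISK_OUTCOMES = ("mets",) + biomarkers.RISK_FLAG_NAMES


@dataclass
class RunConfig:
    input_path: str | None = None
    simulate: dict | None = None  # SimulationConfig field overrides
    eligibility: dict = field(default_factory=dict)
    mets_ruleset: str = "atp3"
    quicki_cut: float = 0.33
    posthoc: str = "lsd"
    models: tuple[str, ...] = ("crude", "model1", "model2")
    interaction_responses: tuple[str, ...] = DEFAULT_INTERACTION_RESPONSES
    risk_outcomes: tuple[str, ...] = DEFAULT_RISK_OUTCOMES
    out_dir: str = "genediet_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.input_path is not None and self.simulate is not None:
            raise ValueError("set exactly one of input_path / simulate, not both")
        if self.mets_ruleset not in biomarkers.METS_RULESETS:
            raise ValueError(f"unknown MetS ruleset {self.mets_ruleset!r}")
        if self.posthoc not in ("lsd", "bonferroni"):
            raise ValueError(f"unknown post-hoc method {self.posthoc!r}")
        unknown = set(self.models) - set(association.MODEL_SPECS)
        if unknown:
            raise ValueError(f"unknown model spec(s): {sorted(unknown)}")


def validate_config(source) -> RunConfig:
    """Load and normalize a YAML/JSON run config (path, mapping, or None).

    Missing keys take their defaults; an empty file yields the all-default
    (simulate-mode) config.  Unknown keys and contradictory choices raise.
    """
    if source is None:
        raw = {}
    elif isinstance(source, dict):
        raw = dict(source)
    else:
        text = Path(source).read_text()
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError("run config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for key in ("models", "interaction_responses", "risk_outcomes"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def _json_safe(obj):
    """Recursively stringify mapping keys JSON cannot represent (e.g. tuples)."""
    if isinstance(obj, dict):
        return {k if isinstance(k, (str, int, float, bool)) else str(k): _json_safe(v)
                for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    return obj


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(_json_safe(dataclasses.asdict(config)), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _or_rows(results, outcome: str) -> list[dict]:
    return [
        {"outcome": outcome, "model": r.model, "contrast": r.contrast,
         "odds_ratio": r.odds_ratio, "ci_low": r.ci_low, "ci_high": r.ci_high,
         "p_value": r.p_value, "flag": r.flag}
        for r in results
    ]


def run_pipeline(config: RunConfig | str | dict | None = None) -> dict:
    """Execute every stage and write the table analogues under ``out_dir``.

    Returns the result bundle as a dict of DataFrames plus the manifest.
    """
    if not isinstance(config, RunConfig):
        config = validate_config(config)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # --- stage 1: cohort ---------------------------------------------------
    if config.input_path is not None:
        log.info("reading cohort from %s", config.input_path)
        raw = cohort_mod.read_cohort(config.input_path)
        ground_truth = None
    else:
        sim_kwargs = dict(config.simulate or {})
        sim_kwargs.setdefault("seed", config.seed)
        if "effects" in sim_kwargs and isinstance(sim_kwargs["effects"], dict):
            sim_kwargs["effects"] = simulate_mod.EffectConfig(**sim_kwargs["effects"])
        sim = simulate_mod.simulate_cohort(simulate_mod.SimulationConfig(**sim_kwargs))
        raw, ground_truth = sim.cohort, sim.ground_truth
        log.info("simulated cohort of %d subjects (seed %d)", len(raw), sim_kwargs["seed"])

    criteria = cohort_mod.EligibilityConfig(**config.eligibility)
    kept, excl = cohort_mod.apply_eligibility(raw, criteria)
    excl.to_frame().to_csv(out_dir / "exclusion_log.csv", index=True)
    log.info("eligibility: %d retained / %d input", excl.n_retained, excl.n_input)

    kept = kept.copy()
    kept["ses"] = cohort_mod.score_ses(kept)

    # --- stage 2: diet scores ----------------------------------------------
    dash = diet_scores.score_dash(kept)
    mds = diet_scores.score_mds(kept)
    kept["dash_total"] = dash["dash_total"]
    kept["mds_total"] = mds["mds_total"]
    for score in ("dash", "mds"):
        tert = diet_scores.assign_tertiles(kept[f"{score}_total"], kept["sex"])
        kept[f"{score}_tertile"] = tert.tertile
    score_table = pd.concat(
        [kept[["subject_id"]], dash, mds.add_prefix("mds_"),
         kept[["dash_tertile", "mds_tertile"]]], axis=1)
    score_table.to_csv(out_dir / "diet_scores.csv", index=False)

    # --- stage 3: phenotypes and genotypes ----------------------------------
    panel = biomarkers.phenotype_panel(kept, mets_ruleset=config.mets_ruleset,
                                       quicki_cut=config.quicki_cut)
    panel.to_csv(out_dir / "phenotype_panel.csv", index=False)
    for col in ("ldl", "aip", "homa_ir", "quicki", "sbp", "dbp", "mets",
                *biomarkers.RISK_FLAG_NAMES):
        kept[col] = panel[col]

    kept["genotype"] = genotyping.call_cohort_genotypes(kept)
    called = kept["genotype"].dropna()
    allele_stats = genotyping.genotype_frequencies(called.tolist()) if len(called) else None
    if allele_stats is not None:
        hwe_p = genotyping.hwe_exact_test(*(allele_stats.counts[g] for g in genotyping.GENOTYPES))
        (out_dir / "allele_stats.json").write_text(json.dumps({
            "counts": allele_stats.counts, "proportions": allele_stats.proportions,
            "freq_C": allele_stats.freq_c, "freq_T": allele_stats.freq_t,
            "maf": allele_stats.maf, "hwe_exact_p": hwe_p}, indent=2))

    # --- stage 4: descriptive tables ----------------------------------------
    desc_vars = ["age", "weight", "fat_mass", "fat_free_mass", "waist_circumference",
                 "sex", "physical_activity", "marital_status", "ses",
                 "ldl", "hdl", "tc", "tg", "aip", "glucose", "insulin",
                 "homa_ir", "quicki", "sbp", "dbp"]
    cohort_mod.summarize_cohort(kept, desc_vars).to_csv(out_dir / "descriptives.csv", index=False)
    intake_vars = ["energy_intake", "dash_total", "mds_total",
                   *cohort_mod.FOOD_GROUP_COLUMNS, "sodium", "mufa", "sfa"]
    cohort_mod.summarize_cohort(kept, intake_vars).to_csv(out_dir / "intake_summary.csv", index=False)

    # --- stage 5: sex-stratified tertile tables ------------------------------
    tertile_tables = []
    cont_vars = ("age", "weight", "fat_mass", "fat_free_mass", "waist_circumference",
                 "ldl", "hdl", "tc", "tg", "aip", "glucose", "insulin", "sbp", "dbp")
    cat_vars = ("physical_activity", "marital_status", "ses", "genotype")
    for sex in ("male", "female"):
        sub = kept[kept["sex"] == sex]
        for score in ("dash", "mds"):
            tab = association.tables_by_tertile(
                sub, sub[f"{score}_tertile"], continuous=cont_vars, categorical=cat_vars)
            tab.insert(0, "stratum", sex)
            tab.insert(1, "score", score)
            tertile_tables.append(tab)
    pd.concat(tertile_tables).to_csv(out_dir / "tertile_tables.csv", index=False)

    # --- stage 6: odds-ratio models ------------------------------------------
    diet_or_rows = []
    for sex in ("male", "female"):
        sub = kept[kept["sex"] == sex]
        for score in ("dash", "mds"):
            for spec in config.models:
                try:
                    res = association.fit_diet_genotype_multinomial(sub, f"{score}_total", spec)
                except Exception as exc:  # singular stratum etc.
                    log.warning("diet-genotype model failed (%s/%s/%s): %s", sex, score, spec, exc)
                    continue
                for row in _or_rows(res, f"{score}_total"):
                    row["stratum"] = sex
                    diet_or_rows.append(row)
    pd.DataFrame(diet_or_rows).to_csv(out_dir / "diet_genotype_or.csv", index=False)

    risk_or_rows = []
    for outcome in config.risk_outcomes:
        for spec in config.models:
            try:
                res = association.fit_genotype_outcome_or(kept, outcome, spec)
            except Exception as exc:
                log.warning("genotype-risk model failed (%s/%s): %s", outcome, spec, exc)
                continue
            risk_or_rows.extend(_or_rows(res, outcome))
    pd.DataFrame(risk_or_rows).to_csv(out_dir / "genotype_risk_or.csv", index=False)

    # --- stage 7: gene x diet interactions -----------------------------------
    inter_rows, cell_rows, posthoc_rows = [], [], []
    for sex in ("male", "female"):
        sub = kept[kept["sex"] == sex]
        for score in ("dash", "mds"):
            sub_t = sub.drop(columns=["tertile"], errors="ignore").rename(
                columns={f"{score}_tertile": "tertile"})
            for response in config.interaction_responses:
                try:
                    res = association.ancova_interaction(
                        sub_t, response, stratum=sex, tertile_col="tertile")
                except Exception as exc:
                    log.warning("interaction failed (%s/%s/%s): %s", sex, score, response, exc)
                    continue
                inter_rows.append({
                    "stratum": sex, "score": score, "response": response,
                    "f_statistic": res.f_statistic, "p_interaction": res.p_interaction,
                    "df_num": res.df_num, "df_den": res.df_den, "flag": res.flag})
                cells = res.cell_means.copy()
                cells.insert(0, "stratum", sex)
                cells.insert(1, "score", score)
                cells.insert(2, "response", response)
                cell_rows.append(cells)
                if np.isfinite(res.p_interaction):
                    ph = association.posthoc_cell_comparisons(res, method=config.posthoc)
                    ph.insert(0, "stratum", sex)
                    ph.insert(1, "score", score)
                    ph.insert(2, "response", response)
                    posthoc_rows.append(ph)
    interactions = pd.DataFrame(inter_rows)
    interactions.to_csv(out_dir / "interactions.csv", index=False)
    if cell_rows:
        pd.concat(cell_rows).to_csv(out_dir / "interaction_cell_means.csv", index=False)
    if posthoc_rows:
        pd.concat(posthoc_rows).to_csv(out_dir / "posthoc_contrasts.csv", index=False)

    manifest = {
        "package_version": _pkg_version,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_input": excl.n_input,
        "n_retained": excl.n_retained,
        "config": _json_safe(dataclasses.asdict(config)),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    if ground_truth is not None:
        (out_dir / "ground_truth.json").write_text(json.dumps(ground_truth, indent=2))

    return {
        "cohort": kept,
        "exclusion_log": excl,
        "allele_stats": allele_stats,
        "interactions": interactions,
        "diet_genotype_or": pd.DataFrame(diet_or_rows),
        "genotype_risk_or": pd.DataFrame(risk_or_rows),
        "manifest": manifest,
    }
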