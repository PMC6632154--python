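"""End-to-end staged estimation: participation weights -> stage models -> curves.

`fit_staged` runs the whole estimator on an observed record frame:

1. fit per-stage participation logistics (enrollment on everyone contacted,
   amyloid PET among the enrolled, tau PET among amyloid-PET participants);
2. assemble the three nested cohorts and their IPW weights;
3. fit the weighted clinical multinomial and the conditional amyloid / tau
   models;
4. expose combined prevalence curves for any entity, sex and age grid.

`run_pipeline` is the config-driven driver behind the CLI: it simulates or
loads a cohort, fits, jackknifes, runs comparisons and sensitivity variants,
and writes `prevalence.csv`, `comparisons.csv`, `sensitivity.csv` and a
`run.json` provenance record to an output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import assemble_nested_cohorts, read_cohort, validate_records
from .combine import DEFAULT_AGES, ENTITIES, PrevalenceCurve, combined_prevalence, sex_difference_curve
from .jackknife import JackknifeSpec, curve_difference_test, jackknife_ci
from .models import (
    DEFAULT_CLINICAL_TERMS,
    DEFAULT_CONDITIONAL_TERMS,
    CutpointConfig,
    fit_clinical_multinomial,
    fit_conditional_model,
)
from .sensitivity import SensitivityVariant, matched_roi_variant, recalibrate_cutpoint
from .synth import default_params, generate_population, simulate_observation
from .weights import DEFAULT_PARTICIPATION_TERMS, compute_weights, fit_participation_model

log = logging.getLogger("adprev")


@dataclass
class PipelineConfig:
    """Everything the staged fit needs beyond the data."""

    cutpoints: CutpointConfig = field(default_factory=CutpointConfig)
    clinical_terms: tuple = DEFAULT_CLINICAL_TERMS
    conditional_terms: tuple = DEFAULT_CONDITIONAL_TERMS
    participation_terms: tuple = DEFAULT_PARTICIPATION_TERMS
    #: apply inverse-probability-of-participation weights (stratum weights
    #: always apply); False gives the naive participants-only estimator
    use_ipw: bool = True
    truncate_percentile: float | None = 99.0
    passive_complete: bool | None = None
    min_group_n: int = 25


@dataclass
class StagedFit:
    """Fitted participation models, weighted cohorts and stage models."""

    config: PipelineConfig
    participation: dict
    clinical_sample: object
    amyloid_sample: object
    tau_sample: object
    clinical_model: object
    amyloid_model: object
    tau_model: object

    def curve(self, entity: str, sex: str, ages=DEFAULT_AGES) -> PrevalenceCurve:
        c = combined_prevalence(self.clinical_model, self.amyloid_model,
                                self.tau_model, entity, sex, ages)
        c.provenance.update({
            "cutpoints": vars(self.config.cutpoints).copy(),
            "ipw": self.config.use_ipw,
        })
        return c

    def population_age_weights(self, ages=DEFAULT_AGES, sex: str | None = None) -> np.ndarray:
        """Estimated population age distribution on the grid (from the weighted
        clinical sample), normalized to sum to 1; used to aggregate curves."""
        ages = np.asarray(ages)
        rec, w = self.clinical_sample.records, self.clinical_sample.weights
        keep = np.ones(len(rec), dtype=bool) if sex is None else (rec["sex"] == sex).to_numpy()
        a = rec["age"].to_numpy()[keep]
        ww = np.asarray(w)[keep]
        out = np.array([ww[a == age].sum() for age in ages], dtype=float)
        if out.sum() == 0:
            return np.full(ages.size, 1.0 / ages.size)
        return out / out.sum()


def _stage_frames(records: pd.DataFrame):
    """(frame, participated) pairs defining each participation-stage fit."""
    contacted = records[records["ascertainment"] != "excluded"]
    enrolled_flag = contacted["enrolled"].astype(bool).to_numpy()
    enrolled = contacted[enrolled_flag]
    amy_flag = enrolled["has_amyloid_pet"].astype(bool).to_numpy()
    amy = enrolled[amy_flag]
    tau_flag = amy["has_tau_pet"].astype(bool).to_numpy()
    return {
        "enroll": (contacted, enrolled_flag),
        "amyloid_pet": (enrolled, amy_flag),
        "tau_pet": (amy, tau_flag),
    }


def fit_staged(records: pd.DataFrame, config: PipelineConfig | None = None) -> StagedFit:
    """Fit the full staged estimator on a validated observed record frame."""
    config = config or PipelineConfig()
    validate_records(records)
    cohorts = assemble_nested_cohorts(records)

    participation = {}
    for stage, (frame, flag) in _stage_frames(records).items():
        if config.use_ipw:
            participation[stage] = fit_participation_model(
                frame, stage, flag, terms=config.participation_terms)
        else:
            participation[stage] = fit_participation_model(
                frame, stage, np.ones(len(frame)), terms=config.participation_terms)

    clinical_sample = compute_weights(participation, cohorts.clinical, "enroll",
                                      config.truncate_percentile, config.passive_complete)
    amyloid_sample = compute_weights(participation, cohorts.amyloid, "amyloid_pet",
                                     config.truncate_percentile)
    tau_sample = compute_weights(participation, cohorts.tau, "tau_pet",
                                 config.truncate_percentile)

    clinical_model = fit_clinical_multinomial(clinical_sample, config.clinical_terms)
    amyloid_model = fit_conditional_model(amyloid_sample, "A", config.cutpoints,
                                          config.conditional_terms, config.min_group_n)
    tau_model = fit_conditional_model(tau_sample, "T", config.cutpoints,
                                      config.conditional_terms, config.min_group_n)
    return StagedFit(config=config, participation=participation,
                     clinical_sample=clinical_sample, amyloid_sample=amyloid_sample,
                     tau_sample=tau_sample, clinical_model=clinical_model,
                     amyloid_model=amyloid_model, tau_model=tau_model)


def curve_refitter(config: PipelineConfig, targets, ages):
    """Functional for the jackknife: records -> {(entity, sex): estimates}."""

    def refit(records):
        fit = fit_staged(records, config)
        return {(e, s): fit.curve(e, s, ages).estimates for (e, s) in targets}

    return refit


# ---------------------------------------------------------------------------
# config-driven run


DEFAULT_RUN_CONFIG = {
    "seed": 0,
    "simulate": {"n": 20000},
    "input": None,
    "ages": {"start": 60, "stop": 90},
    "entities": list(ENTITIES),
    "sexes": ["female", "male"],
    "cutpoints": {},
    "jackknife": {"groups": 10},
    "comparisons": [["A_plus", "male", "A_plus", "female"]],
    "sensitivity": {"tau_rois": ["entorhinal", "inferior_temporal", "lateral_parietal"],
                    "cu_fraction_deltas": [0.10, -0.10]},
    "ipw": True,
    "truncate_percentile": 99.0,
}


class ConfigError(ValueError):
    pass


def load_run_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        user = path_or_dict
    else:
        with open(path_or_dict, "r", encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULT_RUN_CONFIG))
    for key, value in user.items():
        if key not in DEFAULT_RUN_CONFIG:
            raise ConfigError(f"unknown config key {key!r}")
        if isinstance(DEFAULT_RUN_CONFIG[key], dict) and isinstance(value, dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    bad = [e for e in cfg["entities"] if e not in ENTITIES]
    if bad:
        raise ConfigError(f"unknown entity in config key 'entities': {bad}")
    return cfg


def run_pipeline(config, out_dir, seed: int | None = None) -> dict:
    """Run the configured analysis end to end and write the result bundle.

    Returns a dict with the curves, comparison table, sensitivity tables and
    warning count.  Deterministic given config + seed.
    """
    from pathlib import Path

    t0 = time.time()
    cfg = load_run_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings_count = 0

    if cfg["input"]:
        records = read_cohort(cfg["input"])
        log.info("loaded %d records from %s", len(records), cfg["input"])
    else:
        params = default_params()
        pop = generate_population(params, int(cfg["simulate"]["n"]), seed=cfg["seed"])
        records = simulate_observation(pop, params, seed=cfg["seed"] + 1)
        log.info("simulated population n=%d -> observed frame n=%d",
                 len(pop), len(records))

    ages = np.arange(int(cfg["ages"]["start"]), int(cfg["ages"]["stop"]) + 1)
    cutpoints = CutpointConfig(**cfg["cutpoints"])
    pcfg = PipelineConfig(cutpoints=cutpoints, use_ipw=bool(cfg["ipw"]),
                          truncate_percentile=cfg["truncate_percentile"])

    targets = [(e, s) for e in cfg["entities"] for s in cfg["sexes"]]
    spec = JackknifeSpec(n_groups=int(cfg["jackknife"]["groups"]), seed=cfg["seed"])
    refit = curve_refitter(pcfg, targets, ages)
    curves, replicates = jackknife_ci(records, refit, spec, targets, ages)
    fit = fit_staged(records, pcfg)

    prev = pd.concat([curves[t].to_frame() for t in targets], ignore_index=True)
    prev.to_csv(out / "prevalence.csv", index=False)

    comp_rows = []
    for comparison in cfg["comparisons"]:
        ea, sa, eb, sb = comparison
        if (ea, sa) not in curves or (eb, sb) not in curves:
            log.warning("comparison %s skipped: curve not computed", comparison)
            warnings_count += 1
            continue
        age_w = fit.population_age_weights(ages)
        res = curve_difference_test(curves[(ea, sa)], curves[(eb, sb)],
                                    replicates[(ea, sa)], replicates[(eb, sb)], age_w,
                                    df=spec.n_groups - 1)
        comp_rows.append({"entity_a": ea, "sex_a": sa, "entity_b": eb, "sex_b": sb,
                          "statistic": res["statistic"], "se": res["se"],
                          "z": res["z"], "p_value": res["p_value"]})
    pd.DataFrame(comp_rows).to_csv(out / "comparisons.csv", index=False)

    sens_table = run_configured_sensitivity(records, fit, pcfg, cfg, ages)
    sens_table.to_csv(out / "sensitivity.csv", index=False)

    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode("utf-8")).hexdigest()
    provenance = {
        "config": cfg, "config_sha256": cfg_hash, "seed": cfg["seed"],
        "package_version": __version__,
        "numpy": np.__version__, "pandas": pd.__version__,
        "elapsed_s": round(time.time() - t0, 2),
        "warnings": warnings_count,
    }
    with open(out / "run.json", "w", encoding="utf-8") as fh:
        json.dump(provenance, fh, indent=2)
    log.info("wrote results to %s (%.1fs, %d warnings)", out,
             time.time() - t0, warnings_count)
    return {"curves": curves, "replicates": replicates,
            "comparisons": pd.DataFrame(comp_rows), "sensitivity": sens_table,
            "provenance": provenance, "fit": fit, "records": records,
            "warnings": warnings_count}


def run_configured_sensitivity(records, fit: StagedFit, pcfg: PipelineConfig,
                               cfg: dict, ages) -> pd.DataFrame:
    """Build the variant list from config and run the sensitivity suite."""
    from .sensitivity import run_sensitivity_suite

    primary = pcfg.cutpoints
    variants = [SensitivityVariant("primary", primary)]

    tau_rec = fit.tau_sample.records
    tau_w = np.asarray(fit.tau_sample.weights)
    cu = (tau_rec["clinical_status"] == "CU").to_numpy()
    primary_cu = tau_rec[primary.tau_column].to_numpy()[cu]
    for roi in cfg["sensitivity"].get("tau_rois", []):
        col = f"tau_suvr_{roi}"
        if col not in tau_rec.columns or tau_rec[col].notna().sum() == 0:
            continue
        alt_cu = tau_rec[col].to_numpy()[cu]
        variants.append(matched_roi_variant(f"tau_roi_{roi}", roi, primary,
                                            primary_cu, alt_cu, tau_w[cu]))

    amy_rec = fit.amyloid_sample.records
    amy_w = np.asarray(fit.amyloid_sample.weights)
    amy_cu = (amy_rec["clinical_status"] == "CU").to_numpy()
    for delta in cfg["sensitivity"].get("cu_fraction_deltas", []):
        # recalibrate each modality independently; a modality whose shifted
        # CU-abnormal target is not a probability (e.g. CU tau abnormality
        # below 10% under delta = -0.10) keeps its primary cut, with a warning
        cuts = {"amyloid_cutpoint": primary.amyloid_cutpoint,
                "tau_cutpoint": primary.tau_cutpoint}
        feasible = False
        for key, values, wts, base in (
                ("amyloid_cutpoint", amy_rec["amyloid_suvr"].to_numpy()[amy_cu],
                 amy_w[amy_cu], primary.amyloid_cutpoint),
                ("tau_cutpoint", primary_cu, tau_w[cu], primary.tau_cutpoint)):
            try:
                cuts[key] = recalibrate_cutpoint(values, base, delta, wts)
                feasible = True
            except ValueError as err:
                log.warning("cut-point variant delta=%+.2f: %s unchanged (%s)",
                            delta, key, err)
        if not feasible:
            log.warning("cut-point variant delta=%+.2f skipped entirely", delta)
            continue
        variants.append(SensitivityVariant(f"cu_fraction_{delta:+.2f}",
                                           replace(primary, **cuts)))

    def fit_fn(recs, cutpoints):
        sfit = fit_staged(recs, replace(pcfg, cutpoints=cutpoints))
        return {(e, s): sfit.curve(e, s, ages).estimates
                for e in cfg["entities"] for s in cfg["sexes"]}

    table, summary = run_sensitivity_suite(fit_fn, records, variants,
                                           cfg["entities"], cfg["sexes"], ages)
    if not summary.empty:
        table = table.merge(summary, on="variant", how="left")
    return table


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(stream=sys.stderr, level=getattr(logging, level.upper()),
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
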