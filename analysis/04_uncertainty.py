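#!/usr/bin/env python
"""Jackknife confidence bands and curve-comparison tests.

Runs the delete-a-group (G = 10) jackknife around the full staged pipeline on
a simulated cohort, writes prevalence curves with 95% bands, and tests the
male-female difference for each entity.

Finding: with the default generator (higher MCI logit in men), the
MCI-or-dementia curves differ significantly between sexes while the A+ curves
do not — the same qualitative pattern the estimator is designed to resolve.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from adprev.jackknife import JackknifeSpec, curve_difference_test, jackknife_ci
from adprev.pipeline import PipelineConfig, curve_refitter, fit_staged
from adprev.synth import default_params, generate_population, simulate_observation

RESULTS = Path(__file__).resolve().parents[1] / "results"
AGES = np.arange(60, 91)
ENTITIES = ["A_plus", "A_plus_T_minus", "A_plus_T_plus",
            "MCI_or_dementia", "dementia", "probable_AD"]


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    params = default_params()
    pop = generate_population(params, 30_000, seed=0)
    obs = simulate_observation(pop, params, seed=1)

    targets = [(e, s) for e in ENTITIES for s in ("female", "male")]
    spec = JackknifeSpec(n_groups=10, seed=0)
    refit = curve_refitter(PipelineConfig(), targets, AGES)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        curves, reps = jackknife_ci(obs, refit, spec, targets, AGES)
        fit = fit_staged(obs, PipelineConfig())

    pd.concat([curves[t].to_frame() for t in targets], ignore_index=True).to_csv(
        RESULTS / "prevalence_with_ci.csv", index=False)

    age_w = fit.population_age_weights(AGES)
    rows = []
    for entity in ENTITIES:
        res = curve_difference_test(curves[(entity, "male")], curves[(entity, "female")],
                                    reps[(entity, "male")], reps[(entity, "female")],
                                    age_w, df=spec.n_groups - 1)
        rows.append({"entity": entity, "men_minus_women": res["statistic"],
                     "se": res["se"], "p_value": res["p_value"]})
    comp = pd.DataFrame(rows)
    comp.to_csv(RESULTS / "sex_comparisons.csv", index=False)
    print(comp.round(4).to_string(index=False))
    sig = comp[comp["p_value"] < 0.05]["entity"].tolist()
    print(f"\nEntities with a significant (P < .05) sex difference: {sig or 'none'}")


if __name__ == "__main__":
    main()
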