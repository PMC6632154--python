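#!/usr/bin/env python
"""Fit the staged IPW estimator and compare it with truth and the naive fit.

On the simulated default scenario (n = 100 000), fits the participation
models, the weighted clinical multinomial and the conditional amyloid/tau
models, combines them by total probability, and tabulates the estimated
prevalence of every entity against the generating values — with and without
inverse probability weighting.

Finding: the naive participants-only estimate of Alzheimer-continuum (A+)
prevalence is ~4-5 percentage points too low at age 75 (healthier, better
educated participants), while the IPW estimate is within a point of truth.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from adprev.combine import ENTITIES
from adprev.pipeline import PipelineConfig, fit_staged
from adprev.synth import default_params, generate_population, simulate_observation, true_prevalence

RESULTS = Path(__file__).resolve().parents[1] / "results"
AGES = np.arange(60, 91)
KEY_AGES = [65, 70, 75, 80, 85]


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    params = default_params()
    pop = generate_population(params, 100_000, seed=0)
    obs = simulate_observation(pop, params, seed=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit_w = fit_staged(obs, PipelineConfig(use_ipw=True))
        fit_u = fit_staged(obs, PipelineConfig(use_ipw=False))

    rows = []
    for entity in ENTITIES:
        for sex in ("female", "male"):
            truth = true_prevalence(params, entity, sex, AGES)
            ipw = fit_w.curve(entity, sex, AGES).estimates
            naive = fit_u.curve(entity, sex, AGES).estimates
            for age, t, w, u in zip(AGES, truth, ipw, naive):
                rows.append({"entity": entity, "sex": sex, "age": int(age),
                             "truth": t, "ipw": w, "naive": u})
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "prevalence_vs_truth.csv", index=False)

    key = table[table["age"].isin(KEY_AGES) & (table["entity"] == "A_plus")].copy()
    key["ipw_err_pct"] = 100 * (key["ipw"] - key["truth"])
    key["naive_err_pct"] = 100 * (key["naive"] - key["truth"])
    print(key.round(3).to_string(index=False))
    at75 = key[key["age"] == 75]
    print(f"\nA+ at 75: naive error {at75['naive_err_pct'].mean():+.1f} points, "
          f"IPW error {at75['ipw_err_pct'].mean():+.1f} points "
          "(averaged over sexes).")


if __name__ == "__main__":
    main()
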