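#!/usr/bin/env python
"""Tau-ROI and cut-point sensitivity analyses.

Re-runs the staged pipeline with tau positivity defined on each alternative
ROI channel (cut points matched on CU specificity) and with amyloid/tau cut
points recalibrated so that 10% more or fewer CU participants are abnormal.

Finding: alternative tau ROIs move the A+T+ curves by at most a few points
(the channels share one latent tau state), while the +/-10-point CU
recalibration moves population A+ prevalence by roughly the expected
10 points.
"""

import warnings
from pathlib import Path

import numpy as np

from adprev.pipeline import (
    PipelineConfig,
    fit_staged,
    run_configured_sensitivity,
    DEFAULT_RUN_CONFIG,
)
from adprev.synth import default_params, generate_population, simulate_observation

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    params = default_params()
    pop = generate_population(params, 50_000, seed=0)
    obs = simulate_observation(pop, params, seed=1)
    cfg = dict(DEFAULT_RUN_CONFIG)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_staged(obs, PipelineConfig())
        table = run_configured_sensitivity(obs, fit, PipelineConfig(), cfg,
                                           np.arange(60, 91))
    table.to_csv(RESULTS / "sensitivity.csv", index=False)
    summary = (table.groupby("variant")
               .agg(max_abs_deviation=("max_abs_deviation", "first"),
                    tau_cut=("tau_cutpoint", "first"),
                    amyloid_cut=("amyloid_cutpoint", "first")))
    print(summary.round(4).to_string())
    print("\nDeviation is measured against the primary configuration "
          "(temporal meta-ROI, amyloid 1.48 / tau 1.25).")


if __name__ == "__main__":
    main()
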