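"""Sensitivity analyses: alternative tau ROI channels and cut-point recalibration.

Two families of variants are supported, mirroring the primary analysis:

* **alternative tau ROIs** — re-run the staged pipeline with tau positivity
  defined on the entorhinal, inferior temporal or lateral parietal channel
  instead of the temporal meta-ROI.  No published per-ROI cut points exist,
  so each alternative channel's cut point is set by matching the primary
  channel's abnormal fraction among (IPW-weighted) cognitively unimpaired
  participants — the least-assumption choice, recorded in the output
  metadata;
* **cut-point recalibration** — shift the amyloid and/or tau cut point so
  that 10% more or 10% fewer cognitively unimpaired individuals are
  classified abnormal, and re-run the pipeline.

Both reduce to empirical-quantile computations on a weighted CU reference
distribution followed by a full pipeline re-run per variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .models import CutpointConfig


def abnormal_fraction(values, cutpoint: float, weights=None) -> float:
    """Weighted fraction of values classified abnormal (>= cut point)."""
    v = np.asarray(values, dtype=float)
    keep = ~np.isnan(v)
    v = v[keep]
    w = np.ones(v.size) if weights is None else np.asarray(weights, dtype=float)[keep]
    if v.size == 0:
        raise ValueError("no reference values")
    return float(w[v >= cutpoint].sum() / w.sum())


def cutpoint_for_fraction(values, target_fraction: float, weights=None) -> float:
    """Empirical cut point whose abnormal fraction is nearest the target.

    Scans every achievable cut (the observed values, plus one above the
    maximum for fraction 0) and returns the one whose weighted >=-fraction is
    closest to *target_fraction*; ties prefer the higher cut point, which
    makes the returned cut monotone non-increasing in the target.
    """
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError("target fraction must lie in [0, 1]")
    v = np.asarray(values, dtype=float)
    keep = ~np.isnan(v)
    v = v[keep]
    if v.size == 0:
        raise ValueError("no reference values")
    w = np.ones(v.size) if weights is None else np.asarray(weights, dtype=float)[keep]

    order = np.argsort(v)[::-1]          # descending
    vs, ws = v[order], w[order]
    total = ws.sum()
    cum = np.cumsum(ws) / total
    # candidate cut = vs[i] achieves fraction cum at the last duplicate of vs[i]
    uniq, last_idx = np.unique(vs[::-1], return_index=True)
    uniq = uniq[::-1]                     # descending unique values
    last = vs.size - 1 - last_idx[::-1]   # last position of each unique value
    fracs = cum[last]
    cand_cuts = np.concatenate([[np.nextafter(vs[0], np.inf)], uniq])
    cand_fracs = np.concatenate([[0.0], fracs])
    err = np.abs(cand_fracs - target_fraction)
    best = int(np.argmin(err))            # argmin takes the first (higher cut) on ties
    return float(cand_cuts[best])


def recalibrate_cutpoint(reference_values, baseline_cut: float, delta: float,
                         weights=None) -> float:
    """Shift a cut point so the reference abnormal fraction changes by *delta*.

    *reference_values* is the (weighted) CU SUVR distribution of the relevant
    imaging cohort; ``delta=+0.10`` returns the cut at which 10 percentage
    points more of the reference distribution is abnormal, to the resolution
    the empirical distribution allows.
    """
    base = abnormal_fraction(reference_values, baseline_cut, weights)
    target = base + delta
    if not 0.0 <= target <= 1.0:
        raise ValueError(f"target abnormal fraction {target:.3f} outside [0, 1]")
    return cutpoint_for_fraction(reference_values, target, weights)


@dataclass
class SensitivityVariant:
    """A named cut-point configuration to re-run the pipeline under."""

    name: str
    cutpoints: CutpointConfig


def matched_roi_variant(name: str, roi: str, primary: CutpointConfig,
                        primary_cu_values, alternative_cu_values,
                        cu_weights=None) -> SensitivityVariant:
    """Variant using an alternative tau ROI, cut matched on CU specificity.

    The primary channel's abnormal fraction among (weighted) CU tau-PET
    participants is computed from *primary_cu_values*, and the alternative
    channel's cut point is the empirical quantile of *alternative_cu_values*
    reproducing that fraction.
    """
    target = abnormal_fraction(primary_cu_values, primary.tau_cutpoint, cu_weights)
    cut = cutpoint_for_fraction(alternative_cu_values, target, cu_weights)
    return SensitivityVariant(name=name,
                              cutpoints=replace(primary, tau_roi=roi, tau_cutpoint=cut))


def run_sensitivity_suite(fit_fn, records, variants: list[SensitivityVariant],
                          entities, sexes, ages) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-run the staged pipeline per variant and tabulate prevalence curves.

    Parameters
    ----------
    fit_fn
        ``fit_fn(records, cutpoints) -> {(entity, sex): estimates}`` running
        the full staged pipeline under a cut-point configuration.
    variants
        The first variant is treated as the primary configuration for the
        deviation summary.  A variant whose tau channel is absent from the
        data is skipped with a warning; the run continues.

    Returns
    -------
    (table, summary)
        ``table`` has one row per (variant, entity, sex, age);
        ``summary`` the maximum absolute deviation from the primary
        configuration per variant.
    """
    ages = np.asarray(ages)
    rows = []
    results: dict[str, dict] = {}
    for variant in variants:
        col = variant.cutpoints.tau_column
        if col not in records.columns or records[col].notna().sum() == 0:
            warnings.warn(f"variant {variant.name!r}: tau channel "
                          f"{variant.cutpoints.tau_roi!r} unavailable; skipped",
                          stacklevel=2)
            continue
        est = fit_fn(records, variant.cutpoints)
        results[variant.name] = est
        for entity in entities:
            for sex in sexes:
                for age, value in zip(ages, est[(entity, sex)]):
                    rows.append({"variant": variant.name, "entity": entity,
                                 "sex": sex, "age": int(age), "estimate": value,
                                 "amyloid_cutpoint": variant.cutpoints.amyloid_cutpoint,
                                 "tau_cutpoint": variant.cutpoints.tau_cutpoint,
                                 "tau_roi": variant.cutpoints.tau_roi})
    table = pd.DataFrame(rows)
    if not results:
        return table, pd.DataFrame(columns=["variant", "max_abs_deviation"])

    primary_name = next(iter(results))
    primary = results[primary_name]
    summary_rows = []
    for name, est in results.items():
        dev = max(float(np.max(np.abs(np.asarray(est[key]) - np.asarray(primary[key]))))
                  for key in primary)
        summary_rows.append({"variant": name, "max_abs_deviation": dev})
    return table, pd.DataFrame(summary_rows)
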