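"""Delete-a-group jackknife confidence bands and curve-comparison tests.

Uncertainty in the staged estimator comes from every stage at once —
participation models, stratum weights, the multinomial clinical fit and the
conditional biomarker fits — so the variance estimator re-fits the *entire*
pipeline.  The data are partitioned once into G random groups (assigned on
the full observed frame so that the nested subcohorts inherit membership);
for each left-out group the pipeline is re-fitted on the remainder, giving
replicates theta_(g), and

    var_jk = (G - 1) / G * sum_g (theta_(g) - theta_bar)^2 .

With G = n this is the classical delete-1 jackknife (for a sample mean it
reproduces s^2/n exactly).  Confidence bands for prevalence estimates are
formed on the logit scale and back-transformed so they respect [0, 1]; at
point estimates of exactly 0 or 1 the band falls back to the linear scale
with clipping (flagged in the curve provenance).

Two curves are compared by a scalar summary — the average pointwise
difference over the age grid, weighted by the estimated population age
distribution — studentized by its jackknife standard error against a normal
reference.  The summary statistic is this package's concretization of a
curve-level test; it is documented as such in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit
from scipy.stats import norm, t as t_dist

from .combine import PrevalenceCurve

_EPS = 1e-12


@dataclass
class JackknifeSpec:
    """Grouping and confidence-level configuration for the jackknife."""

    n_groups: int = 10
    seed: int = 0
    ci_level: float = 0.95

    def __post_init__(self):
        if self.n_groups < 2:
            raise ValueError("need at least 2 jackknife groups")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")


def assign_groups(n: int, n_groups: int, seed: int = 0) -> np.ndarray:
    """Random near-equal-size group labels 0..G-1 for n items (seeded)."""
    if n_groups > n:
        raise ValueError("more groups than items")
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % n_groups
    return labels[rng.permutation(n)]


def jackknife_variance(replicates: np.ndarray, axis: int = 0) -> np.ndarray:
    """Delete-a-group jackknife variance from the replicate estimates."""
    reps = np.asarray(replicates, dtype=float)
    g = reps.shape[axis]
    mean = reps.mean(axis=axis, keepdims=True)
    return (g - 1) / g * np.sum((reps - mean) ** 2, axis=axis)


def grouped_jackknife(statistic, items: np.ndarray, n_groups: int | None = None,
                      seed: int = 0) -> tuple[np.ndarray, float]:
    """Generic delete-a-group jackknife of ``statistic(remaining_items)``.

    With ``n_groups=None`` (or == len(items)) this is the delete-1 jackknife.
    Returns (replicates, standard error).
    """
    items = np.asarray(items)
    n = len(items)
    g = n if n_groups is None else n_groups
    labels = assign_groups(n, g, seed)
    reps = np.asarray([statistic(items[labels != k]) for k in range(g)], dtype=float)
    return reps, float(np.sqrt(jackknife_variance(reps)))


def jackknife_ci(records, refit_fn, spec: JackknifeSpec,
                 targets: list[tuple[str, str]], ages) -> tuple[dict, dict]:
    """Jackknife confidence bands for combined prevalence curves.

    Parameters
    ----------
    records
        The full observed frame (participants and nonparticipants); groups
        partition it and subcohorts inherit membership.
    refit_fn
        ``refit_fn(records_subset) -> {(entity, sex): estimates array}`` —
        runs the entire staged pipeline (weights + stage models +
        combination) and evaluates every target curve on *ages*.
    targets
        List of (entity, sex) pairs to evaluate.

    Returns
    -------
    (curves, replicates)
        ``curves`` maps (entity, sex) to a PrevalenceCurve with CI bounds;
        ``replicates`` maps (entity, sex) to the (G_eff, n_ages) replicate
        matrix, for downstream curve-comparison tests.
    """
    ages = np.asarray(ages)
    n = len(records)
    labels = assign_groups(n, spec.n_groups, spec.seed)

    point = refit_fn(records)
    reps: dict[tuple[str, str], list[np.ndarray]] = {t: [] for t in targets}
    failures = 0
    for k in range(spec.n_groups):
        subset = records[labels != k]
        try:
            est = refit_fn(subset)
        except Exception:  # noqa: BLE001 — replicate failures are counted, not fatal
            failures += 1
            continue
        for t in targets:
            reps[t].append(est[t])
    if failures > 0.2 * spec.n_groups:
        raise RuntimeError(
            f"{failures}/{spec.n_groups} jackknife replicates failed to fit")

    # the jackknife SE is estimated with ~G-1 degrees of freedom, so the
    # interval uses a t quantile (survey-resampling convention), not a normal
    g_eff = spec.n_groups - failures
    zq = t_dist.ppf(0.5 + spec.ci_level / 2, df=max(g_eff - 1, 1))
    curves: dict[tuple[str, str], PrevalenceCurve] = {}
    replicates: dict[tuple[str, str], np.ndarray] = {}
    for (entity, sex) in targets:
        rep = np.asarray(reps[(entity, sex)])
        replicates[(entity, sex)] = rep
        theta = np.asarray(point[(entity, sex)], dtype=float)
        lower, upper, flagged = _ci_bounds(theta, rep, zq)
        curves[(entity, sex)] = PrevalenceCurve(
            entity=entity, sex=sex, ages=ages, estimates=theta,
            lower=lower, upper=upper,
            provenance={"n_groups": spec.n_groups, "failed_replicates": failures,
                        "ci_level": spec.ci_level, "linear_scale_fallback": flagged})
    return curves, replicates


def _ci_bounds(theta, rep, zq):
    """Logit-scale CI; linear-scale fallback (clipped, flagged) at 0/1 estimates."""
    interior = (theta > 0.0) & (theta < 1.0)
    lower = np.empty_like(theta)
    upper = np.empty_like(theta)

    rep_clipped = np.clip(rep, _EPS, 1 - _EPS)
    se_logit = np.sqrt(jackknife_variance(logit(rep_clipped), axis=0))
    t_logit = logit(np.clip(theta, _EPS, 1 - _EPS))
    lower[interior] = expit(t_logit - zq * se_logit)[interior]
    upper[interior] = expit(t_logit + zq * se_logit)[interior]

    flagged = bool((~interior).any())
    if flagged:
        se_lin = np.sqrt(jackknife_variance(rep, axis=0))
        lower[~interior] = np.clip(theta - zq * se_lin, 0.0, 1.0)[~interior]
        upper[~interior] = np.clip(theta + zq * se_lin, 0.0, 1.0)[~interior]
    return lower, upper, flagged


def curve_difference_test(curve_a: PrevalenceCurve, curve_b: PrevalenceCurve,
                          replicates_a: np.ndarray, replicates_b: np.ndarray,
                          age_weights: np.ndarray | None = None,
                          df: int | None = None) -> dict:
    """Test whether two prevalence curves differ.

    The scalar summary is the average pointwise difference over the common
    age grid, weighted by *age_weights* (the estimated population age
    distribution; uniform if None).  The summary is studentized by its
    delete-a-group jackknife SE (replicates must come from the same group
    assignment) and referred two-sided to a standard normal, or to a
    Student t with *df* degrees of freedom when given (G - 1 is the
    calibrated choice for a G-group jackknife SE).
    """
    if curve_a.ages.shape != curve_b.ages.shape or (curve_a.ages != curve_b.ages).any():
        raise ValueError("curves must share an age grid")
    ra, rb = np.asarray(replicates_a, dtype=float), np.asarray(replicates_b, dtype=float)
    if ra.shape != rb.shape:
        raise ValueError("replicate matrices must share group assignment and grid")
    w = (np.full(curve_a.ages.size, 1.0 / curve_a.ages.size)
         if age_weights is None else np.asarray(age_weights, dtype=float))
    if w.shape != curve_a.ages.shape:
        raise ValueError("age_weights must align with the age grid")
    w = w / w.sum()

    d_hat = float(np.sum(w * (curve_a.estimates - curve_b.estimates)))
    d_reps = (ra - rb) @ w
    se = float(np.sqrt(jackknife_variance(d_reps)))
    if se == 0.0:
        if d_hat == 0.0:
            return {"statistic": 0.0, "se": 0.0, "z": 0.0, "p_value": 1.0,
                    "degenerate": False}
        return {"statistic": d_hat, "se": 0.0, "z": np.inf * np.sign(d_hat),
                "p_value": 5e-324, "degenerate": True}
    z = d_hat / se
    p = float(2 * (norm.sf(abs(z)) if df is None else t_dist.sf(abs(z), df)))
    return {"statistic": d_hat, "se": se, "z": z, "p_value": p, "degenerate": False}
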