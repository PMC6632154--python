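"""Per-stage participation models and inverse-probability-of-participation weights.

Participation in each stage of the study (initial enrollment, amyloid PET,
tau PET) is modelled by a separate logistic regression on sex, age (linear +
quadratic) and education category — the three factors identified as the main
determinants of participation.  Fitted probabilities become inverse
probability weights: a participant in stage k carries

    weight = stratum_weight * prod_{s <= k} 1 / p_hat_s ,

where ``stratum_weight`` is the inverse sampling fraction of the person's
10-year age x sex stratum.  Weights are truncated at a configurable
percentile (default 99th) to stabilize the small late-stage models.

Dementia cases are a special case: when passive medical-record surveillance
of nonparticipants is treated as complete (the default whenever passive
records are present), every dementia case in the sampled strata is observed —
actively or passively — so dementia records enter the clinical-status model
with the stratum weight only.  Weighting active dementia cases by 1/p_hat as
well would count the nonparticipant dementia mass twice (once through the
inverse weight, once through the passive cases).  Passive cases never
contribute to the imaging-stage models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import DEMENTIA_STATUSES
from ._design import design_matrix

STAGES = ["enroll", "amyloid_pet", "tau_pet"]

DEFAULT_PARTICIPATION_TERMS = ("z", "z2", "male", "edu")


@dataclass
class ParticipationModel:
    """Fitted logistic model of participation at one stage."""

    stage: str
    terms: tuple
    coefficients: np.ndarray | None
    coef_names: list[str] = field(default_factory=list)
    log_likelihood: float = np.nan
    n_iterations: int = 0
    #: "all_participated" / "none_participated" / "separation" / None
    degenerate: str | None = None

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        """Predicted participation probability for each record."""
        if self.degenerate == "all_participated":
            return np.ones(len(frame))
        if self.degenerate == "none_participated":
            return np.zeros(len(frame))
        X, _ = design_matrix(frame, self.terms)
        eta = X @ self.coefficients
        return 1.0 / (1.0 + np.exp(-eta))


def fit_participation_model(frame: pd.DataFrame, stage: str,
                            participated: np.ndarray | str = "participated",
                            terms: tuple = DEFAULT_PARTICIPATION_TERMS,
                            maxiter: int = 200) -> ParticipationModel:
    """Maximum-likelihood logistic fit of participation on sex, age, education.

    With saturated categorical predictors the fitted probabilities equal the
    empirical cell proportions.  All-participated (or none-participated)
    input yields a flagged degenerate model with probability 1 (or 0), not an
    exception.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; allowed: {STAGES}")
    y = frame[participated].to_numpy() if isinstance(participated, str) else np.asarray(participated)
    y = y.astype(float)
    if len(y) == 0:
        raise ValueError("empty stage frame")
    if y.min() >= 1.0:
        return ParticipationModel(stage, terms, None, degenerate="all_participated")
    if y.max() <= 0.0:
        return ParticipationModel(stage, terms, None, degenerate="none_participated")

    X, names = design_matrix(frame, terms)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(maxiter=maxiter, tol=1e-10)
    if not res.converged:
        raise RuntimeError(
            f"participation model for stage {stage!r} did not converge after "
            f"{maxiter} iterations (deviance {res.deviance:.3g})")
    coefs = np.asarray(res.params)
    degenerate = "separation" if np.abs(coefs).max() > 30 else None
    return ParticipationModel(
        stage=stage, terms=terms, coefficients=coefs, coef_names=names,
        log_likelihood=float(res.llf), n_iterations=int(res.fit_history["iteration"]),
        degenerate=degenerate)


@dataclass
class WeightedSample:
    """Records plus per-record analysis weights targeting one nested cohort."""

    records: pd.DataFrame
    weights: np.ndarray
    stage: str
    truncated_at: float | None = None
    n_truncated: int = 0

    def __post_init__(self):
        if len(self.records) != len(self.weights):
            raise ValueError("records/weights length mismatch")
        if len(self.weights) and (not np.all(np.isfinite(self.weights)) or self.weights.min() <= 0):
            raise ValueError("weights must be positive and finite")


def compute_weights(models: dict[str, ParticipationModel], records: pd.DataFrame,
                    target_stage: str, truncate_percentile: float | None = 99.0,
                    passive_complete: bool | None = None) -> WeightedSample:
    """Inverse-probability weights for the cohort targeted by *target_stage*.

    ``records`` must contain exactly the members of the target cohort (all of
    whom participated through that stage, apart from passive dementia cases
    in the clinical cohort).  ``passive_complete=None`` infers completeness of
    dementia surveillance from the presence of passive records.
    """
    if target_stage not in STAGES:
        raise ValueError(f"unknown target stage {target_stage!r}")
    upto = STAGES[: STAGES.index(target_stage) + 1]
    strat = (records["stratum_weight"].to_numpy(dtype=float)
             if "stratum_weight" in records.columns else np.ones(len(records)))

    prob = np.ones(len(records))
    for stage in upto:
        p = models[stage].predict(records)
        if (p <= 0).any():
            raise ValueError(f"zero participation probability at stage {stage!r} "
                             "for an included record")
        prob *= p
    w = strat / prob

    passive = (records["ascertainment"] == "passive").to_numpy()
    if target_stage == "enroll":
        if passive_complete is None:
            passive_complete = bool(passive.any())
        if passive_complete:
            dem = records["clinical_status"].isin(DEMENTIA_STATUSES).to_numpy()
            w[dem | passive] = strat[dem | passive]
        else:
            w[passive] = strat[passive]
    elif passive.any():
        raise ValueError("passive records cannot enter imaging-stage cohorts")

    truncated_at, n_trunc = None, 0
    if truncate_percentile is not None and len(w):
        cap = float(np.percentile(w, truncate_percentile))
        n_trunc = int((w > cap).sum())
        if n_trunc:
            w = np.minimum(w, cap)
        truncated_at = cap
    return WeightedSample(records=records, weights=w, stage=target_stage,
                          truncated_at=truncated_at, n_truncated=n_trunc)
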