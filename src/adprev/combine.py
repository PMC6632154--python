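"""Combine the stage models into entity prevalence curves via total probability.

For a biological entity the staged estimate at (age, sex) is

    P(A+)      = sum_status P(status | age, sex) * P(A+ | status, age, sex)
    P(A+T+)    = sum_status P(status | age, sex) * P(A+ | status, age, sex)
                                                 * P(T+ | A+, status, age, sex)
    P(A+T-)    = P(A+) - P(A+T+)                    (exact, by construction)

where the sum runs over the four clinical categories; the two dementia
subcategories share the pooled dementia-group biomarker probabilities.
Clinical entities (CU, MCI, dementia, probable AD, MCI-or-dementia) read
directly off the clinical model.  Curves are evaluated on integer ages with
no smoothing beyond the models' functional form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import ClinicalModel, ConditionalBiomarkerModel

ENTITIES = [
    "CU", "MCI", "dementia", "probable_AD", "MCI_or_dementia",
    "A_plus", "A_plus_T_minus", "A_plus_T_plus",
]

CLINICAL_ENTITIES = {"CU", "MCI", "dementia", "probable_AD", "MCI_or_dementia"}

#: clinical category -> broad biomarker group
_GROUP_OF = {"CU": "CU", "MCI": "MCI",
             "dementia_probable_AD": "dementia", "dementia_other": "dementia"}

DEFAULT_AGES = np.arange(60, 91)


@dataclass
class PrevalenceCurve:
    """Entity x sex prevalence estimates on an integer age grid, with optional CI."""

    entity: str
    sex: str
    ages: np.ndarray
    estimates: np.ndarray
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ages = np.asarray(self.ages)
        self.estimates = np.asarray(self.estimates, dtype=float)
        if self.ages.shape != self.estimates.shape:
            raise ValueError("age grid and estimates must align")

    def at(self, age) -> float:
        idx = np.flatnonzero(self.ages == age)
        if idx.size == 0:
            raise KeyError(f"age {age} not on the curve grid")
        return float(self.estimates[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"entity": self.entity, "sex": self.sex,
                            "age": self.ages, "estimate": self.estimates})
        out["lower"] = self.lower if self.lower is not None else np.nan
        out["upper"] = self.upper if self.upper is not None else np.nan
        return out


def combined_prevalence(clinical: ClinicalModel,
                        amyloid: ConditionalBiomarkerModel | None,
                        tau: ConditionalBiomarkerModel | None,
                        entity: str, sex: str,
                        ages=DEFAULT_AGES) -> PrevalenceCurve:
    """Total-probability prevalence curve for *entity* at *sex* over *ages*."""
    if entity not in ENTITIES:
        raise ValueError(f"unknown entity {entity!r}; allowed: {ENTITIES}")
    ages = np.asarray(ages)
    grid = pd.DataFrame({"age": ages, "sex": sex})
    p_status = clinical.predict(grid)

    if entity in CLINICAL_ENTITIES:
        est = _clinical_entity(p_status, entity)
        return PrevalenceCurve(entity, sex, ages, est)

    if amyloid is None:
        raise ValueError("amyloid model required for biomarker entities")
    if entity in ("A_plus_T_plus", "A_plus_T_minus") and tau is None:
        raise ValueError(f"tau model required for entity {entity!r}")

    a_plus = np.zeros(len(ages))
    a_plus_t_plus = np.zeros(len(ages))
    for cat in p_status.columns:
        if cat not in _GROUP_OF:
            continue
        ps = p_status[cat].to_numpy()
        if not ps.any():
            continue
        group = _GROUP_OF[cat]
        pA = amyloid.predict(group, grid)
        a_plus += ps * pA
        if tau is not None:
            a_plus_t_plus += ps * pA * tau.predict(group, grid)

    if entity == "A_plus":
        est = a_plus
    elif entity == "A_plus_T_plus":
        est = a_plus_t_plus
    else:
        est = a_plus - a_plus_t_plus
    return PrevalenceCurve(entity, sex, ages, est)


def _clinical_entity(p_status: pd.DataFrame, entity: str) -> np.ndarray:
    if entity == "CU":
        return p_status["CU"].to_numpy()
    if entity == "MCI":
        return p_status["MCI"].to_numpy()
    if entity == "probable_AD":
        return p_status["dementia_probable_AD"].to_numpy()
    if entity == "dementia":
        return (p_status["dementia_probable_AD"] + p_status["dementia_other"]).to_numpy()
    # MCI_or_dementia
    return (p_status["MCI"] + p_status["dementia_probable_AD"]
            + p_status["dementia_other"]).to_numpy()


def sex_difference_curve(men: PrevalenceCurve, women: PrevalenceCurve) -> PrevalenceCurve:
    """Pointwise men - women difference curve (positive = higher in men)."""
    if men.entity != women.entity:
        raise ValueError("curves must describe the same entity")
    if men.ages.shape != women.ages.shape or (men.ages != women.ages).any():
        raise ValueError("age grids do not match")
    return PrevalenceCurve(entity=men.entity, sex="men_minus_women", ages=men.ages,
                           estimates=men.estimates - women.estimates)
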