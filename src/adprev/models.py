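"""Biomarker thresholding, NIA-AA entity classification, and the weighted stage models.

Two model families are fitted on the weighted nested cohorts:

* a weighted multinomial-logit **clinical model** for
  P(status | age, sex) over {CU, MCI, dementia_probable_AD, dementia_other},
  with logit-scale linear + quadratic age, sex and an age x sex interaction
  (probable AD is modelled as a dementia subcategory so that its prevalence
  falls out of the same staged structure);
* weighted logistic **conditional biomarker models** per broad clinical group
  (CU / MCI / dementia) for P(A+ | status, age, sex) on the amyloid PET
  cohort, and P(T+ | A+, status, age, sex) on the A+ members of the tau PET
  cohort.  The dementia group is pooled to an intercept-only estimate across
  all ages and both sexes because of its small imaging sample.

Binary outcomes come from SUVR cut points (amyloid 1.48, tau 1.25 on the
temporal meta-ROI by default); a study is abnormal iff SUVR >= cut point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from .cohort import TAU_ROIS
from .weights import WeightedSample
from ._design import design_matrix

CLINICAL_CATEGORIES = ["CU", "MCI", "dementia_probable_AD", "dementia_other"]
#: broad groups used by the conditional biomarker models
BIOMARKER_GROUPS = ["CU", "MCI", "dementia"]

DEFAULT_CLINICAL_TERMS = ("z", "z2", "male", "z_male")
DEFAULT_CONDITIONAL_TERMS = ("z", "male")

ENTITY_LABELS = {"continuum", "pathologic_change", "biological_AD"}


@dataclass
class CutpointConfig:
    """SUVR cut points and the tau ROI channel defining A/T positivity."""

    amyloid_cutpoint: float = 1.48
    tau_cutpoint: float = 1.25
    tau_roi: str = "temporal_meta"
    #: boundary rule: abnormal iff SUVR >= cut point
    abnormal_if_equal: bool = True

    def __post_init__(self):
        if self.amyloid_cutpoint <= 0 or self.tau_cutpoint <= 0:
            raise ValueError("cut points must be positive")
        if self.tau_roi not in TAU_ROIS:
            raise ValueError(f"unknown tau ROI {self.tau_roi!r}; allowed: {TAU_ROIS}")

    @property
    def tau_column(self) -> str:
        return f"tau_suvr_{self.tau_roi}"


def apply_cutpoint(suvr, cutpoint: float, abnormal_if_equal: bool = True):
    """Classify SUVR value(s) as 'abnormal' / 'normal' ('unknown' if missing).

    Scalar in, scalar out; array in, object array out.  Non-positive SUVR is
    an error; missing (NaN/None) maps to 'unknown'.
    """
    if cutpoint <= 0:
        raise ValueError("cut point must be positive")
    arr = np.asarray(suvr, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    known = ~np.isnan(arr)
    if (arr[known] <= 0).any():
        raise ValueError("SUVR values must be positive")
    abn = arr >= cutpoint if abnormal_if_equal else arr > cutpoint
    out = np.where(known, np.where(abn, "abnormal", "normal"), "unknown").astype(object)
    return out[0] if scalar else out


def classify_profile(a_status: str, t_status: str) -> frozenset:
    """NIA-AA entity membership for an (amyloid, tau) biomarker status pair.

    A+T- -> {continuum, pathologic_change}; A+T+ -> {continuum,
    biological_AD}; A+ with unknown tau -> {continuum} (the continuum is the
    umbrella definition covering any A+ individual); any A- profile,
    including A-T+, belongs to none of the entities.
    """
    allowed = {"abnormal", "normal", "unknown"}
    if a_status not in allowed or t_status not in allowed:
        raise ValueError(f"statuses must be in {allowed}")
    if a_status != "abnormal":
        return frozenset()
    if t_status == "normal":
        return frozenset({"continuum", "pathologic_change"})
    if t_status == "abnormal":
        return frozenset({"continuum", "biological_AD"})
    return frozenset({"continuum"})


def _broad_group(status: np.ndarray) -> np.ndarray:
    out = np.asarray(status, dtype=object).copy()
    out[np.isin(out, ["dementia_probable_AD", "dementia_other"])] = "dementia"
    return out


# ---------------------------------------------------------------------------
# clinical multinomial model


@dataclass
class ClinicalModel:
    """Weighted multinomial-logit model of clinical status by age and sex."""

    categories: list[str]
    terms: tuple
    #: fitted sklearn estimator, or None for closed-form/degenerate fits
    _estimator: object = None
    #: closed-form category probabilities (intercept-only / single-category)
    _constant_probs: np.ndarray | None = None
    missing_categories: list[str] = field(default_factory=list)
    weights_total: float = np.nan

    @classmethod
    def from_constants(cls, probs: dict[str, float]) -> "ClinicalModel":
        """Build a constant-probability model (used for oracles and toys)."""
        cats = list(probs)
        p = np.asarray([probs[c] for c in cats], dtype=float)
        if abs(p.sum() - 1.0) > 1e-9 or p.min() < 0:
            raise ValueError("probabilities must be a distribution")
        return cls(categories=cats, terms=(), _constant_probs=p,
                   missing_categories=[c for c in CLINICAL_CATEGORIES if c not in cats])

    def predict(self, frame: pd.DataFrame) -> pd.DataFrame:
        """Category probabilities for each row of *frame* (age, sex columns)."""
        n = len(frame)
        if self._constant_probs is not None:
            probs = np.tile(self._constant_probs, (n, 1))
        else:
            X, _ = design_matrix(frame, self.terms)
            probs = self._estimator.predict_proba(X[:, 1:])
            order = [list(self._estimator.classes_).index(c) for c in self.categories]
            probs = probs[:, order]
        out = pd.DataFrame(0.0, index=frame.index, columns=CLINICAL_CATEGORIES)
        for j, c in enumerate(self.categories):
            if c in out.columns:
                out[c] = probs[:, j]
            else:
                out[c] = 0.0
                out.loc[:, c] = probs[:, j]
        return out

    def predict_at(self, age, sex: str) -> pd.DataFrame:
        age = np.atleast_1d(age)
        return self.predict(pd.DataFrame({"age": age, "sex": sex}))


def fit_clinical_multinomial(sample: WeightedSample,
                             terms: tuple = DEFAULT_CLINICAL_TERMS) -> ClinicalModel:
    """Weighted maximum-likelihood multinomial-logit fit on the clinical cohort.

    Intercept-only fits (empty *terms*) reduce to exact weighted category
    proportions.  Categories absent from the data are flagged and predicted
    as probability zero.
    """
    records, w = sample.records, np.asarray(sample.weights, dtype=float)
    y = records["clinical_status"].to_numpy(dtype=object)
    bad = ~np.isin(y, CLINICAL_CATEGORIES)
    if bad.any():
        raise ValueError("clinical sample contains non-diagnosis statuses "
                         f"({set(y[bad])})")
    present = [c for c in CLINICAL_CATEGORIES if (y == c).any()]
    missing = [c for c in CLINICAL_CATEGORIES if c not in present]
    if missing:
        warnings.warn(f"clinical categories absent from data: {missing}", stacklevel=2)

    if len(present) == 1:
        return ClinicalModel(categories=present, terms=terms,
                             _constant_probs=np.array([1.0]),
                             missing_categories=missing, weights_total=float(w.sum()))
    if not terms:
        p = np.array([w[y == c].sum() for c in present])
        return ClinicalModel(categories=present, terms=terms,
                             _constant_probs=p / p.sum(),
                             missing_categories=missing, weights_total=float(w.sum()))

    X, _ = design_matrix(records, terms)
    est = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=10000,
                             tol=1e-12, fit_intercept=True)
    est.fit(X[:, 1:], y, sample_weight=w)
    return ClinicalModel(categories=present, terms=terms, _estimator=est,
                         missing_categories=missing, weights_total=float(w.sum()))


# ---------------------------------------------------------------------------
# conditional biomarker models


@dataclass
class _GroupFit:
    kind: str                      # "glm" | "constant"
    coefficients: np.ndarray | None = None
    constant: float = np.nan
    flag: str | None = None        # "degenerate", "small_sample", "pooled"


@dataclass
class ConditionalBiomarkerModel:
    """Per-clinical-group logistic models of biomarker positivity."""

    target: str                    # "A_plus_given_status" | "T_plus_given_A_plus_and_status"
    terms: tuple
    cutpoints: CutpointConfig
    group_fits: dict = field(default_factory=dict)

    @classmethod
    def from_constants(cls, probs: dict[str, float], target: str = "A_plus_given_status",
                       cutpoints: CutpointConfig | None = None) -> "ConditionalBiomarkerModel":
        fits = {g: _GroupFit(kind="constant", constant=float(p), flag=None)
                for g, p in probs.items()}
        return cls(target=target, terms=(), cutpoints=cutpoints or CutpointConfig(),
                   group_fits=fits)

    def predict(self, group: str, frame: pd.DataFrame) -> np.ndarray:
        if group not in self.group_fits:
            raise KeyError(f"no fit for clinical group {group!r}")
        fit = self.group_fits[group]
        if fit.kind == "constant":
            return np.full(len(frame), fit.constant)
        X, _ = design_matrix(frame, self.terms)
        return expit(X @ fit.coefficients)

    def predict_at(self, group: str, age, sex: str) -> np.ndarray:
        age = np.atleast_1d(age)
        return self.predict(group, pd.DataFrame({"age": age, "sex": sex}))


def _weighted_proportion(y, w) -> float:
    return float(np.sum(w * y) / np.sum(w))


def fit_conditional_model(sample: WeightedSample, target: str,
                          cutpoints: CutpointConfig | None = None,
                          terms: tuple = DEFAULT_CONDITIONAL_TERMS,
                          min_group_n: int = 25) -> ConditionalBiomarkerModel:
    """Fit P(A+ | group, age, sex) or P(T+ | A+, group, age, sex) on a weighted cohort.

    *target* is ``"A"`` (amyloid positivity on the amyloid PET cohort) or
    ``"T"`` (tau positivity among A+ members of the tau PET cohort).  The
    dementia group is always pooled intercept-only; other groups fall back to
    a flagged intercept-only fit below *min_group_n* observations, and to a
    flagged constant when the outcome is all-0/all-1.
    """
    cutpoints = cutpoints or CutpointConfig()
    if target not in ("A", "T"):
        raise ValueError("target must be 'A' or 'T'")
    records, w = sample.records, np.asarray(sample.weights, dtype=float)

    a_status = apply_cutpoint(records["amyloid_suvr"].to_numpy(),
                              cutpoints.amyloid_cutpoint, cutpoints.abnormal_if_equal)
    if target == "A":
        frame, wts = records, w
        outcome = (np.atleast_1d(a_status) == "abnormal").astype(float)
    else:
        tau_col = cutpoints.tau_column
        if tau_col not in records.columns or records[tau_col].notna().sum() == 0:
            raise ValueError(f"tau channel {cutpoints.tau_roi!r} unavailable in the sample")
        keep = np.atleast_1d(a_status) == "abnormal"
        frame, wts = records[keep], w[keep]
        t_status = apply_cutpoint(frame[tau_col].to_numpy(),
                                  cutpoints.tau_cutpoint, cutpoints.abnormal_if_equal)
        outcome = (np.atleast_1d(t_status) == "abnormal").astype(float)

    group = _broad_group(frame["clinical_status"].to_numpy())
    target_name = "A_plus_given_status" if target == "A" else "T_plus_given_A_plus_and_status"
    fits: dict[str, _GroupFit] = {}
    for g in BIOMARKER_GROUPS:
        m = group == g
        if not m.any():
            fits[g] = _GroupFit(kind="constant", constant=0.0, flag="degenerate")
            warnings.warn(f"clinical group {g!r} empty in {target_name}; predicting 0",
                          stacklevel=2)
            continue
        yg, wg, fg = outcome[m], wts[m], frame[m]
        if g == "dementia":
            fits[g] = _GroupFit(kind="constant", constant=_weighted_proportion(yg, wg),
                                flag="pooled")
            continue
        if yg.min() >= 1.0 or yg.max() <= 0.0:
            fits[g] = _GroupFit(kind="constant", constant=float(yg.max() > 0),
                                flag="degenerate")
            continue
        if m.sum() < min_group_n:
            warnings.warn(f"clinical group {g!r} has {int(m.sum())} < {min_group_n} "
                          f"observations in {target_name}; intercept-only fit", stacklevel=2)
            fits[g] = _GroupFit(kind="constant", constant=_weighted_proportion(yg, wg),
                                flag="small_sample")
            continue
        X, _ = design_matrix(fg, terms)
        res = sm.GLM(yg, X, family=sm.families.Binomial(), var_weights=wg).fit(
            maxiter=200, tol=1e-10)
        fits[g] = _GroupFit(kind="glm", coefficients=np.asarray(res.params),
                            flag="separation" if np.abs(res.params).max() > 30 else None)
    return ConditionalBiomarkerModel(target=target_name, terms=terms,
                                     cutpoints=cutpoints, group_fits=fits)
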