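"""Cut-point thresholding, entity classification, and weighted stage models."""

import warnings

import numpy as np
import pandas as pd
import pytest

from adprev.models import (
    ClinicalModel,
    CutpointConfig,
    apply_cutpoint,
    classify_profile,
    fit_clinical_multinomial,
    fit_conditional_model,
)
from adprev.synth import true_prevalence
from adprev.weights import WeightedSample


@pytest.mark.parametrize("suvr,cut,expected", [
    (1.49, 1.48, "abnormal"),
    (1.47, 1.48, "normal"),
    (1.48, 1.48, "abnormal"),   # boundary: abnormal iff SUVR >= cut
    (np.nan, 1.48, "unknown"),
])
def test_apply_cutpoint(suvr, cut, expected):
    assert apply_cutpoint(suvr, cut) == expected


def test_apply_cutpoint_rejects_nonpositive_suvr():
    with pytest.raises(ValueError):
        apply_cutpoint(-1.0, 1.48)
    with pytest.raises(ValueError):
        apply_cutpoint(1.3, 0.0)


def test_apply_cutpoint_boundary_rule_configurable():
    assert apply_cutpoint(1.48, 1.48, abnormal_if_equal=False) == "normal"


@pytest.mark.parametrize("a,t,expected", [
    ("abnormal", "normal", {"continuum", "pathologic_change"}),
    ("abnormal", "abnormal", {"continuum", "biological_AD"}),
    ("abnormal", "unknown", {"continuum"}),
    ("normal", "abnormal", set()),       # A-T+ belongs to no entity
    ("normal", "normal", set()),
    ("normal", "unknown", set()),
    ("unknown", "abnormal", set()),
])
def test_classify_profile(a, t, expected):
    assert classify_profile(a, t) == frozenset(expected)


def test_classify_profile_rejects_bad_status():
    with pytest.raises(ValueError):
        classify_profile("positive", "normal")


def _sample(statuses, weights, **cols):
    n = len(statuses)
    frame = pd.DataFrame({
        "age": cols.get("age", np.full(n, 75)),
        "sex": cols.get("sex", ["female"] * n),
        "education": "13-16",
        "clinical_status": statuses,
        "amyloid_suvr": cols.get("amyloid_suvr", np.full(n, 1.3)),
        "tau_suvr_temporal_meta": cols.get("tau", np.full(n, 1.1)),
    })
    return WeightedSample(records=frame, weights=np.asarray(weights, dtype=float),
                          stage="enroll")


def test_intercept_only_multinomial_equals_weighted_proportions():
    sample = _sample(["CU", "CU", "MCI"], [2.0, 1.0, 1.0])
    model = fit_clinical_multinomial(sample, terms=())
    probs = model.predict_at(75, "female")
    assert probs["CU"].iloc[0] == pytest.approx(0.75, abs=1e-8)
    assert probs["MCI"].iloc[0] == pytest.approx(0.25, abs=1e-8)


def test_single_category_predicts_one_everywhere():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = fit_clinical_multinomial(_sample(["CU"] * 5, np.ones(5)))
    probs = model.predict_at([65, 75, 85], "male")
    np.testing.assert_allclose(probs["CU"], 1.0)
    np.testing.assert_allclose(probs["MCI"], 0.0)


def test_clinical_probabilities_sum_to_one_on_grid(fit_fully_observed):
    rng = np.random.default_rng(2)
    grid = pd.DataFrame({"age": rng.integers(60, 91, 1000),
                         "sex": rng.choice(["female", "male"], 1000)})
    probs = fit_fully_observed.clinical_model.predict(grid)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
    assert (probs.to_numpy() >= 0).all()


def test_clinical_recovery_at_age_75(fit_fully_observed, params_default):
    """Fully observed fit recovers generating P(CU | 75, sex) within 2 points."""
    for sex in ("female", "male"):
        fitted = fit_fully_observed.clinical_model.predict_at(75, sex)["CU"].iloc[0]
        truth = true_prevalence(params_default, "CU", sex, np.array([75]))[0]
        assert abs(fitted - truth) < 0.02


def test_conditional_recovery_at_key_ages(fit_fully_observed, params_default):
    """Fitted staged conditionals at 65/75/85 are within 2 points of truth."""
    ages = np.array([65, 75, 85])
    for sex in ("female", "male"):
        for entity in ("A_plus", "A_plus_T_plus"):
            est = fit_fully_observed.curve(entity, sex, ages).estimates
            tru = true_prevalence(params_default, entity, sex, ages)
            assert np.all(np.abs(est - tru) < 0.02), (entity, sex)


def test_dementia_group_is_pooled_constant(fit_fully_observed):
    model = fit_fully_observed.amyloid_model
    assert model.group_fits["dementia"].flag == "pooled"
    p = model.predict_at("dementia", [60, 75, 90], "female")
    assert p[0] == p[1] == p[2]
    p_m = model.predict_at("dementia", [75], "male")
    assert p_m[0] == p[0]


def test_all_negative_group_flagged_degenerate():
    sample = _sample(["CU"] * 40 + ["MCI"] * 40, np.ones(80),
                     amyloid_suvr=np.r_[np.full(40, 1.30), np.full(40, 1.60)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = fit_conditional_model(sample, "A", CutpointConfig())
    assert model.group_fits["CU"].flag == "degenerate"
    np.testing.assert_allclose(model.predict_at("CU", [70, 80], "female"), 0.0)


def test_intercept_only_conditional_equals_proportion():
    suvr = np.r_[np.full(30, 1.60), np.full(70, 1.30)]
    sample = _sample(["CU"] * 100, np.ones(100), amyloid_suvr=suvr)
    model = fit_conditional_model(sample, "A", CutpointConfig(), terms=())
    assert model.predict_at("CU", [75], "female")[0] == pytest.approx(0.30, abs=1e-8)


def test_small_group_falls_back_to_intercept_only():
    rng = np.random.default_rng(5)
    suvr = np.where(rng.uniform(size=10) < 0.5, 1.6, 1.3)
    if suvr.min() == suvr.max():
        suvr[0] = 1.6 if suvr.min() < 1.48 else 1.3
    sample = _sample(["CU"] * 10, np.ones(10), amyloid_suvr=suvr,
                     age=rng.integers(60, 91, 10))
    with pytest.warns(UserWarning, match="intercept-only"):
        model = fit_conditional_model(sample, "A", CutpointConfig(), min_group_n=25)
    assert model.group_fits["CU"].flag == "small_sample"


def test_monotone_generating_logit_yields_increasing_fit(fit_fully_observed):
    """Generating A+ logits increase with age, so fitted curves must too."""
    ages = np.arange(60, 91)
    for group in ("CU", "MCI"):
        p = fit_fully_observed.amyloid_model.predict_at(group, ages, "female")
        assert np.all(np.diff(p) > 0), group


def test_tau_model_requires_available_channel(small_observed, fit_ipw_100k):
    sample = fit_ipw_100k.tau_sample
    broken = CutpointConfig(tau_roi="entorhinal")
    records = sample.records.copy()
    records["tau_suvr_entorhinal"] = np.nan
    ws = WeightedSample(records=records, weights=sample.weights, stage="tau_pet")
    with pytest.raises(ValueError, match="unavailable"):
        fit_conditional_model(ws, "T", broken)


def test_from_constants_validates_distribution():
    with pytest.raises(ValueError):
        ClinicalModel.from_constants({"CU": 0.9, "MCI": 0.2})
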