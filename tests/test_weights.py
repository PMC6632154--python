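"""Participation models and inverse-probability weights."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from adprev.synth import Coeffs, default_params, generate_population, simulate_observation, true_prevalence
from adprev.pipeline import PipelineConfig, fit_staged
from adprev.weights import ParticipationModel, compute_weights, fit_participation_model

from conftest import sex_average


def _frame(n, ages=75, sex="female", edu="13-16"):
    return pd.DataFrame({"age": np.full(n, ages), "sex": sex, "education": edu})


def test_all_participated_gives_flagged_unit_probabilities():
    frame = _frame(50)
    model = fit_participation_model(frame, "enroll", np.ones(50))
    assert model.degenerate == "all_participated"
    np.testing.assert_array_equal(model.predict(frame), 1.0)


def test_saturated_sex_model_equals_cell_proportions():
    frame = pd.concat([_frame(100, sex="male"), _frame(100, sex="female")],
                      ignore_index=True)
    participated = np.r_[np.repeat([1, 0], [80, 20]), np.repeat([1, 0], [60, 40])]
    model = fit_participation_model(frame, "enroll", participated, terms=("male",))
    p = model.predict(frame)
    np.testing.assert_allclose(p[:100], 0.80, atol=1e-8)
    np.testing.assert_allclose(p[100:], 0.60, atol=1e-8)


def test_independent_participation_recovers_flat_rate():
    rng = np.random.default_rng(8)
    n = 50_000
    frame = pd.DataFrame({
        "age": rng.integers(60, 91, n),
        "sex": np.where(rng.uniform(size=n) < 0.5, "female", "male"),
        "education": rng.choice(["<12", "12", "13-16", ">16"], n),
    })
    participated = (rng.uniform(size=n) < 0.5).astype(float)
    model = fit_participation_model(frame, "enroll", participated)
    p = model.predict(frame)
    assert np.all(np.abs(p - 0.5) < 0.02)
    sample = compute_weights(
        {"enroll": model}, frame.assign(
            id=np.arange(n).astype(str), ascertainment="active",
            clinical_status="CU", enrolled=True)[participated.astype(bool)],
        "enroll", truncate_percentile=None)
    assert np.all(np.abs(sample.weights - 2.0) < 0.1)


def _constant_model(stage, p):
    return ParticipationModel(stage=stage, terms=(), coefficients=np.array([logit(p)]))


def test_weight_is_product_of_inverse_stage_probabilities():
    records = _frame(4).assign(id=list("abcd"), ascertainment="active",
                               clinical_status="CU", enrolled=True)
    models = {"enroll": _constant_model("enroll", 0.8),
              "amyloid_pet": _constant_model("amyloid_pet", 0.5)}
    sample = compute_weights(models, records, "amyloid_pet", truncate_percentile=None)
    np.testing.assert_allclose(sample.weights, 2.5, atol=1e-9)


def test_unit_probabilities_give_unit_weights():
    records = _frame(6).assign(id=[f"r{i}" for i in range(6)], ascertainment="active",
                               clinical_status="CU", enrolled=True)
    models = {"enroll": ParticipationModel("enroll", (), None,
                                           degenerate="all_participated")}
    sample = compute_weights(models, records, "enroll", truncate_percentile=None)
    np.testing.assert_array_equal(sample.weights, 1.0)


def test_truncation_caps_only_the_extreme_weight():
    n = 200
    records = _frame(n).assign(id=[f"r{i}" for i in range(n)], ascertainment="active",
                               clinical_status="CU", enrolled=True,
                               stratum_weight=np.r_[np.ones(n - 1), 50.0])
    models = {"enroll": ParticipationModel("enroll", (), None,
                                           degenerate="all_participated")}
    sample = compute_weights(models, records, "enroll", truncate_percentile=99.0)
    raw = np.r_[np.ones(n - 1), 50.0]
    cap = np.percentile(raw, 99.0)
    assert sample.n_truncated == 1
    np.testing.assert_allclose(sample.weights[:-1], 1.0)
    assert sample.weights[-1] == pytest.approx(cap)


def test_weighted_count_estimates_enumerated_population(fit_ipw_100k, observed_100k):
    pop, _ = observed_100k
    total = float(np.sum(fit_ipw_100k.clinical_sample.weights))
    assert abs(total - len(pop)) / len(pop) < 0.05


def test_ipw_improves_clinical_status_composition_at_every_age(
        params_default, fit_ipw_100k, fit_unweighted_100k):
    """Strict improvement: IPW total-variation error of the clinical-status
    composition is below the unweighted error at every age in 65..85."""
    ages = np.array([65, 70, 75, 80, 85])

    def tv(fit):
        errs = []
        for entity in ("CU", "MCI", "dementia"):
            tru = sex_average(lambda s, e=entity: true_prevalence(params_default, e, s, ages))
            est = sex_average(lambda s, e=entity: fit.curve(e, s, ages).estimates)
            errs.append(np.abs(est - tru))
        return 0.5 * np.sum(errs, axis=0)

    assert (tv(fit_ipw_100k) < tv(fit_unweighted_100k)).all()


def test_independent_participation_weighted_equals_unweighted():
    """With participation independent of covariates (and no passive
    surveillance channel, which by design enriches the cohort in dementia),
    IPW and unweighted prevalence curves coincide within Monte-Carlo error."""
    p = default_params()
    p.passive_sensitivity = 0.0
    p.participation_coeffs = {
        "enroll": Coeffs(intercept=float(logit(0.6))),
        "amyloid_pet": Coeffs(intercept=float(logit(0.5))),
        "tau_pet": Coeffs(intercept=float(logit(0.5))),
    }
    pop = generate_population(p, 40_000, seed=61)
    obs = simulate_observation(pop, p, seed=62)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fw = fit_staged(obs, PipelineConfig(use_ipw=True))
        fu = fit_staged(obs, PipelineConfig(use_ipw=False))
    ages = np.array([65, 70, 75, 80, 85])
    for sex in ("female", "male"):
        a = fw.curve("A_plus", sex, ages).estimates
        b = fu.curve("A_plus", sex, ages).estimates
        assert np.all(np.abs(a - b) < 0.02)


def test_passive_records_rejected_from_imaging_cohorts(small_observed):
    passive = small_observed[small_observed["ascertainment"] == "passive"]
    models = {"enroll": _constant_model("enroll", 0.5),
              "amyloid_pet": _constant_model("amyloid_pet", 0.5)}
    with pytest.raises(ValueError, match="passive"):
        compute_weights(models, passive, "amyloid_pet")
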