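"""Total-probability combination and prevalence-curve invariants."""

import warnings

import numpy as np
import pytest

from adprev.combine import ENTITIES, PrevalenceCurve, combined_prevalence, sex_difference_curve
from adprev.models import ClinicalModel, ConditionalBiomarkerModel
from adprev.pipeline import PipelineConfig, fit_staged
from adprev.synth import (
    Coeffs,
    default_params,
    generate_population,
    simulate_observation,
    true_prevalence,
)


def _toy_models():
    clinical = ClinicalModel.from_constants({"CU": 0.7, "MCI": 0.3})
    amyloid = ConditionalBiomarkerModel.from_constants({"CU": 0.2, "MCI": 0.6})
    tau = ConditionalBiomarkerModel.from_constants(
        {"CU": 0.5, "MCI": 0.9}, target="T_plus_given_A_plus_and_status")
    return clinical, amyloid, tau


def test_toy_two_status_hand_enumeration():
    clinical, amyloid, tau = _toy_models()
    ages = np.array([70, 80])
    a = combined_prevalence(clinical, amyloid, tau, "A_plus", "female", ages)
    at = combined_prevalence(clinical, amyloid, tau, "A_plus_T_plus", "female", ages)
    an = combined_prevalence(clinical, amyloid, tau, "A_plus_T_minus", "female", ages)
    np.testing.assert_allclose(a.estimates, 0.32, atol=1e-12)
    np.testing.assert_allclose(at.estimates, 0.232, atol=1e-12)
    np.testing.assert_allclose(an.estimates, 0.088, atol=1e-12)


def test_combination_matches_generator_oracle():
    """The staged combination and the generator's closed form agree exactly
    when fed the same constant stage probabilities."""
    clinical, amyloid, tau = _toy_models()
    p = default_params()
    p.education_probs = (0.0, 0.0, 1.0, 0.0)
    p.clinical_coeffs = {"MCI": Coeffs(intercept=float(np.log(0.3 / 0.7))),
                         "dementia_probable_AD": Coeffs(intercept=-50.0),
                         "dementia_other": Coeffs(intercept=-50.0)}
    from scipy.special import logit
    p.amyloid_coeffs = {s: Coeffs(intercept=float(logit(0.2))) for s in p.amyloid_coeffs}
    p.amyloid_coeffs["MCI"] = Coeffs(intercept=float(logit(0.6)))
    p.tau_coeffs = {s: Coeffs(intercept=float(logit(0.5))) for s in p.tau_coeffs}
    p.tau_coeffs["MCI"] = Coeffs(intercept=float(logit(0.9)))
    est = combined_prevalence(clinical, amyloid, tau, "A_plus_T_plus", "male",
                              np.array([75])).estimates[0]
    oracle = true_prevalence(p, "A_plus_T_plus", "male", np.array([75]))[0]
    assert est == pytest.approx(oracle, abs=1e-12)


def test_certain_amyloid_gives_unit_continuum():
    clinical = ClinicalModel.from_constants({"CU": 0.7, "MCI": 0.3})
    amyloid = ConditionalBiomarkerModel.from_constants({"CU": 1.0, "MCI": 1.0})
    curve = combined_prevalence(clinical, amyloid, None, "A_plus", "male",
                                np.arange(60, 91))
    np.testing.assert_allclose(curve.estimates, 1.0)


def test_missing_tau_model_rejected_for_t_entities():
    clinical, amyloid, _ = _toy_models()
    with pytest.raises(ValueError, match="tau model"):
        combined_prevalence(clinical, amyloid, None, "A_plus_T_plus", "male",
                            np.array([70]))


def test_unknown_entity_rejected():
    clinical, amyloid, tau = _toy_models()
    with pytest.raises(ValueError, match="unknown entity"):
        combined_prevalence(clinical, amyloid, tau, "N_plus", "male", np.array([70]))


@pytest.mark.parametrize("seed", [101, 202, 303])
def test_curve_invariants_hold_on_random_fitted_scenarios(seed):
    """A+T- + A+T+ = A+, MCI-or-dementia = MCI + dementia (machine precision),
    dementia >= probable AD, and all estimates within [0, 1], on pipelines
    fitted to populations drawn from randomized generating parameters."""
    rng = np.random.default_rng(seed)
    p = default_params()
    for coefs, scale in ((p.clinical_coeffs, 0.4), (p.amyloid_coeffs, 0.3),
                         (p.tau_coeffs, 0.3)):
        for k, c in coefs.items():
            coefs[k] = Coeffs(c.intercept + rng.normal(0, scale),
                              c.z + rng.normal(0, scale / 2), c.z2, c.male, c.edu)
    pop = generate_population(p, 8000, seed=seed)
    obs = simulate_observation(pop, p, seed=seed + 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_staged(obs, PipelineConfig())
    ages = np.arange(60, 91)
    for sex in ("female", "male"):
        curves = {e: fit.curve(e, sex, ages).estimates for e in ENTITIES}
        np.testing.assert_allclose(curves["A_plus_T_minus"] + curves["A_plus_T_plus"],
                                   curves["A_plus"], atol=1e-12)
        np.testing.assert_allclose(curves["MCI"] + curves["dementia"],
                                   curves["MCI_or_dementia"], atol=1e-12)
        assert np.all(curves["dementia"] >= curves["probable_AD"] - 1e-12)
        for est in curves.values():
            assert np.all((est >= 0) & (est <= 1))


def test_sex_difference_identical_curves_is_zero():
    ages = np.arange(60, 91)
    c = PrevalenceCurve("A_plus", "female", ages, np.linspace(0.2, 0.6, ages.size))
    d = sex_difference_curve(c, c)
    np.testing.assert_array_equal(d.estimates, 0.0)


def test_sex_difference_constant_curves():
    ages = np.arange(60, 91)
    men = PrevalenceCurve("MCI", "male", ages, np.full(ages.size, 0.4))
    women = PrevalenceCurve("MCI", "female", ages, np.full(ages.size, 0.3))
    np.testing.assert_allclose(sex_difference_curve(men, women).estimates, 0.1)


def test_sex_difference_grid_mismatch_rejected():
    men = PrevalenceCurve("MCI", "male", np.arange(60, 91), np.full(31, 0.4))
    women = PrevalenceCurve("MCI", "female", np.arange(60, 90), np.full(30, 0.3))
    with pytest.raises(ValueError, match="grid"):
        sex_difference_curve(men, women)


def test_generating_male_mci_excess_shows_in_difference(fit_ipw_100k):
    """The generator gives men a higher MCI logit, so the fitted
    MCI-or-dementia men-women difference must be positive at ages >= 75."""
    ages = np.arange(75, 91)
    men = fit_ipw_100k.curve("MCI_or_dementia", "male", ages)
    women = fit_ipw_100k.curve("MCI_or_dementia", "female", ages)
    assert np.all(sex_difference_curve(men, women).estimates > 0)
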