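"""Synthetic-population generator: determinism, calibration, oracle identities."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from adprev.cohort import TAU_COLUMNS
from adprev.synth import (
    Coeffs,
    StratumDesign,
    TrueModelParams,
    default_params,
    fully_observed_params,
    generate_population,
    simulate_observation,
    true_prevalence,
)


def test_same_seed_reproduces_identical_population(params_default):
    a = generate_population(params_default, 2000, seed=42)
    b = generate_population(params_default, 2000, seed=42)
    pd.testing.assert_frame_equal(a, b)


def test_same_seed_reproduces_identical_observation(params_default):
    pop = generate_population(params_default, 2000, seed=42)
    a = simulate_observation(pop, params_default, seed=7)
    b = simulate_observation(pop, params_default, seed=7)
    pd.testing.assert_frame_equal(a, b)


def test_degenerate_dementia_intercepts_give_zero_cases():
    p = default_params()
    for status in ("dementia_probable_AD", "dementia_other"):
        c = p.clinical_coeffs[status]
        p.clinical_coeffs[status] = Coeffs(-50.0, c.z, c.z2, c.male, c.edu)
    pop = generate_population(p, 20_000, seed=3)
    assert not pop["true_status"].str.startswith("dementia").any()


def test_amyloid_rate_matches_stated_bernoulli_rate():
    """With a flat P(A+ | CU) = 0.3, the empirical rate is 0.30 +/- 0.01."""
    p = default_params()
    p.amyloid_coeffs["CU"] = Coeffs(intercept=float(logit(0.3)))
    pop = generate_population(p, 200_000, seed=11)
    cu = pop[pop["true_status"] == "CU"]
    assert abs(cu["true_A"].mean() - 0.30) < 0.01


def test_enrollment_rate_matches_stated_rate():
    """Flat enrollment probability 0.8 -> enrolled fraction 0.80 +/- 0.01."""
    p = default_params()
    p.participation_coeffs["enroll"] = Coeffs(intercept=float(logit(0.8)))
    pop = generate_population(p, 100_000, seed=13)
    obs = simulate_observation(pop, p, seed=14)
    assert abs(obs["enrolled"].mean() - 0.80) < 0.01


def test_full_participation_recovers_population(params_default):
    p = fully_observed_params(params_default)
    pop = generate_population(p, 5000, seed=21)
    obs = simulate_observation(pop, p, seed=22)
    assert len(obs) == len(pop)
    assert obs["enrolled"].all()
    assert obs["has_amyloid_pet"].all() and obs["has_tau_pet"].all()
    assert (obs["clinical_status"] != "unknown").all()


def test_passive_sensitivity_one_detects_every_nonparticipant_dementia(params_default):
    pop = generate_population(params_default, 30_000, seed=31)
    obs = simulate_observation(pop, params_default, seed=32)
    truth = pop.set_index("id")["true_status"]
    nonenrolled = obs[~obs["enrolled"].astype(bool)]
    dem_mask = truth.loc[nonenrolled["id"]].str.startswith("dementia").to_numpy()
    assert (nonenrolled.loc[dem_mask, "ascertainment"] == "passive").all()
    assert (nonenrolled.loc[~dem_mask, "clinical_status"] == "unknown").all()


def test_thresholding_recovers_latent_states_exactly(params_default):
    pop = generate_population(params_default, 50_000, seed=41)
    assert ((pop["amyloid_suvr"] >= 1.48).astype(int) == pop["true_A"]).all()
    for col in TAU_COLUMNS:
        assert ((pop[col] >= 1.25).astype(int) == pop["true_T"]).all()


def test_overlap_mode_allows_misclassification():
    p = default_params()
    p.separated = False
    pop = generate_population(p, 50_000, seed=43)
    mism = ((pop["amyloid_suvr"] >= 1.48).astype(int) != pop["true_A"]).mean()
    assert 0 < mism < 0.05


def test_invalid_correlation_rejected_at_construction():
    with pytest.raises(ValueError, match="positive definite"):
        TrueModelParams(tau_roi_correlation=-0.5)


def test_true_prevalence_certain_amyloid_is_one():
    p = default_params()
    for st in p.amyloid_coeffs:
        p.amyloid_coeffs[st] = Coeffs(intercept=50.0)
    ages = np.arange(60, 91)
    np.testing.assert_allclose(true_prevalence(p, "A_plus", "female", ages), 1.0,
                               atol=1e-12)


def test_true_prevalence_two_status_hand_enumeration():
    """P(c1)=.7, P(c2)=.3; P(A+)=.2/.6; P(T+|A+)=.5/.9 -> .32/.232/.088."""
    p = default_params()
    p.education_probs = (0.0, 0.0, 1.0, 0.0)
    # multinomial logit vs CU: exp(b)/(1+exp(b)) = .3 -> b = log(.3/.7)
    p.clinical_coeffs = {
        "MCI": Coeffs(intercept=float(np.log(0.3 / 0.7))),
        "dementia_probable_AD": Coeffs(intercept=-50.0),
        "dementia_other": Coeffs(intercept=-50.0),
    }
    p.amyloid_coeffs = {s: Coeffs(intercept=float(logit(0.2))) for s in p.amyloid_coeffs}
    p.amyloid_coeffs["MCI"] = Coeffs(intercept=float(logit(0.6)))
    p.tau_coeffs = {s: Coeffs(intercept=float(logit(0.5))) for s in p.tau_coeffs}
    p.tau_coeffs["MCI"] = Coeffs(intercept=float(logit(0.9)))
    age = np.array([75])
    assert true_prevalence(p, "A_plus", "female", age)[0] == pytest.approx(0.32, abs=1e-12)
    assert true_prevalence(p, "A_plus_T_plus", "female", age)[0] == pytest.approx(0.232, abs=1e-12)
    assert true_prevalence(p, "A_plus_T_minus", "female", age)[0] == pytest.approx(0.088, abs=1e-12)


def test_entity_additivity_over_random_parameter_draws():
    rng = np.random.default_rng(99)
    ages = np.arange(60, 91)
    for _ in range(100):
        p = default_params()
        for coefs in (p.clinical_coeffs, p.amyloid_coeffs, p.tau_coeffs):
            for k in coefs:
                coefs[k] = Coeffs(*rng.normal(0, 1, size=4), tuple(rng.normal(0, 0.5, 4)))
        for sex in ("female", "male"):
            a = true_prevalence(p, "A_plus", sex, ages)
            at = true_prevalence(p, "A_plus_T_plus", sex, ages)
            an = true_prevalence(p, "A_plus_T_minus", sex, ages)
            np.testing.assert_allclose(at + an, a, atol=1e-14)
            md = true_prevalence(p, "MCI_or_dementia", sex, ages)
            m = true_prevalence(p, "MCI", sex, ages)
            d = true_prevalence(p, "dementia", sex, ages)
            np.testing.assert_allclose(m + d, md, atol=1e-14)


def test_unknown_entity_rejected(params_default):
    with pytest.raises(ValueError, match="unknown entity"):
        true_prevalence(params_default, "A_minus_T_plus", "female", 75)


def test_empirical_prevalence_matches_oracle_in_age_sex_cells(params_default):
    """Fully generated population agrees with the closed form in every 5-year
    age x sex cell for every entity, within a binomial bound that controls the
    family-wise error of the 112 simultaneous cell comparisons at 1%
    (a flat 3-SD bound would falsely reject a correct generator in about a
    quarter of runs)."""
    from scipy.stats import norm
    z_star = norm.ppf(1 - 0.01 / (2 * 112))
    pop = generate_population(params_default, 500_000, seed=0)
    status = pop["true_status"].to_numpy()
    emp = {
        "CU": status == "CU",
        "MCI": status == "MCI",
        "dementia": np.char.startswith(status.astype(str), "dementia"),
        "probable_AD": status == "dementia_probable_AD",
        "A_plus": pop["true_A"].to_numpy() == 1,
        "A_plus_T_plus": pop["true_T"].to_numpy() == 1,
    }
    emp["MCI_or_dementia"] = emp["MCI"] | emp["dementia"]
    emp["A_plus_T_minus"] = emp["A_plus"] & ~emp["A_plus_T_plus"]
    ages = pop["age"].to_numpy()
    for sex in ("female", "male"):
        sex_mask = (pop["sex"] == sex).to_numpy()
        for lo in range(60, 90, 5):
            cell = sex_mask & (ages >= lo) & (ages < lo + 5)
            n_cell = cell.sum()
            cell_truth = {e: true_prevalence(params_default, e, sex, ages[cell]).mean()
                          for e in emp}
            for entity, ind in emp.items():
                p = cell_truth[entity]
                tol = z_star * np.sqrt(max(p * (1 - p), 1e-12) / n_cell)
                assert abs(ind[cell].mean() - p) < tol, (entity, sex, lo)


def test_stratified_sampling_weights_are_inverse_fractions(params_default):
    pop = generate_population(params_default, 20_000, seed=51)
    obs = simulate_observation(pop, params_default, seed=52)
    design = params_default.stratum_design
    for lo, hi in design.bands:
        for sex in ("female", "male"):
            n_pop = ((pop["age"].between(lo, hi)) & (pop["sex"] == sex)).sum()
            sel = obs[(obs["age"].between(lo, hi)) & (obs["sex"] == sex)]
            if len(sel):
                np.testing.assert_allclose(sel["stratum_weight"], n_pop / len(sel))
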