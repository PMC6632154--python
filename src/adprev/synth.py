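"""Synthetic enumerated populations with known Alzheimer-spectrum prevalences.

The generator emulates the study design the estimator targets:

1. an enumerated population aged 60-90 with a declining age pyramid and an
   education distribution;
2. clinical status (CU / MCI / dementia, the latter split into probable AD and
   other etiologies) from a multinomial-logit model in age, age^2, sex and
   education;
3. latent amyloid (A) and tau (T) biomarker states: A ~ Bernoulli(logit) given
   status, T ~ Bernoulli(logit) given status among A+ (T+ without A+ is not
   generated — the A-T+ group is irrelevant to the entities estimated here);
4. continuous SUVR channels conditional on the latent states: log-normal
   mixture components on either side of the generating cut points; the four
   tau ROI channels share the single latent T state with correlated noise
   (Gaussian copula on the log scale).  Under the default *separated* setting
   the components are truncated at the cut points so that thresholding
   reproduces the latent states exactly; ``separated=False`` allows overlap;
5. a stratified random sample by 10-year age and sex strata with equal numbers
   of women and men per stratum, followed by three nested participation
   stages (enrollment, amyloid PET, tau PET) whose logit probabilities depend
   on sex, age and education, and passive detection of dementia among sampled
   nonparticipants.

Every probability the estimator targets has a closed form in the generating
coefficients (:func:`true_prevalence`), making the generator the oracle for
the staged estimation pipeline.

The default parameters are deliberately adversarial for unweighted
estimation: participation falls with age and low education while low
education is associated with impairment and amyloid positivity, so the
participant pool is healthier and more amyloid-negative than the population
at every age.  Inverse-probability weighting on sex, age and education
removes this bias.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm, truncnorm

from .cohort import TAU_COLUMNS, TAU_ROIS, validate_records
from ._design import EDU_LEVELS, age_z

STATUSES = ["CU", "MCI", "dementia_probable_AD", "dementia_other"]

ENTITIES = [
    "CU", "MCI", "dementia", "probable_AD", "MCI_or_dementia",
    "A_plus", "A_plus_T_minus", "A_plus_T_plus",
]


@dataclass
class Coeffs:
    """Logit coefficients over (intercept, z, z^2, male, education categories).

    z = (age - 75)/10; ``edu`` lists one offset per category in
    :data:`~adprev._design.EDU_LEVELS` order (reference handled by offsets
    themselves, so they are absolute category effects, not contrasts).
    """

    intercept: float = 0.0
    z: float = 0.0
    z2: float = 0.0
    male: float = 0.0
    edu: tuple = (0.0, 0.0, 0.0, 0.0)

    def logit(self, z, male, edu_idx):
        z = np.asarray(z, dtype=float)
        edu_eff = np.asarray(self.edu, dtype=float)[edu_idx]
        return self.intercept + self.z * z + self.z2 * z * z + self.male * np.asarray(male, dtype=float) + edu_eff


@dataclass
class SuvrMixture:
    """Two log-normal SUVR components on either side of a generating cut point."""

    cutpoint: float
    neg_meanlog: float
    neg_sdlog: float
    pos_meanlog: float
    pos_sdlog: float


@dataclass
class StratumDesign:
    """10-year age x sex sampling strata with equal numbers of women and men.

    Within each age band the target per sex is ``fraction`` times the size of
    the smaller sex; explicit per-band ``counts`` (band -> per-sex target)
    override the fraction.
    """

    bands: tuple = ((60, 69), (70, 79), (80, 90))
    fraction: float = 0.75
    counts: dict | None = None
    #: equalize women and men per band (target = fraction of the smaller sex);
    #: False samples each sex at `fraction` of its own band count
    equal_sexes: bool = True


@dataclass
class TrueModelParams:
    """Full generative parameterization — the recovery target for estimation."""

    age_range: tuple = (60, 90)
    #: P(age = a) proportional to exp(-age_decline * (a - 60))
    age_decline: float = 0.055
    #: P(male | age) = male_base + male_slope * (age - 60)
    male_base: float = 0.50
    male_slope: float = -0.004
    education_probs: tuple = (0.12, 0.30, 0.38, 0.20)
    stratum_design: StratumDesign = field(default_factory=StratumDesign)
    #: multinomial logits vs CU (reference)
    clinical_coeffs: dict = field(default_factory=dict)
    #: P(A+ | status, age, sex, edu)
    amyloid_coeffs: dict = field(default_factory=dict)
    #: P(T+ | A+, status, age)
    tau_coeffs: dict = field(default_factory=dict)
    amyloid_suvr: SuvrMixture = field(default_factory=lambda: SuvrMixture(
        cutpoint=1.48, neg_meanlog=np.log(1.30), neg_sdlog=0.05,
        pos_meanlog=np.log(1.90), pos_sdlog=0.12))
    tau_suvr: SuvrMixture = field(default_factory=lambda: SuvrMixture(
        cutpoint=1.25, neg_meanlog=np.log(1.10), neg_sdlog=0.06,
        pos_meanlog=np.log(1.50), pos_sdlog=0.10))
    #: common correlation of the 4 tau ROI channels on the log scale
    tau_roi_correlation: float = 0.9
    #: truncate SUVR components at the cut points (exact latent recovery)
    separated: bool = True
    participation_coeffs: dict = field(default_factory=dict)
    passive_sensitivity: float = 1.0

    def __post_init__(self):
        if not self.clinical_coeffs:
            self.clinical_coeffs = {
                "MCI": Coeffs(-2.25, 0.85, 0.10, 0.40, (1.5, 0.55, 0.0, -0.55)),
                "dementia_probable_AD": Coeffs(-4.0, 1.9, 0.35, 0.0, (1.7, 0.65, 0.0, -0.65)),
                "dementia_other": Coeffs(-4.7, 1.8, 0.35, 0.20, (1.7, 0.65, 0.0, -0.65)),
            }
        if not self.amyloid_coeffs:
            self.amyloid_coeffs = {
                "CU": Coeffs(-1.12, 0.55, 0.0, -0.10, (1.8, 0.7, 0.0, -0.8)),
                "MCI": Coeffs(-0.62, 0.50, 0.0, 0.0, (1.8, 0.7, 0.0, -0.8)),
                "dementia_probable_AD": Coeffs(2.4, 0.30, 0.0, 0.0, (0.0, 0.0, 0.0, 0.0)),
                "dementia_other": Coeffs(-0.30, 0.30, 0.0, 0.0, (0.0, 0.0, 0.0, 0.0)),
            }
        if not self.tau_coeffs:
            self.tau_coeffs = {
                "CU": Coeffs(-1.7, 0.65),
                "MCI": Coeffs(-0.7, 0.60),
                "dementia_probable_AD": Coeffs(2.2, 0.30),
                "dementia_other": Coeffs(0.3, 0.30),
            }
        if not self.participation_coeffs:
            self.participation_coeffs = {
                "enroll": Coeffs(0.40, -0.25, 0.0, -0.10, (-1.5, -0.65, 0.0, 0.55)),
                "amyloid_pet": Coeffs(-0.55, -0.20, 0.0, 0.05, (-0.8, -0.35, 0.0, 0.40)),
                "tau_pet": Coeffs(-0.45, -0.15, 0.0, 0.0, (-0.5, -0.2, 0.0, 0.20)),
            }
        self._validate()

    def _validate(self):
        probs = np.asarray(self.education_probs, dtype=float)
        if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("education_probs must be a probability vector")
        r = self.tau_roi_correlation
        corr = np.full((4, 4), r)
        np.fill_diagonal(corr, 1.0)
        if np.linalg.eigvalsh(corr).min() <= 0:
            raise ValueError("tau ROI correlation matrix is not positive definite")
        if not 0.0 <= self.passive_sensitivity <= 1.0:
            raise ValueError("passive_sensitivity must be in [0, 1]")
        for st in ["MCI", "dementia_probable_AD", "dementia_other"]:
            if st not in self.clinical_coeffs:
                raise ValueError(f"clinical_coeffs missing status {st}")

    def copy(self) -> "TrueModelParams":
        return copy.deepcopy(self)


def default_params(**overrides) -> TrueModelParams:
    """The default study-like scenario (biased participation, separated SUVRs)."""
    return TrueModelParams(**overrides)


def fully_observed_params(base: TrueModelParams | None = None) -> TrueModelParams:
    """Variant with sampling fraction 1 and participation probability 1 everywhere."""
    p = (base or default_params()).copy()
    p.stratum_design = StratumDesign(fraction=1.0, equal_sexes=False)
    for stage in p.participation_coeffs:
        p.participation_coeffs[stage] = Coeffs(intercept=50.0)
    return p


# ---------------------------------------------------------------------------
# closed-form probabilities


def clinical_status_probs(params: TrueModelParams, z, male, edu_idx) -> np.ndarray:
    """(n, 4) matrix of P(status | age, sex, edu), columns in STATUSES order."""
    z = np.atleast_1d(np.asarray(z, dtype=float))
    male = np.broadcast_to(np.asarray(male, dtype=float), z.shape)
    edu_idx = np.broadcast_to(np.asarray(edu_idx, dtype=int), z.shape)
    logits = np.zeros((z.size, len(STATUSES)))
    for j, st in enumerate(STATUSES[1:], start=1):
        logits[:, j] = params.clinical_coeffs[st].logit(z, male, edu_idx)
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    return p / p.sum(axis=1, keepdims=True)


def true_prevalence(params: TrueModelParams, entity: str, sex: str, age) -> np.ndarray:
    """Closed-form population prevalence of *entity* at (sex, age).

    Total-probability evaluation over clinical strata and the education
    distribution from the generating coefficients.  A_plus_T_minus +
    A_plus_T_plus = A_plus holds exactly.
    """
    if entity not in ENTITIES:
        raise ValueError(f"unknown entity {entity!r}; allowed: {ENTITIES}")
    if sex not in ("female", "male"):
        raise ValueError(f"unknown sex {sex!r}")
    age = np.atleast_1d(np.asarray(age, dtype=float))
    z = age_z(age)
    male = float(sex == "male")
    edu_p = np.asarray(params.education_probs, dtype=float)

    out = np.zeros(age.shape)
    for e_idx, w in enumerate(edu_p):
        if w == 0:
            continue
        p_status = clinical_status_probs(params, z, male, e_idx)
        if entity == "CU":
            contrib = p_status[:, 0]
        elif entity == "MCI":
            contrib = p_status[:, 1]
        elif entity == "dementia":
            contrib = p_status[:, 2] + p_status[:, 3]
        elif entity == "probable_AD":
            contrib = p_status[:, 2]
        elif entity == "MCI_or_dementia":
            contrib = p_status[:, 1:].sum(axis=1)
        else:
            contrib = np.zeros(age.shape)
            for j, st in enumerate(STATUSES):
                pA = expit(params.amyloid_coeffs[st].logit(z, male, e_idx))
                if entity == "A_plus":
                    factor = pA
                elif entity == "A_plus_T_plus":
                    factor = pA * expit(params.tau_coeffs[st].logit(z, 0.0, 0))
                else:  # A_plus_T_minus
                    factor = pA * (1.0 - expit(params.tau_coeffs[st].logit(z, 0.0, 0)))
                contrib += p_status[:, j] * factor
        out += w * contrib
    return out if out.size > 1 else out


# ---------------------------------------------------------------------------
# population generation


def _sample_suvr(rng, state: np.ndarray, mix: SuvrMixture, separated: bool,
                 normal_draws: np.ndarray | None = None) -> np.ndarray:
    """Draw SUVR values conditional on a binary latent state.

    With *separated*, each component is truncated at log(cutpoint) so that
    thresholding recovers the state exactly.  ``normal_draws`` (standard
    normal) lets the caller impose cross-channel correlation via a Gaussian
    copula: the draw is mapped through its N(0,1) CDF and re-expressed as a
    quantile of the (possibly truncated) component.
    """
    n = state.size
    zdraw = rng.standard_normal(n) if normal_draws is None else normal_draws
    logcut = np.log(mix.cutpoint)
    out = np.empty(n)
    for s, meanlog, sdlog in ((0, mix.neg_meanlog, mix.neg_sdlog),
                              (1, mix.pos_meanlog, mix.pos_sdlog)):
        m = state == s
        if not m.any():
            continue
        if separated:
            a = -np.inf if s == 0 else (logcut - meanlog) / sdlog
            b = (logcut - meanlog) / sdlog if s == 0 else np.inf
            u = norm.cdf(zdraw[m])
            # keep strictly inside (0, 1) for ppf stability
            u = np.clip(u, 1e-12, 1 - 1e-12)
            out[m] = truncnorm.ppf(u, a, b, loc=meanlog, scale=sdlog)
        else:
            out[m] = meanlog + sdlog * zdraw[m]
    vals = np.exp(out)
    if separated:
        # ppf can land exactly on the boundary; keep each component strictly
        # on its side of the cut so thresholding (abnormal iff >= cut) is exact
        neg = state == 0
        vals[neg] = np.minimum(vals[neg], mix.cutpoint * (1 - 1e-9))
        vals[~neg] = np.maximum(vals[~neg], mix.cutpoint)
    return vals


def generate_population(params: TrueModelParams, n: int, seed: int = 0) -> pd.DataFrame:
    """Generate a fully observed enumerated population of *n* individuals.

    The returned frame is a valid, fully observed cohort frame (everyone
    active, enrolled and imaged, stratum_weight 1) with the latent states
    recorded in side columns ``true_status``, ``true_A`` and ``true_T``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    lo, hi = params.age_range
    ages_all = np.arange(lo, hi + 1)
    age_w = np.exp(-params.age_decline * (ages_all - lo))
    age = rng.choice(ages_all, size=n, p=age_w / age_w.sum())
    p_male = np.clip(params.male_base + params.male_slope * (age - 60), 0.05, 0.95)
    male = (rng.uniform(size=n) < p_male).astype(int)
    edu_idx = rng.choice(4, size=n, p=np.asarray(params.education_probs))

    z = age_z(age)
    p_status = clinical_status_probs(params, z, male, edu_idx)
    u = rng.uniform(size=n)
    status_idx = np.minimum((u[:, None] > np.cumsum(p_status, axis=1)).sum(axis=1), 3)
    status = np.asarray(STATUSES, dtype=object)[status_idx]

    pA = np.empty(n)
    pT = np.empty(n)
    for j, st in enumerate(STATUSES):
        m = status_idx == j
        pA[m] = expit(params.amyloid_coeffs[st].logit(z[m], male[m], edu_idx[m]))
        pT[m] = expit(params.tau_coeffs[st].logit(z[m], 0.0, 0))
    A = (rng.uniform(size=n) < pA).astype(int)
    T = ((rng.uniform(size=n) < pT) & (A == 1)).astype(int)

    amyloid_suvr = _sample_suvr(rng, A, params.amyloid_suvr, params.separated)

    r = params.tau_roi_correlation
    corr = np.full((4, 4), r)
    np.fill_diagonal(corr, 1.0)
    chol = np.linalg.cholesky(corr)
    zmat = rng.standard_normal((n, 4)) @ chol.T
    tau_vals = {
        col: _sample_suvr(rng, T, params.tau_suvr, params.separated, normal_draws=zmat[:, k])
        for k, col in enumerate(TAU_COLUMNS)
    }

    frame = pd.DataFrame({
        "id": [f"s{i:07d}" for i in range(n)],
        "age": age.astype(int),
        "sex": np.where(male == 1, "male", "female"),
        "education": np.asarray(EDU_LEVELS, dtype=object)[edu_idx],
        "ascertainment": "active",
        "clinical_status": status,
        "enrolled": True,
        "has_amyloid_pet": True,
        "has_tau_pet": True,
        "amyloid_suvr": amyloid_suvr,
        **{col: v for col, v in tau_vals.items()},
        "stratum_weight": 1.0,
        "true_status": status,
        "true_A": A,
        "true_T": T,
    })
    return frame


def _stage_prob(params, stage, z, male, edu_idx):
    return expit(params.participation_coeffs[stage].logit(z, male, edu_idx))


def stratum_labels(age: np.ndarray, sex: np.ndarray, design: StratumDesign) -> np.ndarray:
    """Map (age, sex) to 10-year stratum labels like '70-79/female'."""
    out = np.empty(age.size, dtype=object)
    for lo, hi in design.bands:
        m = (age >= lo) & (age <= hi)
        out[m] = [f"{lo}-{hi}/{s}" for s in sex[m]]
    if (out == None).any():  # noqa: E711 — object-array sentinel check
        raise ValueError("ages outside the stratum bands")
    return out


def simulate_observation(population: pd.DataFrame, params: TrueModelParams,
                         seed: int = 1) -> pd.DataFrame:
    """Apply stratified sampling, staged participation and passive ascertainment.

    Returns the observed study frame: sampled individuals only, with
    ``stratum_weight`` set to the inverse sampling fraction of their 10-year
    age x sex stratum, imaging values revealed only where participation
    allows, nonparticipants' diagnoses masked to ``unknown`` except for
    dementia cases detected passively (probability ``passive_sensitivity``).
    The output validates under the cohort-model invariants.
    """
    rng = np.random.default_rng(seed)
    n = len(population)
    age = population["age"].to_numpy()
    sexes = population["sex"].to_numpy()
    male = (sexes == "male").astype(float)
    edu_idx = np.asarray(
        [EDU_LEVELS.index(e) if isinstance(e, str) else 2 for e in population["education"]])
    z = age_z(age)

    design = params.stratum_design
    labels = stratum_labels(age, sexes, design)
    sampled = np.zeros(n, dtype=bool)
    weight = np.ones(n)
    for lo, hi in design.bands:
        band = (age >= lo) & (age <= hi)
        nf = int((band & (male == 0)).sum())
        nm = int((band & (male == 1)).sum())
        for sx, count in (("female", nf), ("male", nm)):
            if design.counts is not None:
                target = int(design.counts[(lo, hi)])
            elif design.equal_sexes:
                target = int(round(design.fraction * min(nf, nm)))
            else:
                target = int(round(design.fraction * count))
            idx = np.flatnonzero(band & (sexes == sx))
            take = min(target, count)
            if take == 0:
                continue
            chosen = rng.choice(idx, size=take, replace=False)
            sampled[chosen] = True
            weight[idx] = count / take

    p_enroll = _stage_prob(params, "enroll", z, male, edu_idx)
    p_amy = _stage_prob(params, "amyloid_pet", z, male, edu_idx)
    p_tau = _stage_prob(params, "tau_pet", z, male, edu_idx)
    enrolled = sampled & (rng.uniform(size=n) < p_enroll)
    has_amy = enrolled & (rng.uniform(size=n) < p_amy)
    has_tau = has_amy & (rng.uniform(size=n) < p_tau)

    true_status = population["true_status"].to_numpy(dtype=object)
    is_dem = np.isin(true_status, ["dementia_probable_AD", "dementia_other"])
    passive = sampled & ~enrolled & is_dem & (rng.uniform(size=n) < params.passive_sensitivity)

    obs = population.loc[sampled, [c for c in population.columns if not c.startswith("true_")]].copy()
    keep = sampled
    obs["stratum_weight"] = weight[keep]
    obs["enrolled"] = enrolled[keep]
    obs["has_amyloid_pet"] = has_amy[keep]
    obs["has_tau_pet"] = has_tau[keep]
    status_obs = np.where(enrolled | passive, true_status, "unknown")[keep]
    obs["clinical_status"] = status_obs
    asc = np.where(enrolled, "active", np.where(passive, "passive", "nonparticipant"))[keep]
    obs["ascertainment"] = asc
    obs.loc[~obs["has_amyloid_pet"], "amyloid_suvr"] = np.nan
    for col in TAU_COLUMNS:
        obs.loc[~obs["has_tau_pet"], col] = np.nan
    obs = obs.reset_index(drop=True)
    validate_records(obs)
    return obs
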