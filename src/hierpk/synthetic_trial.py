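"""Synthetic trial generator.

Emulates the study design the analysis assumes: 22 women with type 1
diabetes on insulin-pump therapy, each observed on two visits with an evening
meal on day 1 (window 17:30-23:00, bolus at 18:00) and a morning meal on
day 2 (window 06:30-12:00, bolus at 07:00); basal infusion around 0.6 U/h,
prandial boluses around 8.9 U delivered over 1 min (a few over longer
periods); plasma insulin sampled every 10 min for 90 min post-meal, every
15 min from 1.5 to 5 h post-meal and at 30-min intervals otherwise within the
window.  Thirteen clinical/demographic factors are drawn to match the trial's
descriptive summaries.

Profile-level kinetic parameters are drawn from the same population model the
inference modules fit (log-normal for t_max and MCR, normal for a and b, with
woman / visit / meal intercept levels and optional covariate effects), and
observations from the heteroscedastic Gaussian observation model.  The ground
truth is recorded exactly as used, for recovery testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import pk_model
from .pk_model import DosingSchedule, ProfileContext
from .population_model import LOGNORMAL_PARAMS, ModelSpec
from .trial_data import (
    BREAKFAST,
    DINNER,
    Dataset,
    Profile,
    ProfileKey,
    build_design,
)

__all__ = ["TrialDesign", "GroundTruth", "generate_trial", "sampling_times"]

MIN_PER_DAY = 1440.0

COVARIATE_SCHEMA = {
    "continuous": [
        "age",
        "bmi",
        "hba1c",
        "diabetes_duration",
        "gestation",
        "expected_daily_dose",
        "peak_bolus_rate",
    ],
    "binary": ["kings_college", "long_bolus", "multiple_boluses", "closed_loop"],
    "study": "study1",
    "mealtime": "breakfast",
}

# stage-1 prior supports; the generator warns if the design makes excursions
# beyond them non-negligible
TMAX_SUPPORT = (5.0, 500.0)
MCR_SUPPORT = (0.0, 0.25)


@dataclass(frozen=True)
class TrialDesign:
    """Generative settings; defaults reproduce the trial's reported scale.

    Population truth: phi are the global intercepts (log-scale for t_max and
    MCR), sigma_* the sd of each hierarchy component, and beta_true maps
    (parameter index, design column name) to a coefficient on the
    standardized-covariate scale.  The default truth is a three-level (visit)
    model with the study's typical magnitudes (t_max about 55 min, MCR about
    0.025 l/kg/min) and a faster absorption after the second study's
    breakfast.
    """

    n_women: int = 22
    visits_per_woman: int = 2
    meals_per_visit: int = 2
    n_study1_women: int = 10

    # dosing (U/h and U; converted to mU internally)
    basal_median_u_per_h: float = 0.6
    basal_log_sd: float = 0.6
    bolus_median_u: float = 8.9
    bolus_log_sd: float = 0.46
    long_bolus_duration_min: float = 15.0

    # schedule (minutes since midnight day 1)
    dinner_time: float = 18 * 60.0
    dinner_window: tuple[float, float] = (17.5 * 60.0, 23 * 60.0)
    breakfast_time: float = MIN_PER_DAY + 7 * 60.0
    breakfast_window: tuple[float, float] = (
        MIN_PER_DAY + 6.5 * 60.0,
        MIN_PER_DAY + 12 * 60.0,
    )

    # population model truth
    level: str = "threeV"
    phi: tuple[float, float, float, float] = (np.log(55.0), np.log(0.025), -0.03, 31.0)
    sigma_theta: tuple[float, float, float, float] = (0.10, 0.06, 0.03, 6.0)
    sigma_psi: tuple[float, float, float, float] = (0.12, 0.10, 0.02, 7.0)
    sigma_chi: tuple[float, float, float, float] = (0.10, 0.06, 0.02, 5.0)
    beta_true: tuple[tuple[int, str, float], ...] = (
        (0, "study2_breakfast", -0.31),
        (0, "gestation", 0.11),
        (0, "diabetes_duration", -0.095),
        (1, "study2_breakfast", 0.11),
        (2, "study2_breakfast", 0.09),
        (2, "multiple_boluses", 0.12),
    )

    # residual error per profile
    kappa_median: float = 4.0
    kappa_log_sd: float = 0.3
    lam_range: tuple[float, float] = (0.03, 0.08)

    unit_conversion: float = 6.0

    def __post_init__(self):
        if min(self.n_women, self.visits_per_woman, self.meals_per_visit) < 1:
            raise ValueError("all design counts must be >= 1")
        if self.meals_per_visit > 2:
            raise ValueError("at most two meals (dinner, breakfast) per visit")
        if not (0 <= self.n_study1_women <= self.n_women):
            raise ValueError("n_study1_women out of range")
        if not (self.dinner_window[0] <= self.dinner_time < self.dinner_window[1]):
            raise ValueError("dinner_time outside its window")
        if not (
            self.breakfast_window[0] <= self.breakfast_time < self.breakfast_window[1]
        ):
            raise ValueError("breakfast_time outside its window")


@dataclass
class GroundTruth:
    """Everything the generator actually used, recorded for recovery tests."""

    design: TrialDesign
    spec: ModelSpec
    phi: np.ndarray
    sigma_theta: np.ndarray
    sigma_psi: np.ndarray
    sigma_chi: np.ndarray
    beta: dict[tuple[int, str], float]
    theta: pd.DataFrame  # per profile: t_max, MCR, a, b
    nuisance: pd.DataFrame  # per profile: kappa, lambda
    psi: np.ndarray | None = None
    chi: np.ndarray | None = None


def sampling_times(
    meal_time: float, window: tuple[float, float]
) -> np.ndarray:
    """Observation schedule within a meal window.

    10-min grid on (meal, meal+90], 15-min grid on (meal+90, meal+300],
    30-min grid elsewhere in the window (before the meal and beyond 5 h
    post-meal); deduplicated, strictly increasing, clipped to the window.
    """
    lo, hi = float(window[0]), float(window[1])
    if not lo <= meal_time < hi:
        raise ValueError("meal_time must lie inside the window")
    times: list[float] = []
    t = lo
    while t < meal_time:  # pre-meal, 30-min spacing
        times.append(t)
        t += 30.0
    t = meal_time + 10.0
    while t <= min(meal_time + 90.0, hi):
        times.append(t)
        t += 10.0
    t = meal_time + 105.0
    while t <= min(meal_time + 300.0, hi):
        times.append(t)
        t += 15.0
    t = meal_time + 330.0
    while t <= hi:
        times.append(t)
        t += 30.0
    out = np.unique(np.array(times))
    return out[(out >= lo) & (out <= hi)]


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _sample_covariates(design: TrialDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Per-profile factor table matched to the trial's descriptive summaries."""
    rows = []
    nw = design.n_women
    study1_women = set(rng.choice(nw, size=design.n_study1_women, replace=False).tolist())
    kings = set(rng.choice(nw, size=min(max(round(nw * 5 / 22), 0), nw), replace=False).tolist())
    for w in range(nw):
        age = _truncated_normal(rng, 32.0, 4.5, 18.0, 45.0)
        bmi = _truncated_normal(rng, 27.0, 3.3, 18.0, 45.0)
        hba1c = _truncated_normal(rng, 7.1, 1.0, 5.0, 12.0)
        duration = _truncated_normal(rng, 18.0, 8.6, 1.0, 40.0)
        daily_dose = _truncated_normal(rng, 55.0, 18.0, 10.0, 120.0)
        height = rng.normal(1.65, 0.06)
        for v in range(1, design.visits_per_woman + 1):
            gestation = _truncated_normal(rng, 22.0, 6.5, 6.0, 40.0)
            for meal in (DINNER, BREAKFAST)[: design.meals_per_visit]:
                key = ProfileKey(w, v, meal)
                rows.append(
                    dict(
                        profile_id=key.id,
                        age=age,
                        bmi=bmi,
                        hba1c=hba1c,
                        diabetes_duration=duration,
                        gestation=gestation,
                        expected_daily_dose=daily_dose,
                        peak_bolus_rate=_truncated_normal(rng, 9.3, 5.0, 0.5, 40.0),
                        kings_college=float(w in kings),
                        long_bolus=float(rng.random() < 8 / 88),
                        multiple_boluses=float(rng.random() < 17 / 88),
                        closed_loop=float(rng.random() < 24 / 88),
                        study1=float(w in study1_women),
                        breakfast=float(meal == BREAKFAST),
                        _weight=bmi * height**2,
                    )
                )
    return pd.DataFrame(rows).set_index("profile_id")


def generate_trial(
    design: TrialDesign | None = None, seed: int = 0
) -> tuple[Dataset, GroundTruth]:
    """Generate a complete synthetic dataset plus its ground truth.

    Fully reproducible from ``seed``: the master seed spawns independent
    per-stage and per-profile streams, so subsetting profiles leaves the
    others' data unchanged.
    """
    design = design or TrialDesign()
    ss = np.random.SeedSequence(seed)
    cov_ss, pop_ss, obs_ss = ss.spawn(3)

    factors = _sample_covariates(design, np.random.default_rng(cov_ss))
    weights = factors.pop("_weight")
    cov_design = build_design(factors, COVARIATE_SCHEMA)
    n = len(factors)
    pids = list(factors.index)
    keys = [ProfileKey.from_id(p) for p in pids]

    spec = ModelSpec(level=design.level, covariates_on=bool(design.beta_true))
    phi = np.array(design.phi)
    sig_th = np.array(design.sigma_theta)
    sig_ps = np.array(design.sigma_psi)
    sig_ch = np.array(design.sigma_chi)
    beta = {(l, name): val for l, name, val in design.beta_true}

    # covariate contribution on the linear-predictor scale
    wb = np.zeros((n, 4))
    col_of = {nm: i for i, nm in enumerate(cov_design.names)}
    for (l, name), val in beta.items():
        wb[:, l] += val * cov_design.X[:, col_of[name]]

    rng_pop = np.random.default_rng(pop_ss)
    women = sorted({k.woman for k in keys})
    w_of = {w: i for i, w in enumerate(women)}
    psi = chi = None
    if spec.n_levels >= 2:
        psi = phi + rng_pop.normal(size=(len(women), 4)) * sig_ps
    if spec.n_levels == 3:
        cell_key = (
            (lambda k: (k.woman, k.visit))
            if design.level == "threeV"
            else (lambda k: (k.woman, k.meal))
        )
        cells = sorted({cell_key(k) for k in keys})
        c_of = {c: i for i, c in enumerate(cells)}
        chi = np.array(
            [psi[w_of[w]] + rng_pop.normal(size=4) * sig_ch for w, _ in cells]
        )
        base = np.array([chi[c_of[cell_key(k)]] for k in keys])
    elif spec.n_levels == 2:
        base = np.array([psi[w_of[k.woman]] for k in keys])
    else:
        base = np.tile(phi, (n, 1))

    eta = base + wb
    _warn_if_support_excursions(eta, sig_th)
    theta = np.empty((n, 4))
    for l in range(4):
        z = eta[:, l] + rng_pop.normal(size=n) * sig_th[l]
        if l in LOGNORMAL_PARAMS:
            theta[:, l] = np.exp(z)
        else:
            theta[:, l] = z
    # clip the vanishingly rare draw outside the physiological support
    theta[:, 0] = np.clip(theta[:, 0], TMAX_SUPPORT[0] * 1.001, TMAX_SUPPORT[1] * 0.999)
    theta[:, 1] = np.clip(theta[:, 1], 1e-4, MCR_SUPPORT[1] * 0.999)

    kappa = np.exp(np.log(design.kappa_median) + rng_pop.normal(size=n) * design.kappa_log_sd)
    kappa = np.clip(kappa, 0.5, 99.0)
    lam = rng_pop.uniform(*design.lam_range, size=n)

    profile_ss = obs_ss.spawn(n)
    profiles: dict[str, Profile] = {}
    for i, (pid, key) in enumerate(zip(pids, keys)):
        rng = np.random.default_rng(profile_ss[i])
        if key.meal == DINNER:
            meal_time, window = design.dinner_time, design.dinner_window
        else:
            meal_time, window = design.breakfast_time, design.breakfast_window
        basal_rate_u_h = np.exp(
            np.log(design.basal_median_u_per_h) + rng.normal() * design.basal_log_sd
        )
        dose_u = np.exp(np.log(design.bolus_median_u) + rng.normal() * design.bolus_log_sd)
        duration = (
            design.long_bolus_duration_min if factors.loc[pid, "long_bolus"] else 1.0
        )
        boluses = [(meal_time, duration, dose_u * 1000.0)]
        if factors.loc[pid, "multiple_boluses"]:
            boluses.append((meal_time + 45.0, 1.0, 0.5 * dose_u * 1000.0))
        dosing = DosingSchedule(
            basal_segments=((0.0, window[1], basal_rate_u_h * 1000.0 / 60.0),),
            bolus_events=tuple(boluses),
        )
        times = sampling_times(meal_time, window)
        ctx = ProfileContext(
            wt=float(weights.loc[pid]),
            t_end=meal_time + 300.0,
            t_start=window[0],
            unit_conversion=design.unit_conversion,
        )
        params = pk_model.KineticParams(*theta[i])
        q2 = pk_model.q2_at(dosing, params.t_max, times, profile_id=pid)
        mu = pk_model.predicted_concentration(params, ctx, times, q2)
        y = mu + rng.normal(size=len(times)) * np.sqrt(
            kappa[i] ** 2 + lam[i] ** 2 * mu**2
        )
        profiles[pid] = Profile(
            key=key,
            times=times,
            concentrations=y,
            dosing=dosing,
            context=ctx,
            meal_time=meal_time,
        )

    dataset = Dataset(
        profiles=profiles,
        design=cov_design,
        raw_factors=factors,
        schema=COVARIATE_SCHEMA,
    )
    truth = GroundTruth(
        design=design,
        spec=spec,
        phi=phi,
        sigma_theta=sig_th,
        sigma_psi=sig_ps,
        sigma_chi=sig_ch,
        beta=beta,
        theta=pd.DataFrame(theta, index=pids, columns=["t_max", "MCR", "a", "b"]),
        nuisance=pd.DataFrame(
            np.column_stack([kappa, lam]), index=pids, columns=["kappa", "lambda"]
        ),
        psi=psi,
        chi=chi,
    )
    return dataset, truth


def _warn_if_support_excursions(eta: np.ndarray, sigma_theta: np.ndarray) -> None:
    """Warn when the truth puts non-negligible mass outside the independent-fit
    prior supports (probability > 1e-3 for any profile)."""
    z_lo = (np.log(TMAX_SUPPORT[0]) - eta[:, 0]) / sigma_theta[0]
    z_hi = (np.log(TMAX_SUPPORT[1]) - eta[:, 0]) / sigma_theta[0]
    p_out = stats.norm.cdf(z_lo) + stats.norm.sf(z_hi)
    z_hi_m = (np.log(MCR_SUPPORT[1]) - eta[:, 1]) / sigma_theta[1]
    p_out = np.maximum(p_out, stats.norm.sf(z_hi_m))
    if np.any(p_out > 1e-3):
        warnings.warn(
            "design places non-negligible kinetic-parameter mass outside the "
            "independent-fit prior supports",
            stacklevel=3,
        )
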