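"""Leave-one-profile-out model criticism on the random-effect scale.

Assessing the population model through the response data would bury random-
effect disagreement under observation error, so the discrepancy is defined on
the kinetic parameters themselves: for each profile in turn, the hierarchical
model is refitted with that profile excluded (only the cheap second stage is
repeated — the stored first-stage draws are reused untouched) and the
profile's "predicted" random effects are simulated from the resulting
predictive prior

    p(theta_pred | y_without) = Int p(theta_pred | Omega) p(Omega | y_without) dOmega.

Its "observed" random effects are unobservable, so the profile's own
first-stage posterior draws stand in for them.  The Bayesian p-value

    P = Pr(theta_pred - theta_obs <= 0 | y)

is estimated per kinetic parameter by independently pairing resampled
predictive and observed draws.  Under the true sampling model the p-values
are (approximately) uniform — though not independent — so departures show up
in quantile-quantile plots against Uniform(0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .population_model import LOGNORMAL_PARAMS, ModelSpec
from .stage1_mcmc import Stage1Store
from .stage2_mcmc import Stage2Config, Stage2Draws, run_stage2
from .trial_data import Dataset

__all__ = [
    "CrossvalResult",
    "predictive_prior_draws",
    "bayes_pvalue",
    "loo_assessment",
    "qq_uniform",
]

PARAM_NAMES = ("t_max", "MCR", "a", "b")


@dataclass
class CrossvalResult:
    """Bayesian p-values per (profile, kinetic parameter) plus metadata."""

    pvalues: pd.DataFrame  # index: profile id; columns: t_max, MCR, a, b
    spec: ModelSpec
    n_pred: int
    n_obs: int
    seed: int

    def flat(self) -> np.ndarray:
        return self.pvalues.to_numpy().ravel()


def predictive_prior_draws(
    omitted_id: str,
    draws: Stage2Draws,
    dataset: Dataset,
    rng: np.random.Generator,
    n_pred: int | None = None,
) -> np.ndarray:
    """Simulate theta_pred for the omitted profile from the predictive prior.

    One population draw is resampled (with replacement) per predictive draw.
    The omitted profile's linear predictor uses its own covariate row.  For
    hierarchical intercepts, fitted values are used whenever a sibling
    profile identified them in the reduced fit; otherwise the intercept is
    drawn fresh from its population distribution, following the predictive-
    prior integral literally.
    """
    key = dataset.profiles[omitted_id].key
    spec = draws.spec
    S = draws.n_draws
    n_pred = n_pred or S
    take = rng.integers(S, size=n_pred)

    # covariate contribution from each sampled population state
    wb = np.zeros((n_pred, 4))
    if spec.covariates_on and draws.incl is not None:
        x_row = dataset.design.rows_for([omitted_id])[0]
        b = np.where(draws.incl, np.nan_to_num(draws.beta), 0.0)  # (S, 4, c)
        wb = b[take] @ x_row

    w_pos = draws.women.index(key.woman) if key.woman in draws.women else None
    if spec.level == "one":
        base = draws.phi[take]
    else:
        if w_pos is not None:
            psi = draws.psi[take, w_pos]  # (n_pred, 4)
        else:
            psi = draws.phi[take] + rng.standard_normal((n_pred, 4)) * draws.sigma_psi[take]
        if spec.level == "two":
            base = psi
        else:
            cell = (key.woman, key.visit if spec.level == "threeV" else key.meal)
            if cell in draws.cells:
                base = draws.chi[take, draws.cells.index(cell)]
            else:
                base = psi + rng.standard_normal((n_pred, 4)) * draws.sigma_chi[take]

    eta = base + wb
    z = eta + rng.standard_normal((n_pred, 4)) * draws.sigma_theta[take]
    theta = z.copy()
    theta[:, 0] = np.exp(z[:, 0])
    theta[:, 1] = np.exp(z[:, 1])
    return theta


def bayes_pvalue(
    pred_draws: np.ndarray,
    obs_draws: np.ndarray,
    rng: np.random.Generator,
    n_pairs: int | None = None,
) -> np.ndarray:
    """P = Pr(theta_pred - theta_obs <= 0) per column.

    Pairs are formed by independent uniform resampling (with replacement) of
    the two draw sets.
    """
    pred_draws = np.atleast_2d(np.asarray(pred_draws, dtype=float))
    obs_draws = np.atleast_2d(np.asarray(obs_draws, dtype=float))
    if len(pred_draws) == 0 or len(obs_draws) == 0:
        raise ValueError("both draw sets must be non-empty")
    n_pairs = n_pairs or max(len(pred_draws), len(obs_draws))
    ip = rng.integers(len(pred_draws), size=n_pairs)
    io = rng.integers(len(obs_draws), size=n_pairs)
    return (pred_draws[ip] - obs_draws[io] <= 0.0).mean(axis=0)


def loo_assessment(
    store: Stage1Store,
    dataset: Dataset,
    spec: ModelSpec | None = None,
    config: Stage2Config | None = None,
    seed: int = 0,
    n_pred: int | None = None,
) -> CrossvalResult:
    """Leave-one-out p-values for every included profile.

    Each omission triggers one second-stage refit only; the first stage is
    never re-run.  Deterministic given ``seed``.
    """
    spec = spec or ModelSpec()
    config = config or Stage2Config()
    pids = [p for p in dataset.included_ids if p in store.entries]
    ss = np.random.SeedSequence(seed)
    refit_seeds = ss.generate_state(len(pids)) % (2**31 - 1)
    rng = np.random.default_rng(ss.spawn(1)[0])

    rows = {}
    n_pred_used = n_obs_used = 0
    for pid, s in zip(pids, refit_seeds):
        fit = run_stage2(store, dataset, spec, config, int(s), exclude=(pid,))
        pred = predictive_prior_draws(pid, fit, dataset, rng, n_pred=n_pred)
        obs = store.entries[pid].draws[:, :4]
        rows[pid] = bayes_pvalue(pred, obs, rng)
        n_pred_used, n_obs_used = len(pred), len(obs)

    return CrossvalResult(
        pvalues=pd.DataFrame.from_dict(rows, orient="index", columns=PARAM_NAMES),
        spec=spec,
        n_pred=n_pred_used,
        n_obs=n_obs_used,
        seed=seed,
    )


def qq_uniform(p_values) -> dict:
    """Quantile-quantile data and KS statistic against Uniform(0, 1).

    Returns plot-ready arrays (theoretical quantiles i/(n+1) vs ordered
    p-values) plus the Kolmogorov-Smirnov statistic and its p-value.  The
    p-values are not independent across profiles, so the KS test is a guide
    rather than an exact size-alpha test.
    """
    p = np.sort(np.asarray(p_values, dtype=float).ravel())
    n = len(p)
    if n == 0:
        raise ValueError("no p-values supplied")
    res = stats.kstest(p, "uniform")
    return dict(
        theoretical=(np.arange(1, n + 1)) / (n + 1),
        empirical=p,
        ks_statistic=float(res.statistic),
        ks_pvalue=float(res.pvalue),
    )
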