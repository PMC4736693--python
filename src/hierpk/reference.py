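"""Direct single-stage sampler for the one-level hierarchical model.

Fits the joint model — profile likelihoods, population distribution and
hyperpriors — in a single MCMC that evaluates the ODE likelihood at every
profile-parameter proposal (componentwise random-walk Metropolis per profile,
Gibbs for the global means, slice sampling for the sds).  This is the slow,
classical route the two-stage scheme is designed to avoid; it is kept as an
independent reference implementation so the equivalence of the two routes can
be verified on small datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels, pk_model
from .population_model import LOGNORMAL_PARAMS, PHI_PRIOR_SD
from .stage1_mcmc import _INIT_SCALES, _initial_u
from .stage2_mcmc import gibbs_normal_mean, slice_update_sd
from .trial_data import Dataset

__all__ = ["JointConfig", "JointDraws", "fit_joint_onelevel"]


@dataclass(frozen=True)
class JointConfig:
    burn_in: int = 5000
    iterations: int = 40000
    thin: int = 10

    def __post_init__(self):
        if self.burn_in < 0 or self.iterations <= 0 or self.thin < 1:
            raise ValueError("invalid chain lengths")


@dataclass
class JointDraws:
    phi: np.ndarray  # (S, 4)
    sigma_theta: np.ndarray  # (S, 4)
    theta: np.ndarray  # (S, n, 4) natural scale
    profile_ids: list[str]


def fit_joint_onelevel(
    dataset: Dataset, config: JointConfig | None = None, seed: int = 0
) -> JointDraws:
    """Single-stage fit of the one-level model without covariates.

    theta_ijkl ~ LN/N(phi_l, sigma_theta_l^2) with the standard hyperpriors;
    profile parameters are updated against the full ODE likelihood.
    """
    config = config or JointConfig()
    pids = dataset.included_ids
    profiles = [dataset.profiles[p] for p in pids]
    n = len(profiles)
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    total = config.burn_in + config.iterations
    kernel_seeds = rng.integers(0, 2**31 - 1, size=(total, n))

    # pre-extract arrays per profile
    data = []
    for prof in profiles:
        brk, rates = prof.dosing.piecewise_rates(float(prof.times[-1]))
        data.append(
            (
                prof.concentrations,
                prof.times,
                brk,
                rates,
                prof.context.wt,
                prof.context.t_end,
                prof.context.unit_conversion,
            )
        )

    u = np.stack([_initial_u(rng, prof, "heuristic") for prof in profiles])
    scales = np.tile(_INIT_SCALES, (n, 1))
    phi = np.array([np.log(60.0), np.log(0.025), 0.0, 30.0])
    sigma = np.array([0.3, 0.3, 0.1, 10.0])

    S = config.iterations // config.thin
    out_phi = np.empty((S, 4))
    out_sig = np.empty((S, 4))
    out_theta = np.empty((S, n, 4))
    theta_nat = np.empty((n, 6))
    stored = 0

    for it in range(total):
        adapting = it < config.burn_in
        for i in range(n):
            y, t, brk, rates, wt, tend, conv = data[i]
            pk_model._count_ode_call()
            draws, acc, _, u_new, status = _kernels.mh_chain(
                y, t, brk, rates, wt, tend, conv,
                u[i], scales[i], 0, 1, 1,
                int(kernel_seeds[it, i]),
                phi, sigma, 1,
                pk_model.DEFAULT_RTOL, pk_model.DEFAULT_ATOL, 0,
            )
            if status != 0:
                raise pk_model.IntegrationFailure(
                    "integration failed in joint sampler", pids[i]
                )
            u[i] = u_new
            theta_nat[i] = draws[0]
            if adapting:
                gain = min(0.25, 10.0 / (20.0 + it) ** 0.7)
                scales[i] *= np.exp(gain * (acc - 0.44))
                np.clip(scales[i], 1e-6, 1e4, out=scales[i])

        # random-effect scale values
        v = theta_nat[:, :4].copy()
        v[:, 0] = np.log(v[:, 0])
        v[:, 1] = np.log(v[:, 1])
        for l in range(4):
            phi[l] = gibbs_normal_mean(
                0.0, PHI_PRIOR_SD[l], v[:, l].sum(), n, sigma[l], rng
            )
            sigma[l] = slice_update_sd(
                sigma[l], n, float(((v[:, l] - phi[l]) ** 2).sum()), rng
            )

        if it >= config.burn_in and (it - config.burn_in) % config.thin == config.thin - 1:
            out_phi[stored] = phi
            out_sig[stored] = sigma
            out_theta[stored] = theta_nat[:, :4]
            stored += 1

    return JointDraws(
        phi=out_phi, sigma_theta=out_sig, theta=out_theta, profile_ids=list(pids)
    )
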