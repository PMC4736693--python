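"""Independent per-profile posterior sampling (first stage).

Each profile is fitted on its own under deliberately flat priors — uniform
over physiologically plausible ranges for t_max, MCR and the error
parameters, diffuse normals for the residual-insulin terms a and b — using a
componentwise adaptive random-walk Metropolis sampler on transformed scales
(log t_max; logit of MCR/0.25, kappa/100 and lambda; identity for a, b).
Proposal scales adapt toward 0.44 acceptance during burn-in only.  The stored
posterior draws later serve as Metropolis-Hastings proposal pools in the
hierarchical stage, which is what makes wide population-model exploration
cheap: the likelihood never has to be evaluated again.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import _kernels, pk_model
from .pk_model import IntegrationFailure
from .trial_data import Dataset, Profile

__all__ = [
    "Stage1Prior",
    "Stage1Config",
    "Stage1Entry",
    "Stage1Store",
    "run_stage1",
    "run_stage1_dataset",
    "bgr_diagnostic",
    "fit_diagnostics",
    "unfittable_flags",
]

PARAM_COLS = ("t_max", "MCR", "a", "b", "kappa", "lambda")


@dataclass(frozen=True)
class Stage1Prior:
    """Flat first-stage priors.

    t_max ~ U(5, 500) min; MCR ~ U(0, 0.25) l/kg/min; a, b ~ N(0, 100^2);
    kappa ~ U(0, 100) pmol/l; lambda ~ U(0, 1).  The uniform bounds are the
    physiologically plausible ranges and are fixed (the sampling kernel
    enforces them exactly); only the a/b prior sds are recorded here because
    they enter the second-stage acceptance ratio.
    """

    tmax_bounds: tuple[float, float] = (5.0, 500.0)
    mcr_bounds: tuple[float, float] = (0.0, 0.25)
    ab_prior_sd: float = 100.0
    kappa_bounds: tuple[float, float] = (0.0, 100.0)
    lam_bounds: tuple[float, float] = (0.0, 1.0)

    def log_density_ab(self, a, b):
        """The non-constant part of log p1(theta): the N(0, sd^2) terms for
        a and b (uniform components cancel in any within-support ratio)."""
        s2 = self.ab_prior_sd**2
        return -0.5 * (np.asarray(a) ** 2 + np.asarray(b) ** 2) / s2


@dataclass(frozen=True)
class Stage1Config:
    """Run configuration.  The production-scale setting used in the original
    workflow (10^6 iterations, thin 100) is available by construction; the
    default here is a scaled-down configuration adequate for synthetic
    studies."""

    burn_in: int = 5000
    iterations: int = 20000
    thin: int = 20
    n_chains: int = 2
    rtol: float = pk_model.DEFAULT_RTOL
    atol: float = pk_model.DEFAULT_ATOL
    init: str = "prior"  # "prior" (widely dispersed) or "heuristic"

    def __post_init__(self):
        if self.burn_in < 0 or self.iterations <= 0 or self.thin < 1:
            raise ValueError("invalid chain lengths")
        if self.iterations % self.thin:
            raise ValueError("iterations must be a multiple of thin")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")


@dataclass
class Stage1Entry:
    """Stored posterior draws and metadata for one profile."""

    profile_id: str
    draws: np.ndarray  # (H, 6): t_max, MCR, a, b, kappa, lambda
    chain_draws: np.ndarray  # (n_chains, H/n_chains, 6)
    bgr: np.ndarray  # (6,) potential scale reduction per parameter
    acceptance: np.ndarray  # (n_chains, 6)
    seed: int
    flags: tuple[str, ...] = ()

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def medians(self) -> np.ndarray:
        return np.median(self.draws, axis=0)


@dataclass
class Stage1Store:
    """Per-profile posterior draws plus regeneration metadata."""

    entries: dict[str, Stage1Entry]
    config: Stage1Config
    prior: Stage1Prior = field(default_factory=Stage1Prior)

    def __post_init__(self):
        for pid, e in self.entries.items():
            if e.n_draws < 1:
                raise ValueError(f"profile {pid}: empty draw store")

    @property
    def profile_ids(self) -> list[str]:
        return list(self.entries)

    def theta_draws(self, profile_ids=None) -> np.ndarray:
        """Stacked (n_profiles, H, 4) kinetic-parameter draws (uniform H)."""
        pids = profile_ids if profile_ids is not None else self.profile_ids
        return np.stack([self.entries[p].draws[:, :4] for p in pids])

    def nuisance_draws(self, profile_ids=None) -> np.ndarray:
        pids = profile_ids if profile_ids is not None else self.profile_ids
        return np.stack([self.entries[p].draws[:, 4:] for p in pids])

    def medians(self, profile_ids=None) -> np.ndarray:
        pids = profile_ids if profile_ids is not None else self.profile_ids
        return np.stack([self.entries[p].medians() for p in pids])

    def save(self, path: str | Path) -> None:
        path = Path(path)
        meta = dict(
            version=1,
            config=asdict(self.config),
            prior=asdict(self.prior),
            profiles={
                pid: dict(seed=e.seed, flags=list(e.flags)) for pid, e in self.entries.items()
            },
        )
        arrays = {"_meta": np.array(json.dumps(meta))}
        for pid, e in self.entries.items():
            arrays[f"draws:{pid}"] = e.draws
            arrays[f"chains:{pid}"] = e.chain_draws
            arrays[f"bgr:{pid}"] = e.bgr
            arrays[f"acc:{pid}"] = e.acceptance
        np.savez_compressed(path, **arrays)

    @staticmethod
    def load(path: str | Path) -> "Stage1Store":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["_meta"]))
            entries = {}
            for pid, info in meta["profiles"].items():
                entries[pid] = Stage1Entry(
                    profile_id=pid,
                    draws=z[f"draws:{pid}"],
                    chain_draws=z[f"chains:{pid}"],
                    bgr=z[f"bgr:{pid}"],
                    acceptance=z[f"acc:{pid}"],
                    seed=info["seed"],
                    flags=tuple(info["flags"]),
                )
        cfg = meta["config"]
        for k in ("burn_in", "iterations", "thin", "n_chains"):
            cfg[k] = int(cfg[k])
        prior = meta["prior"]
        return Stage1Store(
            entries=entries,
            config=Stage1Config(
                burn_in=cfg["burn_in"],
                iterations=cfg["iterations"],
                thin=cfg["thin"],
                n_chains=cfg["n_chains"],
                rtol=float(cfg["rtol"]),
                atol=float(cfg["atol"]),
                init=str(cfg["init"]),
            ),
            prior=Stage1Prior(
                tmax_bounds=tuple(prior["tmax_bounds"]),
                mcr_bounds=tuple(prior["mcr_bounds"]),
                ab_prior_sd=float(prior["ab_prior_sd"]),
                kappa_bounds=tuple(prior["kappa_bounds"]),
                lam_bounds=tuple(prior["lam_bounds"]),
            ),
        )


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _u_from_theta(theta: np.ndarray) -> np.ndarray:
    """Natural (t_max, MCR, a, b, kappa, lam) -> transformed sampling scale."""
    t, m, a, b, k, lam = theta
    return np.array(
        [np.log(t), _logit(m / 0.25), a, b, _logit(k / 100.0), _logit(lam)]
    )


def _initial_u(rng: np.random.Generator, profile: Profile, how: str) -> np.ndarray:
    if how == "heuristic":
        theta = np.array(
            [60.0, 0.025, 0.0, float(np.median(profile.concentrations)), 5.0, 0.1]
        )
        return _u_from_theta(theta)
    # widely dispersed draw from the flat prior (a, b tempered to the central
    # prior region to keep short burn-ins reliable)
    theta = np.array(
        [
            rng.uniform(10.0, 450.0),
            rng.uniform(0.005, 0.245),
            rng.normal(0.0, 1.0),
            rng.normal(50.0, 40.0),
            rng.uniform(2.0, 60.0),
            rng.uniform(0.02, 0.6),
        ]
    )
    return _u_from_theta(theta)


_INIT_SCALES = np.array([0.2, 0.5, 0.05, 5.0, 0.5, 0.5])


def _run_chain(
    profile: Profile,
    config: Stage1Config,
    seed: int,
    init_u: np.ndarray,
    pop_eta: np.ndarray | None = None,
    pop_sd: np.ndarray | None = None,
):
    """One adaptive chain for one profile; returns (draws, acc, scales, u)."""
    times = profile.times
    brk, rates = profile.dosing.piecewise_rates(float(times[-1]))
    use_pop = 1 if pop_eta is not None else 0
    if pop_eta is None:
        pop_eta = np.zeros(4)
        pop_sd = np.ones(4)
    pk_model._count_ode_call()
    draws, acc, scales, u, status = _kernels.mh_chain(
        profile.concentrations,
        times,
        brk,
        rates,
        profile.context.wt,
        profile.context.t_end,
        profile.context.unit_conversion,
        init_u,
        _INIT_SCALES,
        config.burn_in,
        config.iterations,
        config.thin,
        int(seed),
        np.asarray(pop_eta, dtype=float),
        np.asarray(pop_sd, dtype=float),
        use_pop,
        config.rtol,
        config.atol,
        1,
    )
    if status != 0:
        raise IntegrationFailure(
            f"integration failed during likelihood evaluation (status {status})",
            profile.key.id,
        )
    return draws, acc, scales, u


def run_stage1(
    profile: Profile,
    prior: Stage1Prior | None = None,
    config: Stage1Config | None = None,
    seed: int = 0,
) -> Stage1Entry:
    """Sample the independent posterior for one profile.

    Runs ``config.n_chains`` chains from dispersed starting points, keeps
    every ``thin``-th post-burn-in draw of each, and records the
    Brooks-Gelman-Rubin statistic across chains per parameter.
    """
    prior = prior or Stage1Prior()
    config = config or Stage1Config()
    if profile.n_obs < 6:
        raise ValueError(
            f"profile {profile.key.id}: needs at least 6 observations "
            f"(has {profile.n_obs}) for a 6-parameter fit"
        )
    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.generate_state(config.n_chains) % (2**31 - 1)
    rng = np.random.default_rng(ss.spawn(1)[0])

    chains, accs = [], []
    flags: list[str] = []
    for c in range(config.n_chains):
        init = _initial_u(rng, profile, config.init if c == 0 else "prior")
        try:
            draws, acc, _, _ = _run_chain(profile, config, chain_seeds[c], init)
        except IntegrationFailure:
            flags.append("integration_failure")
            draws = np.empty((0, 6))
            acc = np.full(6, np.nan)
        chains.append(draws)
        accs.append(acc)
    if any(len(c) == 0 for c in chains):
        raise IntegrationFailure("unfittable profile", profile.key.id)

    chain_draws = np.stack(chains)
    bgr = (
        bgr_diagnostic(chain_draws)
        if config.n_chains >= 2
        else np.full(6, np.nan)
    )
    entry = Stage1Entry(
        profile_id=profile.key.id,
        draws=np.concatenate(chains, axis=0),
        chain_draws=chain_draws,
        bgr=bgr,
        acceptance=np.stack(accs),
        seed=seed,
        flags=tuple(flags),
    )
    entry = Stage1Entry(
        **{**entry.__dict__, "flags": tuple(flags) + unfittable_flags(entry)}
    )
    return entry


def run_stage1_dataset(
    dataset: Dataset,
    prior: Stage1Prior | None = None,
    config: Stage1Config | None = None,
    seed: int = 0,
    exclude_flagged: bool = True,
) -> Stage1Store:
    """Fit every included profile; flagged profiles are recorded as excluded
    in the dataset (with the flag as reason) when ``exclude_flagged``."""
    prior = prior or Stage1Prior()
    config = config or Stage1Config()
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(dataset.profiles)) % (2**31 - 1)
    entries = {}
    for s, pid in zip(seeds, list(dataset.included_ids)):
        try:
            entry = run_stage1(dataset.profiles[pid], prior, config, int(s))
        except IntegrationFailure:
            dataset.exclude(pid, "integration_failure")
            continue
        entries[pid] = entry
        if entry.flags and exclude_flagged:
            dataset.exclude(pid, ",".join(entry.flags))
    return Stage1Store(entries=entries, config=config, prior=prior)


def unfittable_flags(entry: Stage1Entry) -> tuple[str, ...]:
    """Reproducible proxy for 'the model could not fit this profile'.

    Flags when the between-chain diagnostic exceeds 1.1 on any kinetic
    parameter, or when more than 5% of the posterior mass of t_max or MCR
    sits within 1% (of the prior range) of a prior bound.
    """
    flags = []
    if np.any(entry.bgr[:4] > 1.1):
        flags.append("bgr")
    d = entry.draws
    for col, (lo, hi) in ((0, (5.0, 500.0)), (1, (0.0, 0.25))):
        tol = 0.01 * (hi - lo)
        frac = np.mean((d[:, col] < lo + tol) | (d[:, col] > hi - tol))
        if frac > 0.05:
            flags.append("boundary")
            break
    return tuple(flags)


def bgr_diagnostic(chains) -> np.ndarray:
    """Brooks-Gelman-Rubin potential scale reduction per parameter.

    ``chains``: (m, n, p) array or list of (n, p) arrays, m >= 2 chains of
    equal length n >= 10.  Returns sqrt(((n-1)/n W + B/n) / W) per parameter;
    values near 1 indicate convergence.  Invariant to joint affine
    transformations of all chains.
    """
    arr = np.stack(list(chains)) if not isinstance(chains, np.ndarray) else chains
    if arr.ndim == 2:
        arr = arr[:, :, None]
    m, n, p = arr.shape
    if m < 2 or n < 10:
        raise ValueError("need at least 2 chains of length >= 10")
    means = arr.mean(axis=1)  # (m, p)
    W = arr.var(axis=1, ddof=1).mean(axis=0)  # (p,)
    B = n * means.var(axis=0, ddof=1)  # (p,)
    out = np.empty(p)
    for j in range(p):
        if W[j] <= 0:
            out[j] = 1.0
        else:
            out[j] = np.sqrt(((n - 1) / n * W[j] + B[j] / n) / W[j])
    return out


def fit_diagnostics(
    profile: Profile,
    draws: np.ndarray,
    n_grid: int = 120,
    band_draws: int = 200,
    seed: int = 0,
) -> dict:
    """Posterior-median fit, 95% predictive band and standardized residuals.

    Returns a dict of plot-ready arrays: ``grid`` (times, median fit, band
    lo/hi) and ``residuals`` (time, predicted, observed, standardized
    residual at the posterior medians).
    """
    if draws.shape[0] < 1:
        raise ValueError("need at least one stored draw")
    rng = np.random.default_rng(seed)
    t0 = min(profile.context.t_start, profile.times[0])
    grid = np.linspace(t0, profile.times[-1], n_grid)
    take = rng.choice(draws.shape[0], size=min(band_draws, draws.shape[0]), replace=False)
    reps = np.empty((len(take), n_grid))
    for r, h in enumerate(take):
        tmax, mcr, a, b, kappa, lam = draws[h]
        params = pk_model.KineticParams(tmax, mcr, a, b)
        q2 = pk_model.q2_at(profile.dosing, tmax, grid)
        mu = pk_model.predicted_concentration(params, profile.context, grid, q2)
        reps[r] = mu + rng.normal(size=n_grid) * np.sqrt(kappa**2 + lam**2 * mu**2)

    med = np.median(draws, axis=0)
    params = pk_model.KineticParams(*med[:4])
    q2g = pk_model.q2_at(profile.dosing, params.t_max, grid)
    fit = pk_model.predicted_concentration(params, profile.context, grid, q2g)
    q2o = pk_model.q2_at(profile.dosing, params.t_max, profile.times)
    mu_obs = pk_model.predicted_concentration(params, profile.context, profile.times, q2o)
    sd_obs = np.sqrt(med[4] ** 2 + med[5] ** 2 * mu_obs**2)
    return dict(
        grid=dict(
            time=grid,
            fit=fit,
            lo=np.quantile(reps, 0.025, axis=0),
            hi=np.quantile(reps, 0.975, axis=0),
        ),
        residuals=dict(
            time=profile.times,
            predicted=mu_obs,
            observed=profile.concentrations,
            standardized=(profile.concentrations - mu_obs) / sd_obs,
        ),
    )


def nearest_draw_index(entry: Stage1Entry) -> int:
    """Index of the stored draw closest to the posterior medians
    (componentwise standardized distance over the kinetic parameters)."""
    d = entry.draws[:, :4]
    med = np.median(d, axis=0)
    scale = np.maximum(d.std(axis=0), 1e-12)
    return int(np.argmin(((d - med) / scale) ** 2 @ np.ones(4)))
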