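"""Hierarchical-model MCMC reusing the first-stage draw store (second stage).

One systematic-scan sweep updates, in order: all intercepts by exact Gibbs
draws from their normal full conditionals; all variance components by
stepping-out/shrinkage slice sampling on the sd scale; every profile's
kinetic parameters by a resampling Metropolis-Hastings step whose proposal is
a uniformly chosen stored first-stage draw; and, when covariates are on, the
twelve reversible-jump blocks (4 parameters x 3 covariate groups).

The resampling step is the heart of the method: because the proposal is the
first-stage posterior, the profile likelihood cancels from the acceptance
ratio

    rho = [p(theta* | Omega) / p(theta | Omega)] * [p1(theta) / p1(theta*)]

so the second stage never touches the ODE solver and a wide range of
population models can be explored at trivial cost.  The uniform components of
the first-stage prior p1 cancel exactly within support; the N(0, 100^2)
components for a and b are computed exactly rather than approximated away.
The ratio does not depend on the error parameters (kappa, lambda), so they
ride along with the stored draw index and need no update of their own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .population_model import (
    GROUPS,
    LOGNORMAL_PARAMS,
    MAX_INTERACTION_Q,
    PHI_PRIOR_SD,
    SD_PRIOR_UPPER,
    HierarchyIndex,
    ModelSpec,
    PopulationState,
    SelectionState,
    default_delta_beta,
    initial_population_state,
    make_group_priors,
    model_prior_logpmf,
)
from .stage1_mcmc import Stage1Store, nearest_draw_index
from .trial_data import Dataset

__all__ = [
    "Stage2Config",
    "Stage2Draws",
    "run_stage2",
    "run_stage2_chains",
    "resample_profile_params",
    "gibbs_normal_mean",
    "slice_update_sd",
    "inclusion_probabilities",
    "prior_inclusion_marginal",
    "variance_decomposition",
    "conditional_effect_summaries",
    "typical_parameters",
]


@dataclass(frozen=True)
class Stage2Config:
    iterations: int = 4000
    burn_in: int = 1000
    thin: int = 4
    slice_width: float = 1.0

    def __post_init__(self):
        if not (self.iterations > 0 and 0 <= self.burn_in and self.thin >= 1):
            raise ValueError("invalid chain lengths")
        if self.iterations % self.thin:
            raise ValueError("iterations must be a multiple of thin")


def gibbs_normal_mean(prior_mean, prior_sd, child_sum, n_children, child_sd, rng):
    """Exact draw from the normal full conditional of a mean node.

    Precision = 1/prior_sd^2 + n/child_sd^2; mean = precision-weighted
    average of the prior mean and the children's average.  Vectorized over
    leading dimensions.
    """
    prec = 1.0 / prior_sd**2 + n_children / child_sd**2
    mean = (prior_mean / prior_sd**2 + child_sum / child_sd**2) / prec
    return mean + rng.standard_normal(np.shape(mean)) / np.sqrt(prec)


def slice_update_sd(
    sigma: float,
    n_children: int,
    sum_sq: float,
    rng: np.random.Generator,
    upper: float = SD_PRIOR_UPPER,
    width: float = 1.0,
) -> float:
    """One stepping-out/shrinkage slice-sampling transition for a sd.

    Target: p(sigma) proportional to sigma^-n exp(-SS / (2 sigma^2)) on
    (0, upper) (normal children, uniform prior on the sd).  With no children
    the target is the Uniform(0, upper) prior itself.
    """

    def logf(s):
        if not 0.0 < s < upper:
            return -math.inf
        if n_children == 0:
            return 0.0
        return -n_children * math.log(s) - 0.5 * sum_sq / (s * s)

    y = logf(sigma) - rng.exponential()
    lo = sigma - width * rng.random()
    hi = lo + width
    while lo > 0.0 and logf(lo) > y:
        lo -= width
    while hi < upper and logf(hi) > y:
        hi += width
    lo = max(lo, 0.0)
    hi = min(hi, upper)
    while True:
        prop = rng.uniform(lo, hi)
        if logf(prop) > y:
            return prop
        if prop < sigma:
            lo = prop
        else:
            hi = prop


def _resample_log_ratio(v_cur, v_prop, lp1_cur, lp1_prop, eta, sigma_theta):
    """Log acceptance ratio of the resampling MH step, vectorized over
    profiles.  v_* are (n, 4) on the random-effect scale (log t_max, log MCR,
    a, b); lp1_* the non-constant stage-1 log-prior; eta (n, 4); sigma (4,)."""
    z_prop = (v_prop - eta) / sigma_theta
    z_cur = (v_cur - eta) / sigma_theta
    delta = 0.5 * (z_cur**2 - z_prop**2).sum(axis=-1)
    # log-normal Jacobians: log p includes -log theta = -v for l = 0, 1
    delta += (v_cur[..., 0] + v_cur[..., 1]) - (v_prop[..., 0] + v_prop[..., 1])
    return delta + lp1_cur - lp1_prop


def resample_profile_params(entry, current_index, eta, sigma_theta, prior, rng):
    """One resampling MH update for a single profile.

    Proposes a uniformly chosen stored draw and accepts with probability
    min(1, rho); the likelihood has cancelled, so only the population density
    and the exact stage-1 prior ratio are evaluated.  Returns the new index
    into the store.
    """
    H = entry.n_draws
    s = int(rng.integers(H))
    theta = entry.draws[:, :4]
    v = theta.copy()
    v[:, 0] = np.log(v[:, 0])
    v[:, 1] = np.log(v[:, 1])
    lp1 = prior.log_density_ab(theta[:, 2], theta[:, 3])
    logr = _resample_log_ratio(
        v[current_index], v[s], lp1[current_index], lp1[s],
        np.asarray(eta, dtype=float), np.asarray(sigma_theta, dtype=float),
    )
    if math.log(rng.random()) < logr:
        return s
    return current_index


class Stage2Sampler:
    """Systematic-scan sampler over the population state and draw indices."""

    def __init__(
        self,
        store: Stage1Store,
        dataset: Dataset,
        spec: ModelSpec,
        config: Stage2Config,
        seed: int,
        profile_ids=None,
    ):
        pids = list(profile_ids) if profile_ids is not None else [
            p for p in dataset.included_ids if p in store.entries
        ]
        missing = [p for p in pids if p not in store.entries]
        if missing:
            raise ValueError(f"store lacks first-stage draws for {missing}")
        if not pids:
            raise ValueError("no profiles to fit")
        self.pids = pids
        self.spec = spec
        self.config = config
        self.store = store
        self.rng = np.random.default_rng(seed)
        self.index = HierarchyIndex(dataset, pids)
        self.n = len(pids)

        theta_store = store.theta_draws(pids)  # (n, H, 4)
        self.H = theta_store.shape[1]
        v_store = theta_store.copy()
        v_store[:, :, 0] = np.log(v_store[:, :, 0])
        v_store[:, :, 1] = np.log(v_store[:, :, 1])
        self.v_store = v_store
        self.lp1_store = store.prior.log_density_ab(
            theta_store[:, :, 2], theta_store[:, :, 3]
        )

        self.design = None
        self.X = np.zeros((self.n, 0))
        if spec.covariates_on:
            if dataset.design is None:
                raise ValueError("covariates_on requires a covariate design")
            self.design = dataset.design
            self.X = dataset.design.rows_for(pids)
            delta = spec.delta_beta or default_delta_beta(store.medians(pids))
            self.group_priors = make_group_priors(spec, dataset.design, delta)
            self.group_cols = {
                g: dataset.design.columns_of(g) for g in GROUPS
            }

        self.theta_idx = np.array(
            [nearest_draw_index(store.entries[p]) for p in pids], dtype=int
        )
        self.v = v_store[np.arange(self.n), self.theta_idx]
        self.state = initial_population_state(spec, self.index, self.v)
        self.accept = {"resample": 0.0, "rj": 0.0}
        self._n_resample = 0
        self._n_rj = 0

    # ---- pieces of one sweep -------------------------------------------

    def _covariate_contribution(self) -> np.ndarray:
        wb = np.zeros((self.n, 4))
        if self.spec.covariates_on:
            for l in range(4):
                wb[:, l] = self.state.covariate_contribution(l, self.X)
        return wb

    def _intercept_vector(self) -> np.ndarray:
        st, spec, idx = self.state, self.spec, self.index
        if spec.level == "one":
            return np.tile(st.phi, (self.n, 1))
        if spec.level == "two":
            return st.psi[idx.woman_of_profile]
        cell_of_profile, _ = idx.cells(spec.level)
        return st.chi[cell_of_profile]

    def _update_intercepts(self, wb: np.ndarray) -> None:
        st, spec, idx, rng = self.state, self.spec, self.index, self.rng
        r = self.v - wb  # residuals after covariates, per profile
        if spec.level == "one":
            for l in range(4):
                st.phi[l] = gibbs_normal_mean(
                    0.0, PHI_PRIOR_SD[l], r[:, l].sum(), self.n,
                    st.sigma_theta[l], rng,
                )
            return
        w_of = idx.woman_of_profile
        nw = idx.n_women
        counts_w = np.bincount(w_of, minlength=nw)
        if spec.level == "two":
            for l in range(4):
                st.psi[:, l] = gibbs_normal_mean(
                    st.phi[l], st.sigma_psi[l],
                    np.bincount(w_of, weights=r[:, l], minlength=nw),
                    counts_w, st.sigma_theta[l], rng,
                )
                st.phi[l] = gibbs_normal_mean(
                    0.0, PHI_PRIOR_SD[l], st.psi[:, l].sum(), nw,
                    st.sigma_psi[l], rng,
                )
            return
        cell_of_profile, woman_of_cell = idx.cells(spec.level)
        ncell = len(woman_of_cell)
        counts_c = np.bincount(cell_of_profile, minlength=ncell)
        counts_cw = np.bincount(woman_of_cell, minlength=nw)
        for l in range(4):
            st.chi[:, l] = gibbs_normal_mean(
                st.psi[woman_of_cell, l], st.sigma_chi[l],
                np.bincount(cell_of_profile, weights=r[:, l], minlength=ncell),
                counts_c, st.sigma_theta[l], rng,
            )
            st.psi[:, l] = gibbs_normal_mean(
                st.phi[l], st.sigma_psi[l],
                np.bincount(woman_of_cell, weights=st.chi[:, l], minlength=nw),
                counts_cw, st.sigma_chi[l], rng,
            )
            st.phi[l] = gibbs_normal_mean(
                0.0, PHI_PRIOR_SD[l], st.psi[:, l].sum(), nw, st.sigma_psi[l], rng,
            )

    def _update_sds(self, wb: np.ndarray) -> None:
        st, spec, idx, rng = self.state, self.spec, self.index, self.rng
        eta = self._intercept_vector() + wb
        dev = self.v - eta
        for l in range(4):
            st.sigma_theta[l] = slice_update_sd(
                st.sigma_theta[l], self.n, float((dev[:, l] ** 2).sum()), rng,
                width=self.config.slice_width,
            )
        if spec.n_levels >= 2:
            d = st.psi - st.phi
            for l in range(4):
                st.sigma_psi[l] = slice_update_sd(
                    st.sigma_psi[l], st.psi.shape[0], float((d[:, l] ** 2).sum()),
                    rng, width=self.config.slice_width,
                )
        if spec.n_levels == 3:
            _, woman_of_cell = idx.cells(spec.level)
            d = st.chi - st.psi[woman_of_cell]
            for l in range(4):
                st.sigma_chi[l] = slice_update_sd(
                    st.sigma_chi[l], st.chi.shape[0], float((d[:, l] ** 2).sum()),
                    rng, width=self.config.slice_width,
                )

    def _resample_theta(self, wb: np.ndarray) -> None:
        rng = self.rng
        eta = self._intercept_vector() + wb
        s = rng.integers(self.H, size=self.n)
        ar = np.arange(self.n)
        v_prop = self.v_store[ar, s]
        logr = _resample_log_ratio(
            self.v, v_prop,
            self.lp1_store[ar, self.theta_idx], self.lp1_store[ar, s],
            eta, self.state.sigma_theta,
        )
        acc = np.log(rng.random(self.n)) < logr
        self.theta_idx[acc] = s[acc]
        self.v[acc] = v_prop[acc]
        self.accept["resample"] += acc.mean()
        self._n_resample += 1

    # ---- reversible jump ------------------------------------------------

    def _rj_update(self, l: int, group: str, intercept: np.ndarray) -> None:
        cols = self.group_cols[group]
        if len(cols) == 0:
            return
        st = self.state
        sel = st.selection[l][group]
        # residual after intercept and the other two groups
        other = np.zeros(self.n)
        for g2, s2 in st.selection[l].items():
            if g2 != group and s2.q:
                other += self.X[:, s2.gamma] @ s2.beta
        r = self.v[:, l] - intercept[:, l] - other
        accepted = rj_update_group(
            sel, self.X, r, st.sigma_theta[l],
            self.group_priors[l].coef_sd[group], group, cols, self.rng,
        )
        if accepted is not None:
            self._n_rj += 1
            self.accept["rj"] += float(accepted)

    def sweep(self) -> None:
        wb = self._covariate_contribution()
        self._update_intercepts(wb)
        self._update_sds(wb)
        self._resample_theta(wb)
        if self.spec.covariates_on:
            intercept = self._intercept_vector()
            for l in range(4):
                for group in GROUPS:
                    self._rj_update(l, group, intercept)


def _move_menu(q: int, c: int, q_max: int) -> list[str]:
    moves = []
    if q < min(c, q_max):
        moves.append("add")
    if q > 0:
        moves.append("delete")
    if 0 < q < c:
        moves.append("swap")
    if q > 0:
        moves.append("refresh")
    return moves


def rj_update_group(
    sel: SelectionState,
    X: np.ndarray,
    r: np.ndarray,
    sigma: float,
    sd_coef: float,
    group: str,
    cols: np.ndarray,
    rng: np.random.Generator,
):
    """One reversible-jump transition on (q, gamma, beta) for one group.

    ``r`` is the residual the group explains (r ~ N(X[:, gamma] beta,
    sigma^2) rowwise); X may have zero rows, in which case the chain samples
    the covariate-model prior exactly.  Moves: add / delete / swap (entering
    coefficients drawn from their prior, so the coefficient prior cancels
    from the acceptance ratio) and a conjugate Gibbs refresh of beta at fixed
    (q, gamma).  Mutates ``sel``; returns True/False for an accepted/rejected
    trans-model move, or None for the (always-accepted) refresh.
    """
    c = len(cols)
    q_max = MAX_INTERACTION_Q if group == "interaction" else c
    q = sel.q

    def sum_sq(gamma, beta):
        e = r if len(gamma) == 0 else r - X[:, gamma] @ beta
        return float(e @ e)

    menu = _move_menu(q, c, q_max)
    move = menu[int(rng.integers(len(menu)))]

    if move == "refresh":
        W = X[:, sel.gamma]
        A = W.T @ W / sigma**2 + np.eye(q) / sd_coef**2
        b = W.T @ r / sigma**2
        L = np.linalg.cholesky(A)
        mean = np.linalg.solve(A, b)
        sel.beta = mean + np.linalg.solve(L.T, rng.standard_normal(q))
        return None

    ss_cur = sum_sq(sel.gamma, sel.beta)
    selected = set(sel.gamma.tolist())
    unselected = [j for j in cols if j not in selected]
    lp_cur = model_prior_logpmf(group, q, _local(sel.gamma, cols), c)
    if move == "add":
        j = unselected[int(rng.integers(len(unselected)))]
        gamma_p = np.append(sel.gamma, j)
        beta_p = np.append(sel.beta, rng.normal(0.0, sd_coef))
        lp_prop = model_prior_logpmf(group, q + 1, _local(gamma_p, cols), c)
        logr = (
            -(sum_sq(gamma_p, beta_p) - ss_cur) / (2 * sigma**2)
            + lp_prop - lp_cur
            + math.log(len(_move_menu(q, c, q_max))) + math.log(c - q)
            - math.log(len(_move_menu(q + 1, c, q_max))) - math.log(q + 1)
        )
    elif move == "delete":
        k = int(rng.integers(q))
        gamma_p = np.delete(sel.gamma, k)
        beta_p = np.delete(sel.beta, k)
        lp_prop = model_prior_logpmf(group, q - 1, _local(gamma_p, cols), c)
        logr = (
            -(sum_sq(gamma_p, beta_p) - ss_cur) / (2 * sigma**2)
            + lp_prop - lp_cur
            + math.log(len(_move_menu(q, c, q_max))) + math.log(q)
            - math.log(len(_move_menu(q - 1, c, q_max))) - math.log(c - q + 1)
        )
    else:  # swap: uniform over (out, in) pairs, entering coefficient from prior
        k = int(rng.integers(q))
        j = unselected[int(rng.integers(len(unselected)))]
        gamma_p = sel.gamma.copy()
        beta_p = sel.beta.copy()
        gamma_p[k] = j
        beta_p[k] = rng.normal(0.0, sd_coef)
        logr = -(sum_sq(gamma_p, beta_p) - ss_cur) / (2 * sigma**2)

    if math.log(rng.random()) < logr:
        sel.gamma = gamma_p
        sel.beta = beta_p
        return True
    return False


def rj_prior_chain(
    n_sweeps: int,
    group: str = "interaction",
    c: int = 4,
    sd_coef: float = 1.0,
    seed: int = 0,
) -> list[tuple[int, ...]]:
    """Reversible-jump chain with a flat likelihood (zero profiles attached).

    The stationary distribution is then exactly the covariate-model prior;
    returns the visited model (sorted gamma tuple) per sweep.
    """
    rng = np.random.default_rng(seed)
    sel = SelectionState()
    X = np.zeros((0, c))
    r = np.zeros(0)
    cols = np.arange(c)
    visits = []
    for _ in range(n_sweeps):
        rj_update_group(sel, X, r, 1.0, sd_coef, group, cols, rng)
        visits.append(tuple(sorted(int(j) for j in sel.gamma)))
    return visits


def _local(gamma: np.ndarray, cols: np.ndarray):
    """Columns of a group expressed as within-group indices (for the prior)."""
    lookup = {int(j): i for i, j in enumerate(cols)}
    return np.array([lookup[int(j)] for j in gamma], dtype=int)


@dataclass
class Stage2Draws:
    """Thinned posterior draws of the population state.

    ``incl`` and ``beta`` are (S, 4, c) over all design columns; ``beta`` is
    NaN where a column is not in the model.  ``theta_idx`` records the
    first-stage draw index per profile at each stored sweep.
    """

    phi: np.ndarray
    sigma_theta: np.ndarray
    sigma_psi: np.ndarray | None
    sigma_chi: np.ndarray | None
    psi: np.ndarray | None
    chi: np.ndarray | None
    incl: np.ndarray | None
    beta: np.ndarray | None
    theta_idx: np.ndarray
    spec: ModelSpec
    profile_ids: list[str]
    col_names: list[str] | None = None
    col_groups: list[str] | None = None
    women: list[int] = field(default_factory=list)  # woman id per psi column
    cells: list[tuple] = field(default_factory=list)  # cell key per chi column
    acceptance: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def n_draws(self) -> int:
        return self.phi.shape[0]

    def save(self, path) -> None:
        import json

        meta = dict(
            version=1,
            level=self.spec.level,
            covariates_on=self.spec.covariates_on,
            delta_beta=None if self.spec.delta_beta is None else list(self.spec.delta_beta),
            profile_ids=self.profile_ids,
            col_names=self.col_names,
            col_groups=self.col_groups,
            women=self.women,
            cells=[list(c) for c in self.cells],
            acceptance={k: float(v) for k, v in self.acceptance.items()},
            seed=int(self.seed),
        )
        arrays = dict(
            _meta=np.array(json.dumps(meta)),
            phi=self.phi,
            sigma_theta=self.sigma_theta,
            theta_idx=self.theta_idx,
        )
        for name in ("sigma_psi", "sigma_chi", "psi", "chi", "incl", "beta"):
            val = getattr(self, name)
            if val is not None:
                arrays[name] = val
        np.savez_compressed(path, **arrays)

    @staticmethod
    def load(path) -> "Stage2Draws":
        import json

        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["_meta"]))
            opt = {
                name: (z[name] if name in z.files else None)
                for name in ("sigma_psi", "sigma_chi", "psi", "chi", "incl", "beta")
            }
            return Stage2Draws(
                phi=z["phi"],
                sigma_theta=z["sigma_theta"],
                theta_idx=z["theta_idx"],
                spec=ModelSpec(
                    level=meta["level"],
                    covariates_on=meta["covariates_on"],
                    delta_beta=None
                    if meta["delta_beta"] is None
                    else tuple(meta["delta_beta"]),
                ),
                profile_ids=meta["profile_ids"],
                col_names=meta["col_names"],
                col_groups=meta["col_groups"],
                women=meta["women"],
                cells=[tuple(c) for c in meta["cells"]],
                acceptance=meta["acceptance"],
                seed=meta["seed"],
                **opt,
            )


def run_stage2(
    store: Stage1Store,
    dataset: Dataset,
    spec: ModelSpec | None = None,
    config: Stage2Config | None = None,
    seed: int = 0,
    exclude: tuple[str, ...] = (),
) -> Stage2Draws:
    """Run the second-stage sampler and return thinned draws.

    ``exclude`` drops profiles from the hierarchy (used by the leave-one-out
    assessment); their first-stage draws are simply never consulted.
    Deterministic given ``seed``.
    """
    spec = spec or ModelSpec()
    config = config or Stage2Config()
    pids = [p for p in dataset.included_ids if p not in exclude]
    smp = Stage2Sampler(store, dataset, spec, config, seed, profile_ids=pids)

    c = smp.X.shape[1]
    S = config.iterations // config.thin
    out_phi = np.empty((S, 4))
    out_st = np.empty((S, 4))
    out_sp = np.empty((S, 4)) if spec.n_levels >= 2 else None
    out_sc = np.empty((S, 4)) if spec.n_levels == 3 else None
    out_psi = (
        np.empty((S, smp.index.n_women, 4)) if spec.n_levels >= 2 else None
    )
    out_chi = (
        np.empty((S, smp.state.chi.shape[0], 4)) if spec.n_levels == 3 else None
    )
    out_incl = np.zeros((S, 4, c), dtype=bool) if spec.covariates_on else None
    out_beta = np.full((S, 4, c), np.nan) if spec.covariates_on else None
    out_idx = np.empty((S, smp.n), dtype=int)

    stored = 0
    for it in range(config.burn_in + config.iterations):
        smp.sweep()
        if it >= config.burn_in and (it - config.burn_in) % config.thin == config.thin - 1:
            out_phi[stored] = smp.state.phi
            out_st[stored] = smp.state.sigma_theta
            if out_sp is not None:
                out_sp[stored] = smp.state.sigma_psi
                out_psi[stored] = smp.state.psi
            if out_sc is not None:
                out_sc[stored] = smp.state.sigma_chi
                out_chi[stored] = smp.state.chi
            if spec.covariates_on:
                for l in range(4):
                    for sel in smp.state.selection[l].values():
                        out_incl[stored, l, sel.gamma] = True
                        out_beta[stored, l, sel.gamma] = sel.beta
            out_idx[stored] = smp.theta_idx
            stored += 1

    acc = dict(smp.accept)
    if smp._n_resample:
        acc["resample"] /= smp._n_resample
    if smp._n_rj:
        acc["rj"] /= smp._n_rj
    return Stage2Draws(
        phi=out_phi,
        sigma_theta=out_st,
        sigma_psi=out_sp,
        sigma_chi=out_sc,
        psi=out_psi,
        chi=out_chi,
        incl=out_incl,
        beta=out_beta,
        theta_idx=out_idx,
        spec=spec,
        profile_ids=smp.pids,
        col_names=None if smp.design is None else smp.design.names,
        col_groups=None if smp.design is None else smp.design.groups,
        women=list(smp.index.women),
        cells=(
            list(smp.index.visit_cells)
            if spec.level == "threeV"
            else list(smp.index.meal_cells)
            if spec.level == "threeM"
            else []
        ),
        acceptance=acc,
        seed=seed,
    )


def run_stage2_chains(
    store: Stage1Store,
    dataset: Dataset,
    spec: ModelSpec | None = None,
    config: Stage2Config | None = None,
    seed: int = 0,
    n_chains: int = 2,
):
    """Multiple independent second-stage chains plus a BGR check on the
    population scalars (phi and sd components)."""
    from .stage1_mcmc import bgr_diagnostic

    seeds = np.random.SeedSequence(seed).generate_state(n_chains) % (2**31 - 1)
    chains = [run_stage2(store, dataset, spec, config, int(s)) for s in seeds]
    scalars = np.stack(
        [np.concatenate([d.phi, d.sigma_theta], axis=1) for d in chains]
    )
    return chains, bgr_diagnostic(scalars)


# ---- posterior summaries -------------------------------------------------


def inclusion_probabilities(draws: Stage2Draws) -> np.ndarray:
    """(4, c) marginal posterior inclusion probability of each design column
    in each kinetic parameter's linear predictor."""
    if draws.incl is None:
        raise ValueError("run with covariates_on to get inclusion probabilities")
    return draws.incl.mean(axis=0)


def prior_inclusion_marginal(group: str, c: int) -> float:
    """Exact prior probability that a given column of ``group`` is selected,
    by enumeration over the q prior (columns exchangeable given q)."""
    from .population_model import interaction_q_pmf
    from scipy.stats import binom

    if group == "interaction":
        return float(sum(interaction_q_pmf(q) * q / c for q in range(5)))
    return float(sum(binom.pmf(q, c, 0.5) * q / c for q in range(c + 1)))


def variance_decomposition(draws: Stage2Draws) -> dict:
    """Posterior mean of each variance component and of its share of the
    total, per kinetic parameter (shares computed per draw, then averaged)."""
    comps = {"theta": draws.sigma_theta**2}
    if draws.sigma_psi is not None:
        comps["psi"] = draws.sigma_psi**2
    if draws.sigma_chi is not None:
        comps["chi"] = draws.sigma_chi**2
    total = sum(comps.values())
    out = {}
    for name, v in comps.items():
        out[name] = dict(
            variance=v.mean(axis=0),
            proportion=(v / total).mean(axis=0),
        )
    return out


def conditional_effect_summaries(draws: Stage2Draws, design=None) -> list[dict]:
    """Per (covariate, parameter): inclusion probability and the posterior
    mean (sd) of the coefficient conditional on inclusion.

    Coefficients are reported per standardized unit; when the design is
    supplied, continuous effects are also given per original covariate unit,
    and effects on t_max and MCR additionally as percentage change per unit
    (100 * (exp(beta) - 1)).  Covariates never selected are flagged
    undefined rather than zero.
    """
    if draws.incl is None:
        raise ValueError("run with covariates_on to get effect summaries")
    pr = inclusion_probabilities(draws)
    out = []
    for l in range(4):
        for j, name in enumerate(draws.col_names):
            sel = draws.incl[:, l, j]
            rec = dict(parameter=l, covariate=name, inclusion=float(pr[l, j]))
            if not sel.any():
                rec.update(defined=False)
            else:
                b = draws.beta[sel, l, j]
                rec.update(defined=True, beta_mean=float(b.mean()), beta_sd=float(b.std()))
                scale = 1.0
                if design is not None:
                    jcol = design.names.index(name)
                    scale = design.scale[jcol]
                b_unit = b / scale
                if l in LOGNORMAL_PARAMS:
                    pct = 100.0 * (np.exp(b_unit) - 1.0)
                    rec.update(pct_per_unit_mean=float(pct.mean()), pct_per_unit_sd=float(pct.std()))
                else:
                    rec.update(per_unit_mean=float(b_unit.mean()), per_unit_sd=float(b_unit.std()))
            out.append(rec)
    return out


def typical_parameters(draws: Stage2Draws) -> dict:
    """Typical kinetic parameters per study-by-mealtime cell.

    'Typical' sets all continuous and binary covariates to zero (their
    centred value) and keeps only the cell's interaction coefficient when it
    is in the model; t_max and MCR are reported on the natural scale
    (exp of the linear predictor).  Returns {cell: (4, 2) mean and sd}.
    """
    if draws.incl is None:
        raise ValueError("run with covariates_on to get typical parameters")
    cells = [n for n, g in zip(draws.col_names, draws.col_groups) if g == "interaction"]
    out = {}
    for cell in cells:
        j = draws.col_names.index(cell)
        b = np.where(draws.incl[:, :, j], np.nan_to_num(draws.beta[:, :, j]), 0.0)
        eta = draws.phi + b  # (S, 4)
        vals = eta.copy()
        vals[:, 0] = np.exp(eta[:, 0])
        vals[:, 1] = np.exp(eta[:, 1])
        out[cell] = np.column_stack([vals.mean(axis=0), vals.std(axis=0)])
    return out
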